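# winterniche

Quantile-regression analysis of how minimum winter temperature limits the
**maximum potential abundance** of wintering birds (or any taxon surveyed on a
grid), with derived thermal-niche statistics and an across-species
meta-analysis.

## The problem and the model

Surveys of winter bird abundance against temperature show a *wedge-shaped*
point cloud: at each temperature, abundance varies from zero up to an upper
limit. The upper edge is the temperature-limited maximum potential abundance;
points below it are cells where other factors (habitat, food) limit the
species further. Ordinary least-squares regression of the mean misses this
limiting-factor structure — upper-quantile regression targets the edge
directly.

For each species, relative abundance *A* (frequency of occurrence in *n* = 60
15-min transects per grid cell, so *A* ∈ [0, 1]) is modelled on minimum winter
temperature *T* with a quadratic quantile regression at percentile τ:

    A = a + b·z₁ + c·z₂,    z₁ = std(T),  z₂ = std(T²)

where `std(·)` standardizes to mean 0, sd 1 so that *b* and *c* are comparable
beta coefficients. The fit minimizes the pinball (check) loss
Σ ρ_τ(residual), solved exactly as a linear program; τ = 0.95 tracks the upper
edge of the wedge. Goodness of fit is the Koenker–Machado pseudo-R²
(1 − V_full/V_null) and model support is the AIC change versus the
intercept-only null, using the asymmetric-Laplace likelihood with the scale
profiled out (AIC = 2k + 2n·ln(V_τ/n)). ΔAIC ≤ −13.82 — an evidence ratio of
exp(13.82/2) ≈ 1,000 — marks a supported temperature model.

From the τ = 0.95 model and the raw survey, three niche statistics follow:

* **T_PREF** — preferred temperature: the °C maximizing the fitted curve on
  the study's thermal span (dÂ/dT = 0, clipped to the span when the vertex
  falls outside or the curve is monotone);
* **T_MEAN** — mean distribution temperature: abundance-weighted average of
  cell temperatures over occupied cells;
* **T_BREADTH** — thermal breadth: area under the fitted curve over the span
  with its maximum standardized to 1, divided by the span width — 1 for a
  thermal generalist, small values for a thermal specialist.

An across-species battery (one-sample/paired t-tests on coefficients and
niche temperatures, a repeated-measures linear contrast of pseudo-R² across
quantile levels, per-species tests of T_MEAN against the regional mean with a
Holm sequential-Bonferroni correction, Pearson r between T_PREF and T_MEAN,
and a mean/sd/range summary table) runs on the resulting species-parameter
table.

Because raw atlas surveys of this kind are rarely deposited, the package
includes a first-class synthetic generator: the wedge arises from a quadratic
potential curve multiplied by a per-cell suppression factor U ~ Uniform(0, 1),
with binomial detection over 60 transects.

## Worked example

```python
import winterniche as wn

cfg = wn.SimulationConfig(n_cells=400, n_species=8, seed=7)
field, pairs = wn.generate_community(cfg)
table, fits = wn.build_species_table(field, [s for _, s in pairs], wn.PipelineConfig())
print(table[["species_id", "t_pref", "t_mean", "t_breadth",
             "delta_aic", "pseudo_r2", "class_pref", "class_thermal"]].round(2))
```

```
species_id  t_pref  t_mean  t_breadth  delta_aic  pseudo_r2 class_pref class_thermal
sp000_cold   -2.00   -0.62       0.25   -1088.72       0.74       cold    specialist
sp001_cold   -2.00   -0.23       0.27    -937.34       0.69       cold    specialist
sp002_flat   -0.78    4.07       0.96     -10.30       0.02       cold    generalist
 sp003_mid    3.02    2.78       0.72    -323.40       0.34        mid  intermediate
 sp004_mid    2.62    3.65       0.84     -83.11       0.10        mid  intermediate
sp005_warm   10.00    6.46       0.54    -384.98       0.39       warm  intermediate
sp006_warm   10.00    6.29       0.64    -370.84       0.37       warm  intermediate
sp007_warm   10.00    6.75       0.47    -385.97       0.39       warm  intermediate
```

Reading the table: the two cold-preferring species peak at the cold edge of
the span (T_PREF clipped to −2 °C) and use a narrow slice of the thermal space
(T_BREADTH ≈ 0.26 → specialists); the flat species has ΔAIC = −10.3 > −13.82,
so its temperature model is not supported, and its breadth ≈ 0.96 marks it a
generalist. The meta battery on this table then reports, e.g.
`r(T_PREF, T_MEAN): statistic=0.985, df=5, p=5.57e-05` — preferred and mean
temperatures rank species almost identically — and
`pseudo-R2 rise across quantiles: statistic=6.965, df=1,7, p=0.0335`: the
temperature signal strengthens toward the upper edge of the wedge.

The same pipeline is available from the shell:

```sh
winterniche all --n-species 8 --n-cells 400 --seed 7 --out-dir out/
# out/: field.csv survey.csv truth.yaml models.csv species_params.csv meta.json
```

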