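# Methods

## Statistical model

For each species, relative abundance per grid cell is the frequency of
occurrence in `n_transects` (default 60) 15-min transects, a probability-like
index in [0, 1]. The predictor is the cell's mean minimum winter temperature
*T* (°C). The fitted model at percentile τ is quadratic in *T* on a
standardized scale:

    Â(T) = a + b·z₁ + c·z₂,   z₁ = (T − μ₁)/σ₁,   z₂ = (T² − μ₂)/σ₂

`z₂` is the standardized *square* of temperature, not the square of `z₁`;
standardizing both predictors to mean 0, sd 1 makes *b* and *c* beta
coefficients comparable across species. The sd uses the sample (n−1)
denominator (configurable via `ddof`); the four constants (μ₁, σ₁, μ₂, σ₂)
are stored on every fitted model because all °C-scale quantities
(T_PREF, T_BREADTH, plotted curves) require the back-transformation

    Â(T) = (a − bμ₁/σ₁ − cμ₂/σ₂) + (b/σ₁)·T + (c/σ₂)·T².

Standardization constants are computed once per species from all cells
supplied for that species' analysis (by default the full field).

### Fitting

The τ-quantile fit minimizes the total pinball loss
Σᵢ ρ_τ(yᵢ − Âᵢ), ρ_τ(r) = r·τ for r ≥ 0 and r·(τ − 1) for r < 0. This convex
problem is solved exactly as a linear program (split positive/negative
residual variables, equality-constrained, HiGHS solver): no tuning, global
optimum, reproducible. On degenerate instances any loss-minimizing vertex is
accepted — tests compare losses, not coefficients. Standard LP optimality
implies the residual-sign coverage property (at most τ·n strictly negative
and (1 − τ)·n strictly positive residuals), asserted in the test suite.
Default quantile levels are τ = 0.50, 0.75, 0.90, 0.95; τ = 0.95 defines the
upper-edge (limiting-factor) model used for the niche statistics.

### Model screening

* Pseudo-R² = 1 − V_full/V_null (Koenker–Machado), with the intercept-only
  model at the same τ as the null; nesting guarantees values in [0, 1].
* AIC from the asymmetric-Laplace likelihood with the scale parameter
  profiled out: AIC = 2k + 2n·ln(V_τ/n) plus an additive constant that
  cancels in ΔAIC = AIC_full − AIC_null (k = 3 vs 1). V_τ = 0 (perfect
  interpolation) returns a −∞ AIC sentinel.
* A temperature model is *supported* when ΔAIC ≤ −13.82, i.e. an evidence
  ratio exp(−ΔAIC/2) ≥ 1,000 over the null. A softer secondary band
  (−13.82 < ΔAIC ≤ −6) can be read directly off the emitted tables.

## Niche statistics

* **T_PREF**: the stationary point of the °C-scale curve is
  T\* = −(b·σ₂)/(2·c·σ₁). If the curve is concave (c < 0) and T\* lies within
  the analysis span (default [−2, 10] °C), T\* is returned flagged
  `interior`. Convex or monotone curves, and exterior vertices, return the
  better endpoint flagged `boundary` — deliberate, since real communities
  contain cold-edge species whose preference saturates at the domain
  boundary. A flat curve (b = c = 0) returns the span midpoint flagged
  `flat`.
* **T_MEAN**: Σ wᵢTᵢ/Σ wᵢ over cells with ≥ 1 detection, wᵢ = relative
  abundance. Invariant to positive rescaling of the weights.
* **T_BREADTH**: ∫ max(Â(T), 0) dT over the span, divided by (max Â)·(span
  width). The integral is closed-form: the quadratic's real roots partition
  the span and the antiderivative is summed over sub-intervals where the
  curve is positive. Negative predicted abundances are clipped before
  integrating (abundance cannot be negative and clipping keeps the index in
  (0, 1]); an unclipped variant is available (`clip_negative=False`) for
  sensitivity analysis.
* Classification: breadth < 0.33 → specialist, > 0.90 → generalist;
  T_PREF < 0 °C → cold-preferring, > 5 °C → warm-preferring. Strict
  inequalities; boundary values fall in the middle class.

## Across-species battery

All tests are closed forms cross-checked against an independent statistics
library in the suite. One-sample and paired t-tests are the classical
two-sided forms (a paired test with *all* differences exactly zero returns
t = 0 by convention; a nonzero constant difference raises a zero-variance
error). The rise of pseudo-R² with quantile level is tested as a
repeated-measures linear contrast: per-species scores sᵢ = Σⱼ wⱼxᵢⱼ with
centered linear-in-level weights wⱼ = τⱼ − mean(τ) (an equal-spacing variant
can be passed explicitly), and F(1, n−1) = t² on the scores. Per-species
tests of occupied-cell temperatures against the regional mean use the
unweighted one-sample t by default — the simplest reading — with an
abundance-weighted variant behind a flag (frequency-weight heuristic:
weights rescaled to sum to the cell count); the Holm step-down procedure is
the meaning adopted for "sequential Bonferroni", at α = 0.05. The summary
table reports mean/sd/range of b, c and T_PREF over species with supported
models only, and of T_MEAN and T_BREADTH over all species, mirroring the
convention that coefficient summaries are meaningless for unsupported
models. The species inclusion filter retains species detected in ≥ 50 cells
with a maximum frequency ≥ 0.05 (= 3/60 transects).

The regional mean temperature defaults to the mean of the supplied field and
can be overridden (e.g. to a published regional value) for replication runs.

## Synthetic data generator

The generator emulates a national winter atlas: 1,689 cells with
temperatures drawn uniformly on [−2, 10] °C (the empirical distribution of a
real grid is survey-specific; uniform is the declared stand-in and is
configurable), 103 species, 60 transects per cell. Each species has a
ground-truth *potential* curve clip(a₀ + b₀T + c₀T², 0, 1) specified on the
°C scale; realized abundance per cell is the potential multiplied by a
suppression factor U ~ Uniform(0, 1) (configurable; `constant 1` disables
suppression for oracle-mode checks), and detections are
Binomial(n_transects, p). Multiplicative uniform suppression is the simplest
process producing a solid wedge whose upper edge equals the potential curve:
the 0.95-quantile of U·potential is 0.95·potential, so the τ = 0.95 fit
recovers the potential's shape (and its vertex exactly).

Species archetypes — warm (vertex 6–9.5 °C), cold (−4–0 °C, often clipped at
the domain edge), mid (1–5 °C) and flat (b₀ = c₀ = 0) — are allocated in
proportions 0.39/0.23/0.28/0.10, chosen to span the compositions reported
for real winter communities (a warm-preferring majority, a substantial
cold-preferring minority, a small temperature-independent fraction). Peak
heights are drawn in 0.25–0.85 and half-widths in 5–11 °C so that breadths
span the specialist-to-generalist range. All randomness flows from a single
seed through `numpy.random.SeedSequence` spawning, so communities are
bit-reproducible.

What the generator does *not* emulate: spatial autocorrelation of
temperature and abundance, habitat covariates, observer effects, and
species co-occurrence. Passing recovery tests therefore show the estimator
chain is correct under the wedge model's assumptions, not that real surveys
satisfy those assumptions.

## Numerical choices and limitations

* Quantile crossing: independently fitted parametric quantile curves can
  cross. In wedge simulations crossings are confined to regions where the
  τ = 0.95 curve predicts abundance below the single-detection resolution
  (1/n_transects) — there all empirical quantiles are zero and the
  parametric tails are unconstrained. The suite asserts the median curve
  lies below the upper-quantile curve on the detectable region and that any
  crossing elsewhere stays within the detection-resolution scale.
* LP tolerance: achieved losses agree with an interior-point oracle to
  1e−6 relative; pseudo-R² is clamped to [0, 1] against sub-tolerance LP
  noise.
* T_PREF grid checks use a 0.001 °C grid; breadth checks an adaptive
  quadrature oracle at 1e−6.
* Problem sizes in the test suite and acceptance script (communities of
  3–103 species, 150–1,689 cells, 25–50 replicates) were chosen as the
  smallest scales at which the recovery properties stabilize.
* The per-species T_MEAN test's exact weighting is a genuine design choice
  (unweighted default, weighted variant); with strongly skewed abundance
  the two can disagree.
* Standardized coefficients depend on the temperature distribution of the
  field: a narrow empirical distribution makes T and T² nearly collinear
  and inflates |b| and |c| in opposite directions. Synthetic (uniform-
  temperature) communities therefore produce smaller beta magnitudes than
  surveys whose cells cluster in a narrow thermal band; comparisons of
  coefficient *magnitudes* across datasets should be made with that in
  mind.
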