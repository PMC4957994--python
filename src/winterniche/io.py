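"""Delimited-text readers/writers and pipeline configuration.

Interchange dialect: comma-separated, header row, UTF-8, "." decimal.  The
survey table has one row per cell × species (cell_id, species_id, detections,
n_transects); the temperature table one row per cell (cell_id, temp_c); the
ground-truth manifest is YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .quantile_fit import DEFAULT_TAUS, DELTA_AIC_CUTOFF, SpeciesFit
from .synthetic_data import (
    SimulationConfig,
    SpeciesSurvey,
    SpeciesTruth,
    SuppressionLaw,
    TemperatureField,
)
from .thermal_niche import (
    BREADTH_GENERALIST,
    BREADTH_SPECIALIST,
    DOMAIN,
    PREF_COLD,
    PREF_WARM,
    NicheParams,
)

__all__ = [
    "PipelineConfig",
    "read_field",
    "write_field",
    "read_surveys",
    "write_surveys",
    "write_truths",
    "read_truths",
    "models_to_frame",
    "niche_to_frame",
    "build_species_table",
]


class ParseError(ValueError):
    """Malformed input table; the message names the offending row."""


@dataclass(frozen=True)
class PipelineConfig:
    """All analysis thresholds in one place; defaults are the standard ones."""

    taus: tuple = DEFAULT_TAUS
    domain_lo: float = DOMAIN[0]
    domain_hi: float = DOMAIN[1]
    min_cells: int = 50
    min_max_freq: float = 0.05
    delta_aic_cutoff: float = DELTA_AIC_CUTOFF
    breadth_specialist: float = BREADTH_SPECIALIST
    breadth_generalist: float = BREADTH_GENERALIST
    pref_cold: float = PREF_COLD
    pref_warm: float = PREF_WARM
    regional_mean: float | None = None  # None -> computed from the field
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        taus = tuple(float(t) for t in self.taus)
        if any(not 0.0 < t < 1.0 for t in taus):
            raise ValueError("quantile levels must lie strictly in (0, 1)")
        if list(taus) != sorted(taus):
            raise ValueError("quantile levels must be sorted ascending")
        if not self.domain_lo < self.domain_hi:
            raise ValueError("domain_lo must be below domain_hi")
        object.__setattr__(self, "taus", taus)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def write_field(field: TemperatureField, path: str | Path) -> None:
    pd.DataFrame({"cell_id": field.cell_id, "temp_c": field.temperature}).to_csv(
        path, index=False
    )


def read_field(path: str | Path) -> TemperatureField:
    df = pd.read_csv(path)
    for col in ("cell_id", "temp_c"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    bad = df.index[~np.isfinite(df["temp_c"].to_numpy(dtype=float))]
    if len(bad):
        raise ParseError(f"{path}: non-finite temperature at row {bad[0] + 2}")
    return TemperatureField(
        cell_id=df["cell_id"].to_numpy(), temperature=df["temp_c"].to_numpy(float)
    )


def write_surveys(surveys: Iterable[SpeciesSurvey], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {
                "cell_id": s.cell_id,
                "species_id": s.species_id,
                "detections": s.detections,
                "n_transects": s.n_transects,
            }
        )
        for s in surveys
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_surveys(path: str | Path) -> list[SpeciesSurvey]:
    df = pd.read_csv(path)
    required = ("cell_id", "species_id", "detections", "n_transects")
    for col in required:
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    det = df["detections"]
    if not np.array_equal(det, det.astype(np.int64)):
        bad = df.index[det != det.astype(np.int64)][0]
        raise ParseError(f"{path}: non-integer detections at row {bad + 2}")
    over = df.index[df["detections"] > df["n_transects"]]
    if len(over):
        raise ParseError(
            f"{path}: detections exceed n_transects at row {over[0] + 2} "
            f"(species {df.loc[over[0], 'species_id']!r})"
        )
    neg = df.index[df["detections"] < 0]
    if len(neg):
        raise ParseError(f"{path}: negative detections at row {neg[0] + 2}")
    out = []
    for sid, grp in df.groupby("species_id", sort=True):
        n_tr = grp["n_transects"].unique()
        if n_tr.size != 1:
            raise ParseError(f"{path}: species {sid!r} has varying n_transects")
        out.append(
            SpeciesSurvey(
                species_id=str(sid),
                cell_id=grp["cell_id"].to_numpy(),
                detections=grp["detections"].to_numpy(np.int64),
                n_transects=int(n_tr[0]),
            )
        )
    return out


def write_truths(truths: Iterable[SpeciesTruth], config: SimulationConfig, path: str | Path) -> None:
    """Ground-truth manifest: the simulation config plus each species' curve."""
    doc = {
        "config": {
            "n_cells": config.n_cells,
            "temp_lo": config.temp_lo,
            "temp_hi": config.temp_hi,
            "n_species": config.n_species,
            "n_transects": config.n_transects,
            "archetype_mix": dict(config.archetype_mix),
            "suppression": asdict(config.suppression),
            "seed": config.seed,
        },
        "species": [
            {
                "species_id": t.species_id,
                "a0": t.a0,
                "b0": t.b0,
                "c0": t.c0,
                "archetype": t.archetype,
                "n_transects": t.n_transects,
                "suppression": asdict(t.suppression),
            }
            for t in truths
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_truths(path: str | Path) -> tuple[SimulationConfig, list[SpeciesTruth]]:
    doc = yaml.safe_load(Path(path).read_text())
    cfg_d = dict(doc["config"])
    cfg_d["suppression"] = SuppressionLaw(**cfg_d["suppression"])
    config = SimulationConfig(**cfg_d)
    truths = [
        SpeciesTruth(
            species_id=s["species_id"],
            a0=s["a0"],
            b0=s["b0"],
            c0=s["c0"],
            archetype=s.get("archetype", ""),
            n_transects=s["n_transects"],
            suppression=SuppressionLaw(**s["suppression"]),
        )
        for s in doc["species"]
    ]
    return config, truths


def models_to_frame(fits: Iterable[SpeciesFit]) -> pd.DataFrame:
    """Per-species per-τ model table (one row per fitted full model)."""
    rows = []
    for fit in fits:
        for tau, m in sorted(fit.models.items()):
            rows.append(
                {
                    "species_id": fit.species_id,
                    "tau": tau,
                    "a": m.a,
                    "b": m.b,
                    "c": m.c,
                    "loss": m.loss,
                    "pseudo_r2": m.pseudo_r2,
                    "delta_aic": m.delta_aic,
                    "n": m.n,
                    "mu1": m.predictors.mu1,
                    "sigma1": m.predictors.sigma1,
                    "mu2": m.predictors.mu2,
                    "sigma2": m.predictors.sigma2,
                }
            )
    return pd.DataFrame(rows)


def niche_to_frame(
    fits: Sequence[SpeciesFit],
    niches: Sequence[NicheParams],
    tau: float = 0.95,
) -> pd.DataFrame:
    """Species-parameter table in the supplementary-table column layout."""
    by_id = {f.species_id: f for f in fits}
    rows = []
    for p in niches:
        fit = by_id[p.species_id]
        m = fit.models[tau]
        row = {
            "species_id": p.species_id,
            "b": m.b,
            "c": m.c,
            "delta_aic": m.delta_aic,
            "pseudo_r2": m.pseudo_r2,
            "t_pref": p.t_pref,
            "t_pref_flag": p.t_pref_flag,
            "t_mean": p.t_mean,
            "t_breadth": p.t_breadth,
            "class_thermal": p.class_thermal,
            "class_pref": p.class_pref,
        }
        for other_tau, om in sorted(fit.models.items()):
            row[f"pseudo_r2_{other_tau:g}"] = om.pseudo_r2
        rows.append(row)
    return pd.DataFrame(rows)


def build_species_table(
    field: TemperatureField,
    surveys: Sequence[SpeciesSurvey],
    config: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, list[SpeciesFit]]:
    """Filter, fit and derive niche parameters for a whole community."""
    from .meta_analysis import species_filter
    from .quantile_fit import fit_species
    from .thermal_niche import species_niche

    cfg = config or PipelineConfig()
    kept = species_filter(surveys, cfg.min_cells, cfg.min_max_freq)
    fits, niches = [], []
    for s in kept:
        fit = fit_species(s, field, taus=cfg.taus)
        fits.append(fit)
        niches.append(
            species_niche(
                fit, s, field,
                tau=cfg.taus[-1],
                domain_lo=cfg.domain_lo,
                domain_hi=cfg.domain_hi,
            )
        )
    return niche_to_frame(fits, niches, tau=cfg.taus[-1]), fits
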