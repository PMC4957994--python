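"""Across-species statistics on a table of thermal-niche parameters.

Mirrors the usual macroecological battery for this kind of study: one-sample
and paired t-tests on regression coefficients and niche temperatures, a
repeated-measures linear-contrast test for the rise of pseudo-R² with the
quantile level, per-species tests of the mean distribution temperature against
the regional mean with a Holm (sequential Bonferroni) correction, Pearson
correlation between preferred and mean temperature, and a summary table of
parameter means/sds/ranges split by model significance.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quantile_fit import DELTA_AIC_CUTOFF
from .synthetic_data import SpeciesSurvey, TemperatureField

__all__ = [
    "MetaResult",
    "species_filter",
    "one_sample_t",
    "paired_t",
    "trend_contrast",
    "holm_flags",
    "per_species_tmean_tests",
    "pearson_corr",
    "summarize_table1",
    "meta_report",
]


@dataclass(frozen=True)
class MetaResult:
    """One across-species test: statistic, degrees of freedom, p-value."""

    name: str
    statistic: float
    df: float | tuple
    p_value: float
    n: int
    extra: dict = dc_field(default_factory=dict)


def species_filter(
    surveys: Iterable[SpeciesSurvey],
    min_cells: int = 50,
    min_max_freq: float = 0.05,
) -> list[SpeciesSurvey]:
    """Apply the atlas inclusion rules.

    A species is retained when it was detected in at least ``min_cells`` cells
    AND its maximum recorded frequency of occurrence is at least
    ``min_max_freq`` (with the default 0.05 = 3 detections out of 60 transects;
    only species strictly below the thresholds are excluded).
    """
    kept = []
    for s in surveys:
        if s.n_occupied_cells < min_cells:
            continue
        if s.detections.size == 0 or s.relative_abundance.max() < min_max_freq:
            continue
        kept.append(s)
    return kept


def one_sample_t(values: Sequence[float], mu0: float, name: str = "one-sample t") -> MetaResult:
    """Classical one-sample t-test of mean(values) against mu0, two-sided."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0.0:
        raise ValueError("zero variance: t statistic undefined")
    t = (x.mean() - mu0) / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    return MetaResult(name, float(t), df, float(p), n, {"mean": float(x.mean()), "mu0": mu0})


def paired_t(x: Sequence[float], y: Sequence[float], name: str = "paired t") -> MetaResult:
    """Paired t-test: one-sample t on the differences against 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    if d.size >= 2 and np.all(d == 0.0):
        # identical samples: no difference at all, t = 0 by convention
        return MetaResult(name, 0.0, d.size - 1, 1.0, d.size, {"mean": 0.0, "mu0": 0.0})
    return one_sample_t(d, 0.0, name=name)


def trend_contrast(
    matrix: np.ndarray,
    levels: Sequence[float],
    weights: Sequence[float] | None = None,
    name: str = "linear trend contrast",
) -> MetaResult:
    """Repeated-measures linear contrast across ordered quantile levels.

    ``matrix`` is species × levels (e.g. pseudo-R² at τ = 0.50…0.95).  Each
    species gets a contrast score s_i = Σ_j w_j·x_ij; with the default
    linear-in-level weights (levels minus their mean) the test of mean(s) = 0
    is the repeated-measures linear-trend F test, F(1, n−1) = t².
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] != len(levels):
        raise ValueError("matrix must be species × levels")
    if weights is None:
        w = np.asarray(levels, dtype=float)
        w = w - w.mean()
    else:
        w = np.asarray(weights, dtype=float)
        if abs(w.sum()) > 1e-12:
            raise ValueError("contrast weights must sum to 0")
    scores = m @ w
    n = scores.size
    # guard against pure floating-point residue when rows are constant
    scale = max(1.0, float(np.abs(m).max()) * float(np.abs(w).sum()))
    if scores.std(ddof=1) <= 1e-12 * scale:
        return MetaResult(name, 0.0, (1, n - 1), 1.0, n, {"degenerate": True})
    t_res = one_sample_t(scores, 0.0)
    f = t_res.statistic**2
    p = stats.f.sf(f, 1, n - 1)
    return MetaResult(name, float(f), (1, n - 1), float(p), n,
                      {"mean_score": t_res.extra["mean"]})


def holm_flags(p_values: Sequence[float], alpha: float = 0.05) -> np.ndarray:
    """Holm step-down (sequential Bonferroni) significance flags.

    Sort p ascending; the i-th smallest (1-based) is significant iff all
    smaller ones were and p_(i) ≤ α/(m − i + 1).
    """
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    flags = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if p[idx] <= alpha / (m - rank):
            flags[idx] = True
        else:
            break
    return flags


def _weighted_one_sample_t(t: np.ndarray, w: np.ndarray, mu0: float) -> tuple[float, int]:
    # frequency-weight heuristic: weights rescaled to sum to n (the cell count)
    n = t.size
    w = w * n / w.sum()
    mean = np.sum(w * t) / n
    var = np.sum(w * (t - mean) ** 2) / (n - 1)
    if var == 0.0:
        raise ValueError("zero weighted variance")
    return float((mean - mu0) / np.sqrt(var / n)), n - 1


def per_species_tmean_tests(
    surveys: Iterable[SpeciesSurvey],
    field: TemperatureField,
    regional_mean: float,
    alpha: float = 0.05,
    weighted: bool = False,
) -> MetaResult:
    """Per-species tests of occupied-cell temperatures against the regional mean.

    Default: unweighted one-sample t over the temperatures of occupied cells.
    ``weighted=True`` uses abundance-weighted mean/variance instead.  Holm's
    sequential Bonferroni is applied across species; species significantly
    colder/warmer than the regional mean are counted, and species with fewer
    than 2 occupied cells are skipped (counted separately).
    """
    order = {int(cid): i for i, cid in enumerate(field.cell_id)}
    ids, pvals, signs, skipped = [], [], [], []
    for s in surveys:
        occ = s.occupied
        if np.count_nonzero(occ) < 2:
            skipped.append(s.species_id)
            continue
        idx = np.array([order[int(c)] for c in s.cell_id])
        t_occ = field.temperature[idx][occ]
        try:
            if weighted:
                t_stat, df = _weighted_one_sample_t(
                    t_occ, s.relative_abundance[occ], regional_mean
                )
                p = 2.0 * stats.t.sf(abs(t_stat), df)
            else:
                res = one_sample_t(t_occ, regional_mean)
                t_stat, p = res.statistic, res.p_value
        except ValueError:
            skipped.append(s.species_id)
            continue
        ids.append(s.species_id)
        pvals.append(p)
        signs.append(np.sign(t_stat))
    flags = holm_flags(pvals, alpha=alpha) if pvals else np.zeros(0, bool)
    signs = np.asarray(signs)
    n_colder = int(np.sum(flags & (signs < 0)))
    n_warmer = int(np.sum(flags & (signs > 0)))
    n_total = len(ids) + len(skipped)
    return MetaResult(
        "per-species T_MEAN vs regional mean (Holm)",
        statistic=float(np.sum(flags)),
        df=float("nan"),
        p_value=float("nan"),
        n=n_total,
        extra={
            "n_significant": int(np.sum(flags)),
            "n_colder": n_colder,
            "n_warmer": n_warmer,
            "n_nonsignificant": len(ids) - int(np.sum(flags)),
            "skipped": skipped,
            "species": ids,
            "p_values": pvals,
            "flags": flags.tolist(),
            "alpha": alpha,
            "regional_mean": regional_mean,
        },
    )


def pearson_corr(x: Sequence[float], y: Sequence[float], name: str = "Pearson r") -> MetaResult:
    """Pearson correlation with the usual two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if x.std() == 0.0 or y.std() == 0.0:
        raise ValueError("zero variance: correlation undefined")
    n = x.size
    xc, yc = x - x.mean(), y - y.mean()
    r = float(np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2)))
    r = max(-1.0, min(1.0, r))
    df = n - 2
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = 2.0 * stats.t.sf(abs(t), df)
    return MetaResult(name, r, df, float(p), n)


# Columns summarized over significant species only (coefficients and the
# preferred temperature need a supported temperature model) vs. all species.
_SIGNIFICANT_COLS = ("b", "c", "t_pref")
_ALL_COLS = ("t_mean", "t_breadth")


def summarize_table1(
    species_table: pd.DataFrame,
    delta_aic_cutoff: float = DELTA_AIC_CUTOFF,
) -> pd.DataFrame:
    """Mean/sd/range summary of niche parameters across species.

    ``species_table`` has one row per species with columns ``b``, ``c``,
    ``delta_aic``, ``t_pref``, ``t_mean``, ``t_breadth``.  Rows for ``b``,
    ``c`` and ``t_pref`` are computed over species whose ΔAIC is at or below
    the cutoff (supported temperature models); ``t_mean`` and ``t_breadth``
    over all species.
    """
    if species_table.empty:
        raise ValueError("empty species table")
    sig = species_table[species_table["delta_aic"] <= delta_aic_cutoff]
    rows = []
    for col, frame in [(c, sig) for c in _SIGNIFICANT_COLS] + [
        (c, species_table) for c in _ALL_COLS
    ]:
        if col not in species_table.columns:
            continue
        v = frame[col].to_numpy(dtype=float)
        rows.append(
            {
                "parameter": col,
                "mean": v.mean() if v.size else float("nan"),
                "sd": v.std(ddof=1) if v.size > 1 else float("nan"),
                "min": v.min() if v.size else float("nan"),
                "max": v.max() if v.size else float("nan"),
                "n": v.size,
            }
        )
    return pd.DataFrame(rows)


def meta_report(
    species_table: pd.DataFrame,
    regional_mean: float,
    alpha: float = 0.05,
    delta_aic_cutoff: float = DELTA_AIC_CUTOFF,
    pseudo_r2_levels: Sequence[float] | None = None,
) -> dict:
    """Run the full across-species battery on a species-parameter table.

    Expects the per-species columns of :func:`summarize_table1`; if columns
    ``pseudo_r2_<tau>`` are present (for the taus in ``pseudo_r2_levels``), the
    repeated-measures linear contrast across quantile levels is included.
    Returns a dict with the summary table and a list of MetaResults.
    """
    sig = species_table[species_table["delta_aic"] <= delta_aic_cutoff]
    tests: list[MetaResult] = []
    if len(sig) >= 2:
        tests.append(one_sample_t(sig["b"], 0.0, name="mean b vs 0"))
        tests.append(one_sample_t(sig["c"], 0.0, name="mean c vs 0"))
        tests.append(paired_t(sig["b"].abs(), sig["c"].abs(), name="|b| vs |c| paired"))
        tests.append(
            one_sample_t(sig["t_pref"], regional_mean, name="T_PREF vs regional mean")
        )
        tests.append(paired_t(sig["t_pref"], sig["t_mean"], name="T_PREF vs T_MEAN paired"))
        if len(sig) >= 3:
            tests.append(pearson_corr(sig["t_pref"], sig["t_mean"],
                                      name="r(T_PREF, T_MEAN)"))
    if pseudo_r2_levels:
        cols = [f"pseudo_r2_{tau:g}" for tau in pseudo_r2_levels]
        if all(c in species_table.columns for c in cols):
            tests.append(
                trend_contrast(
                    species_table[cols].to_numpy(),
                    levels=list(pseudo_r2_levels),
                    name="pseudo-R2 rise across quantiles",
                )
            )
    counts = {
        "n_species": int(len(species_table)),
        "n_significant_models": int(len(sig)),
        "n_tpref_cold": int((sig["t_pref"] < 0.0).sum()) if len(sig) else 0,
        "n_tpref_warm": int((sig["t_pref"] > 5.0).sum()) if len(sig) else 0,
        "n_specialists": int((species_table["t_breadth"] < 0.33).sum()),
        "n_generalists": int((species_table["t_breadth"] > 0.90).sum()),
    }
    return {
        "table1": summarize_table1(species_table, delta_aic_cutoff),
        "tests": tests,
        "counts": counts,
        "alpha": alpha,
        "regional_mean": regional_mean,
    }
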