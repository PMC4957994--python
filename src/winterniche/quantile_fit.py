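"""Quadratic quantile regression of relative abundance on standardized temperature.

The model is ``A = a + b*z1 + c*z2`` where ``z1`` and ``z2`` are the cell
temperature T and its square T², each standardized to mean 0 and sd 1 so the
coefficients are comparable beta coefficients.  Fits minimize the pinball
(check) loss at a chosen percentile τ, solved exactly as a linear program —
at τ = 0.95 the fitted curve tracks the upper edge of the wedge-shaped
abundance–temperature point cloud, i.e. the temperature-limited maximum
potential abundance.

Model screening uses the Koenker–Machado pseudo-R² (1 − V_full/V_null) and an
AIC built from the asymmetric-Laplace likelihood with the scale parameter
profiled out::

    AIC = 2k + 2n·ln(V_τ / n)   (+ an additive constant that cancels in ΔAIC)

A model is treated as supported when ΔAIC = AIC_full − AIC_null ≤ −13.82,
i.e. an evidence ratio exp(−ΔAIC/2) ≥ 1,000.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

from .synthetic_data import SpeciesSurvey, TemperatureField

__all__ = [
    "StandardizedPredictors",
    "QuantileModel",
    "SpeciesFit",
    "standardize_predictors",
    "pinball_loss",
    "fit_quantile",
    "pseudo_r2",
    "aic_quantile",
    "delta_aic",
    "evidence_ratio",
    "delta_aic_for_evidence_ratio",
    "fit_species",
    "DEFAULT_TAUS",
    "DELTA_AIC_CUTOFF",
]

DEFAULT_TAUS = (0.50, 0.75, 0.90, 0.95)

#: ΔAIC at which the evidence ratio reaches 1,000 (= −2·ln 1000).
DELTA_AIC_CUTOFF = -13.82


@dataclass(frozen=True)
class StandardizedPredictors:
    """Standardized T and T² with the constants needed to map back to °C.

    ``z2`` is built from T² and then standardized — it is not ``z1**2``.
    The sd uses the sample (n−1) denominator by default (``ddof=1``).
    """

    z1: np.ndarray
    z2: np.ndarray
    mu1: float
    sigma1: float
    mu2: float
    sigma2: float
    ddof: int = 1


def standardize_predictors(
    temperatures: np.ndarray, ddof: int = 1
) -> StandardizedPredictors:
    """Standardize T and T² to mean 0, sd 1 (identifiability requires ≥ 3 distinct T)."""
    t = np.asarray(temperatures, dtype=float)
    if np.unique(t).size < 3:
        raise ValueError("need at least 3 distinct temperatures")
    t2 = t * t
    mu1, mu2 = t.mean(), t2.mean()
    sigma1 = t.std(ddof=ddof)
    sigma2 = t2.std(ddof=ddof)
    if sigma1 <= 0.0 or sigma2 <= 0.0:
        raise ValueError("zero variance in temperature predictors")
    return StandardizedPredictors(
        z1=(t - mu1) / sigma1,
        z2=(t2 - mu2) / sigma2,
        mu1=float(mu1),
        sigma1=float(sigma1),
        mu2=float(mu2),
        sigma2=float(sigma2),
        ddof=ddof,
    )


def pinball_loss(residuals: np.ndarray, tau: float) -> float:
    """Total check-function loss: Σ r·τ over r ≥ 0 plus Σ r·(τ − 1) over r < 0."""
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must lie strictly in (0, 1)")
    r = np.asarray(residuals, dtype=float)
    return float(np.sum(np.where(r >= 0.0, tau * r, (tau - 1.0) * r)))


@dataclass(frozen=True)
class QuantileModel:
    """A fitted quantile model at one percentile τ.

    ``a`` is the intercept; ``b`` and ``c`` are the beta coefficients of the
    standardized T and T² (both 0 for the intercept-only null, k = 1).
    ``pseudo_r2`` and ``delta_aic`` are populated relative to the null fitted
    on the same data at the same τ.
    """

    tau: float
    a: float
    b: float
    c: float
    loss: float
    n: int
    k: int
    aic: float
    predictors: StandardizedPredictors | None = None
    pseudo_r2: float | None = None
    delta_aic: float | None = None

    def predict_standardized(self, z1: np.ndarray, z2: np.ndarray) -> np.ndarray:
        return self.a + self.b * np.asarray(z1) + self.c * np.asarray(z2)

    def curve_celsius(self) -> tuple[float, float, float]:
        """Back-transform to original-scale coefficients (α, β, γ): Â = α + βT + γT².

        z1 = (T − μ1)/σ1 and z2 = (T² − μ2)/σ2, so
        Â = (a − bμ1/σ1 − cμ2/σ2) + (b/σ1)·T + (c/σ2)·T².
        """
        if self.predictors is None:
            raise ValueError("model carries no standardization constants")
        p = self.predictors
        gamma = self.c / p.sigma2
        beta = self.b / p.sigma1
        alpha = self.a - self.b * p.mu1 / p.sigma1 - self.c * p.mu2 / p.sigma2
        return alpha, beta, gamma

    def predict_celsius(self, temperature: np.ndarray) -> np.ndarray:
        t = np.asarray(temperature, dtype=float)
        alpha, beta, gamma = self.curve_celsius()
        return alpha + beta * t + gamma * t * t


def _aic_from_loss(loss: float, n: int, k: int) -> float:
    # Asymmetric-Laplace profile likelihood; V=0 means infinite likelihood.
    if loss <= 0.0:
        return float("-inf")
    return 2.0 * k + 2.0 * n * np.log(loss / n)


def fit_quantile(
    z1: np.ndarray,
    z2: np.ndarray,
    abundance: np.ndarray,
    tau: float,
    predictors: StandardizedPredictors | None = None,
    intercept_only: bool = False,
) -> QuantileModel:
    """Exact τ-quantile fit by linear programming.

    Splits each residual into positive/negative parts (u, v ≥ 0) and solves::

        min  τ·Σu + (1−τ)·Σv   s.t.   Xβ + u − v = y

    whose optimum is the global minimum of the (convex) pinball loss.  Any
    loss-minimizing vertex is accepted on degenerate instances.
    """
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must lie strictly in (0, 1)")
    y = np.asarray(abundance, dtype=float)
    n = y.size
    if intercept_only:
        X = np.ones((n, 1))
    else:
        X = np.column_stack([np.ones(n), np.asarray(z1, float), np.asarray(z2, float)])
        if n < 4:
            raise ValueError("need at least 4 observations for the 3-parameter model")
        if np.linalg.matrix_rank(X) < 3:
            raise ValueError("design matrix is rank deficient")
    p = X.shape[1]

    c_vec = np.concatenate([np.zeros(p), np.full(n, tau), np.full(n, 1.0 - tau)])
    A_eq = np.hstack([X, np.eye(n), -np.eye(n)])
    bounds = [(None, None)] * p + [(0.0, None)] * (2 * n)
    res = linprog(c_vec, A_eq=A_eq, b_eq=y, bounds=bounds, method="highs")
    if not res.success:  # loss bounded below by 0, so only numeric failure
        raise RuntimeError(f"quantile LP failed: {res.message}")

    beta = res.x[:p]
    loss = pinball_loss(y - X @ beta, tau)
    a = float(beta[0])
    b = float(beta[1]) if p == 3 else 0.0
    c = float(beta[2]) if p == 3 else 0.0
    return QuantileModel(
        tau=tau, a=a, b=b, c=c, loss=loss, n=n, k=p,
        aic=_aic_from_loss(loss, n, p), predictors=predictors,
    )


def pseudo_r2(full: QuantileModel, null: QuantileModel) -> float:
    """Koenker–Machado goodness of fit: 1 − V_full/V_null, in [0, 1]."""
    if full.tau != null.tau or full.n != null.n:
        raise ValueError("models must share tau and data")
    if null.loss <= 0.0:
        raise ValueError("degenerate response: null pinball loss is zero")
    value = 1.0 - full.loss / null.loss
    # nesting guarantees value >= 0 up to LP tolerance
    return float(min(1.0, max(0.0, value)))


def aic_quantile(model: QuantileModel) -> float:
    """Asymmetric-Laplace AIC (additive constant omitted; cancels in ΔAIC)."""
    return _aic_from_loss(model.loss, model.n, model.k)


def delta_aic(full: QuantileModel, null: QuantileModel) -> float:
    """AIC_full − AIC_null; ≤ −13.82 ⇒ evidence ratio ≥ 1,000 over the null."""
    if full.tau != null.tau or full.n != null.n:
        raise ValueError("models must share tau and data")
    return full.aic - null.aic


def evidence_ratio(d_aic: float) -> float:
    """How many times better the model is than the null: exp(−ΔAIC/2)."""
    return float(np.exp(-0.5 * d_aic))


def delta_aic_for_evidence_ratio(ratio: float) -> float:
    """ΔAIC at which the evidence ratio equals ``ratio`` (−2·ln ratio)."""
    if ratio <= 0:
        raise ValueError("evidence ratio must be positive")
    return float(-2.0 * np.log(ratio))


@dataclass(frozen=True)
class SpeciesFit:
    """Full + null models per τ for one species, keyed by quantile level."""

    species_id: str
    models: Mapping[float, QuantileModel]
    nulls: Mapping[float, QuantileModel]

    def __getitem__(self, tau: float) -> QuantileModel:
        return self.models[tau]

    def significant(self, cutoff: float = DELTA_AIC_CUTOFF, tau: float = 0.95) -> bool:
        return self.models[tau].delta_aic <= cutoff


def fit_species(
    survey: SpeciesSurvey,
    field: TemperatureField,
    taus: Sequence[float] = DEFAULT_TAUS,
    ddof: int = 1,
) -> SpeciesFit:
    """Fit full and null quantile models at every τ for one species.

    Cells are matched by id; standardization constants are computed once from
    the matched cell set and recorded on every model so downstream niche
    statistics can back-transform to °C.
    """
    order = {int(cid): i for i, cid in enumerate(field.cell_id)}
    try:
        idx = np.array([order[int(cid)] for cid in survey.cell_id])
    except KeyError as exc:
        raise ValueError(f"survey cell {exc} missing from temperature field") from exc
    if survey.cell_id.size < 4:
        raise ValueError("need at least 4 cells to fit the quadratic model")
    temps = field.temperature[idx]
    preds = standardize_predictors(temps, ddof=ddof)
    y = survey.relative_abundance

    models: dict[float, QuantileModel] = {}
    nulls: dict[float, QuantileModel] = {}
    for tau in taus:
        full = fit_quantile(preds.z1, preds.z2, y, tau, predictors=preds)
        null = fit_quantile(None, None, y, tau, predictors=preds, intercept_only=True)
        full = replace(
            full,
            pseudo_r2=pseudo_r2(full, null),
            delta_aic=delta_aic(full, null),
        )
        models[tau] = full
        nulls[tau] = null
    return SpeciesFit(species_id=survey.species_id, models=models, nulls=nulls)
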