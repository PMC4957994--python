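"""Thermal-niche statistics derived from the 95%-quantile model and the survey.

Three quantities summarize a species' use of the thermal space:

* ``T_PREF`` — environmental preferred temperature: the °C at which the fitted
  upper-quantile abundance curve is maximal within the study's thermal span,
  found by setting dÂ/dT = 0 (clipped to the span when the stationary point
  falls outside it or the curve is monotone/convex).
* ``T_MEAN`` — mean distribution temperature: abundance-weighted average of
  cell temperatures over the cells where the species was detected.
* ``T_BREADTH`` — thermal breadth: area under the fitted curve over the span,
  after normalizing its maximum to 1 and dividing by the span width; 1 means a
  thermal generalist (flat response), small values a thermal specialist.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .quantile_fit import QuantileModel, SpeciesFit
from .synthetic_data import SpeciesSurvey, TemperatureField

__all__ = [
    "NicheParams",
    "preferred_temperature",
    "mean_distribution_temperature",
    "thermal_breadth",
    "classify_species",
    "species_niche",
    "DOMAIN",
    "BREADTH_SPECIALIST",
    "BREADTH_GENERALIST",
    "PREF_COLD",
    "PREF_WARM",
]

#: Default integration/search domain (°C): the study region's thermal span.
DOMAIN = (-2.0, 10.0)

BREADTH_SPECIALIST = 0.33  # T_BREADTH strictly below -> thermal specialist
BREADTH_GENERALIST = 0.90  # T_BREADTH strictly above -> thermal generalist
PREF_COLD = 0.0  # T_PREF strictly below -> cold-preferring
PREF_WARM = 5.0  # T_PREF strictly above -> warm-preferring


@dataclass(frozen=True)
class NicheParams:
    species_id: str
    t_pref: float
    t_pref_flag: str  # 'interior' | 'boundary' | 'flat'
    t_mean: float
    t_breadth: float
    class_thermal: str = ""  # specialist | intermediate | generalist
    class_pref: str = ""  # cold | mid | warm

    @property
    def t_pref_boundary_flag(self) -> bool:
        return self.t_pref_flag != "interior"


def preferred_temperature(
    model: QuantileModel,
    domain_lo: float = DOMAIN[0],
    domain_hi: float = DOMAIN[1],
) -> tuple[float, str]:
    """Temperature (°C) maximizing the fitted curve over [domain_lo, domain_hi].

    Solving dÂ/dT = 0 for the back-transformed quadratic gives the stationary
    point T* = −(b·σ₂)/(2·c·σ₁).  When the parabola is concave (c < 0) and T*
    lies inside the domain, T* is returned with flag ``'interior'``; a convex
    or monotone curve, or an exterior vertex, yields the best endpoint with
    flag ``'boundary'``.  A flat curve (b = c = 0) has no preference: the
    domain midpoint is returned with flag ``'flat'``.
    """
    if model.predictors is None:
        raise ValueError("model carries no standardization constants")
    if not domain_lo < domain_hi:
        raise ValueError("empty temperature domain")
    p = model.predictors
    if model.b == 0.0 and model.c == 0.0:
        return 0.5 * (domain_lo + domain_hi), "flat"
    if model.c != 0.0:
        t_star = -(model.b * p.sigma2) / (2.0 * model.c * p.sigma1)
        if model.c < 0.0 and domain_lo <= t_star <= domain_hi:
            return float(t_star), "interior"
    # convex, monotone, or exterior vertex: the maximum sits at an endpoint
    lo_val, hi_val = model.predict_celsius(np.array([domain_lo, domain_hi]))
    return (float(domain_lo), "boundary") if lo_val >= hi_val else (
        float(domain_hi),
        "boundary",
    )


def mean_distribution_temperature(
    survey: SpeciesSurvey, field: TemperatureField
) -> float:
    """Abundance-weighted mean temperature over occupied cells.

    Weights are relative abundances (detections/n_transects); any positive
    rescaling — e.g. raw counts — gives the identical result.
    """
    order = {int(cid): i for i, cid in enumerate(field.cell_id)}
    idx = np.array([order[int(cid)] for cid in survey.cell_id])
    occ = survey.occupied
    if not np.any(occ):
        raise ValueError(f"species {survey.species_id!r} occupies no cells")
    w = survey.relative_abundance[occ]
    t = field.temperature[idx][occ]
    return float(np.sum(w * t) / np.sum(w))


def _clipped_quadratic_integral(
    alpha: float, beta: float, gamma: float, lo: float, hi: float
) -> float:
    """∫ max(α + βT + γT², 0) dT over [lo, hi], exactly (piecewise polynomial)."""

    def antideriv(t: float) -> float:
        return alpha * t + beta * t * t / 2.0 + gamma * t**3 / 3.0

    def q(t: float) -> float:
        return alpha + beta * t + gamma * t * t

    # breakpoints: real roots inside (lo, hi)
    if gamma != 0.0:
        disc = beta * beta - 4.0 * gamma * alpha
        roots = []
        if disc > 0.0:
            sq = np.sqrt(disc)
            roots = sorted([(-beta - sq) / (2 * gamma), (-beta + sq) / (2 * gamma)])
    elif beta != 0.0:
        roots = [-alpha / beta]
    else:
        return max(alpha, 0.0) * (hi - lo)
    pts = [lo] + [r for r in roots if lo < r < hi] + [hi]
    total = 0.0
    for a_pt, b_pt in zip(pts[:-1], pts[1:]):
        if q(0.5 * (a_pt + b_pt)) > 0.0:
            total += antideriv(b_pt) - antideriv(a_pt)
    return total


def thermal_breadth(
    model: QuantileModel,
    domain_lo: float = DOMAIN[0],
    domain_hi: float = DOMAIN[1],
    clip_negative: bool = True,
) -> float:
    """Normalized area under the fitted curve over [domain_lo, domain_hi].

    The curve's maximum on the domain is standardized to 1 and the area is
    divided by the domain width, so the index lies in (0, 1]: a flat curve
    scores 1, a narrow peak scores near 0.  Negative predicted abundances are
    clipped at zero before integrating by default (abundance cannot be
    negative); ``clip_negative=False`` integrates the raw quadratic instead,
    for sensitivity checks.
    """
    if not domain_lo < domain_hi:
        raise ValueError("empty temperature domain")
    alpha, beta, gamma = model.curve_celsius()

    candidates = [domain_lo, domain_hi]
    if gamma != 0.0:
        t_star = -beta / (2.0 * gamma)
        if domain_lo < t_star < domain_hi:
            candidates.append(t_star)
    a_max = max(alpha + beta * t + gamma * t * t for t in candidates)
    if a_max <= 0.0:
        raise ValueError("fitted curve attains no positive abundance on the domain")

    if clip_negative:
        area = _clipped_quadratic_integral(alpha, beta, gamma, domain_lo, domain_hi)
    else:

        def antideriv(t: float) -> float:
            return alpha * t + beta * t * t / 2.0 + gamma * t**3 / 3.0

        area = antideriv(domain_hi) - antideriv(domain_lo)
    return float(area / (a_max * (domain_hi - domain_lo)))


def classify_species(
    params: NicheParams,
    breadth_specialist: float = BREADTH_SPECIALIST,
    breadth_generalist: float = BREADTH_GENERALIST,
    pref_cold: float = PREF_COLD,
    pref_warm: float = PREF_WARM,
) -> NicheParams:
    """Attach threshold labels; boundary values go to the non-extreme class."""
    if params.t_breadth < breadth_specialist:
        thermal = "specialist"
    elif params.t_breadth > breadth_generalist:
        thermal = "generalist"
    else:
        thermal = "intermediate"
    if params.t_pref < pref_cold:
        pref = "cold"
    elif params.t_pref > pref_warm:
        pref = "warm"
    else:
        pref = "mid"
    return replace(params, class_thermal=thermal, class_pref=pref)


def species_niche(
    fit: SpeciesFit,
    survey: SpeciesSurvey,
    field: TemperatureField,
    tau: float = 0.95,
    domain_lo: float = DOMAIN[0],
    domain_hi: float = DOMAIN[1],
    clip_negative: bool = True,
) -> NicheParams:
    """All three niche statistics for one species, classified."""
    model = fit.models[tau]
    t_pref, flag = preferred_temperature(model, domain_lo, domain_hi)
    params = NicheParams(
        species_id=fit.species_id,
        t_pref=t_pref,
        t_pref_flag=flag,
        t_mean=mean_distribution_temperature(survey, field),
        t_breadth=thermal_breadth(model, domain_lo, domain_hi, clip_negative),
    )
    return classify_species(params)
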