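"""Synthetic wedge-shaped abundance surveys with known thermal-niche ground truth.

The generator emulates a national winter-bird atlas: a grid of survey cells,
each with a mean minimum winter temperature, and per-cell detection counts for
each species out of a fixed number of 15-min transects (nominally 60).  The
species' *potential* relative abundance is a quadratic function of temperature
(the upper edge of the wedge); realized abundance in each cell is the potential
multiplied by a random suppression factor ``U in [0, 1]`` that stands in for
all unmeasured limiting factors (habitat, food, ...).  Detections are then
binomial.  The result is the wedge-shaped abundance-temperature point cloud
whose upper boundary a 95%-quantile regression is meant to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

__all__ = [
    "TemperatureField",
    "SuppressionLaw",
    "SpeciesTruth",
    "SpeciesSurvey",
    "SimulationConfig",
    "generate_temperature_field",
    "generate_species_survey",
    "generate_community",
    "ARCHETYPES",
]


class DegenerateSpeciesError(ValueError):
    """Raised when a species' potential-abundance curve is identically zero."""


class IdentifiabilityError(ValueError):
    """Raised when a temperature field cannot support a quadratic fit."""


@dataclass(frozen=True)
class TemperatureField:
    """Per-cell mean minimum winter temperature (°C)."""

    cell_id: np.ndarray
    temperature: np.ndarray

    def __post_init__(self) -> None:
        cid = np.asarray(self.cell_id, dtype=np.int64)
        temp = np.asarray(self.temperature, dtype=float)
        if cid.shape != temp.shape or cid.ndim != 1:
            raise ValueError("cell_id and temperature must be 1-D and congruent")
        if not np.all(np.isfinite(temp)):
            raise ValueError("temperatures must be finite")
        if np.unique(temp).size < 3:
            raise IdentifiabilityError(
                "need at least 3 distinct temperatures for a quadratic fit"
            )
        if np.unique(cid).size != cid.size:
            raise ValueError("cell ids must be unique")
        object.__setattr__(self, "cell_id", cid)
        object.__setattr__(self, "temperature", temp)

    @property
    def n_cells(self) -> int:
        return int(self.cell_id.size)


@dataclass(frozen=True)
class SuppressionLaw:
    """Distribution of the multiplicative thinning factor ``U in [0, 1]``.

    ``kind='uniform'`` draws U ~ Uniform(lo, hi); ``kind='constant'`` uses the
    fixed ``value`` (value 1 disables suppression — "oracle mode").
    """

    kind: str = "uniform"
    lo: float = 0.0
    hi: float = 1.0
    value: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "constant"):
            raise ValueError(f"unknown suppression law {self.kind!r}")
        if self.kind == "uniform" and not (0.0 <= self.lo < self.hi <= 1.0):
            raise ValueError("uniform suppression requires 0 <= lo < hi <= 1")
        if self.kind == "constant" and not (0.0 < self.value <= 1.0):
            raise ValueError("constant suppression factor must be in (0, 1]")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "constant":
            return np.full(n, self.value)
        return rng.uniform(self.lo, self.hi, size=n)

    @property
    def mean(self) -> float:
        return self.value if self.kind == "constant" else 0.5 * (self.lo + self.hi)


@dataclass(frozen=True)
class SpeciesTruth:
    """Ground-truth potential-abundance curve on the original °C scale.

    The potential relative abundance at temperature T is
    ``clip(a0 + b0*T + c0*T**2, 0, 1)`` — probability units, so the curve must
    be positive somewhere on the temperature range of interest.
    """

    species_id: str
    a0: float
    b0: float
    c0: float
    suppression: SuppressionLaw = dc_field(default_factory=SuppressionLaw)
    n_transects: int = 60
    archetype: str = ""

    def potential(self, temperature: np.ndarray) -> np.ndarray:
        t = np.asarray(temperature, dtype=float)
        return np.clip(self.a0 + self.b0 * t + self.c0 * t * t, 0.0, 1.0)

    def true_vertex(self) -> float | None:
        """Temperature of the unclipped parabola's stationary point, if any."""
        if self.c0 == 0.0:
            return None
        return -self.b0 / (2.0 * self.c0)


@dataclass(frozen=True)
class SpeciesSurvey:
    """Detection counts per cell for one species."""

    species_id: str
    cell_id: np.ndarray
    detections: np.ndarray
    n_transects: int = 60

    def __post_init__(self) -> None:
        cid = np.asarray(self.cell_id, dtype=np.int64)
        det = np.asarray(self.detections)
        if not np.issubdtype(det.dtype, np.integer):
            if not np.allclose(det, np.round(det)):
                raise ValueError("detections must be integral")
            det = np.round(det).astype(np.int64)
        det = det.astype(np.int64)
        if cid.shape != det.shape or cid.ndim != 1:
            raise ValueError("cell_id and detections must be 1-D and congruent")
        if self.n_transects < 1:
            raise ValueError("n_transects must be positive")
        if np.any(det < 0) or np.any(det > self.n_transects):
            raise ValueError("detections must lie in [0, n_transects]")
        object.__setattr__(self, "cell_id", cid)
        object.__setattr__(self, "detections", det)

    @property
    def relative_abundance(self) -> np.ndarray:
        """Frequency of occurrence: detections / n_transects, in [0, 1]."""
        return self.detections / float(self.n_transects)

    @property
    def occupied(self) -> np.ndarray:
        return self.detections >= 1

    @property
    def n_occupied_cells(self) -> int:
        return int(np.count_nonzero(self.occupied))


# Archetype name -> sampler of (vertex °C, peak height, half-width °C) ranges.
# Vertices may fall outside the survey's thermal span (cold species clipped at
# the domain edge are part of the phenomenon being modelled).
ARCHETYPES = {
    "warm": {"vertex": (6.0, 9.5), "height": (0.25, 0.85), "halfwidth": (5.0, 11.0)},
    "cold": {"vertex": (-4.0, 0.0), "height": (0.25, 0.85), "halfwidth": (5.0, 11.0)},
    "mid": {"vertex": (1.0, 5.0), "height": (0.25, 0.85), "halfwidth": (5.0, 11.0)},
    "flat": {"height": (0.15, 0.7)},
}

_DEFAULT_MIX = {"warm": 0.39, "cold": 0.23, "mid": 0.28, "flat": 0.10}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-scale defaults: 1,689 cells spanning [−2, 10] °C, 60 transects."""

    n_cells: int = 1689
    temp_lo: float = -2.0
    temp_hi: float = 10.0
    n_species: int = 103
    n_transects: int = 60
    archetype_mix: dict = dc_field(default_factory=lambda: dict(_DEFAULT_MIX))
    suppression: SuppressionLaw = dc_field(default_factory=SuppressionLaw)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 3:
            raise IdentifiabilityError("n_cells must be >= 3")
        if not self.temp_lo < self.temp_hi:
            raise ValueError("temp_lo must be below temp_hi")
        if self.n_species < 1:
            raise ValueError("n_species must be positive")
        total = sum(self.archetype_mix.values())
        if total <= 0 or any(v < 0 for v in self.archetype_mix.values()):
            raise ValueError("archetype mix must be nonnegative with positive sum")
        unknown = set(self.archetype_mix) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetypes: {sorted(unknown)}")


def generate_temperature_field(
    n_cells: int,
    range_lo: float = -2.0,
    range_hi: float = 10.0,
    seed: int | np.random.SeedSequence = 0,
) -> TemperatureField:
    """Draw ``n_cells`` cell temperatures uniformly over [range_lo, range_hi]."""
    if n_cells < 3:
        raise IdentifiabilityError("n_cells must be >= 3 for a quadratic fit")
    if not range_lo < range_hi:
        raise ValueError("range_lo must be below range_hi")
    rng = np.random.default_rng(seed)
    temps = rng.uniform(range_lo, range_hi, size=n_cells)
    return TemperatureField(cell_id=np.arange(n_cells), temperature=temps)


def generate_species_survey(
    field: TemperatureField,
    truth: SpeciesTruth,
    seed: int | np.random.SeedSequence = 0,
) -> SpeciesSurvey:
    """Simulate one species' detections over a temperature field.

    Per cell: ``p = U * clip(a0 + b0*T + c0*T^2, 0, 1)`` with U drawn from the
    truth's suppression law, then ``detections ~ Binomial(n_transects, p)``.
    """
    potential = truth.potential(field.temperature)
    if not np.any(potential > 0.0):
        raise DegenerateSpeciesError(
            f"species {truth.species_id!r}: potential curve is identically 0 "
            "on the temperature range"
        )
    rng = np.random.default_rng(seed)
    u = truth.suppression.sample(rng, field.n_cells)
    p = u * potential
    detections = rng.binomial(truth.n_transects, p)
    return SpeciesSurvey(
        species_id=truth.species_id,
        cell_id=field.cell_id.copy(),
        detections=detections,
        n_transects=truth.n_transects,
    )


def _sample_truth(
    species_id: str,
    archetype: str,
    rng: np.random.Generator,
    suppression: SuppressionLaw,
    n_transects: int,
) -> SpeciesTruth:
    spec = ARCHETYPES[archetype]
    h = rng.uniform(*spec["height"])
    if archetype == "flat":
        return SpeciesTruth(
            species_id, a0=h, b0=0.0, c0=0.0,
            suppression=suppression, n_transects=n_transects, archetype=archetype,
        )
    tv = rng.uniform(*spec["vertex"])
    w = rng.uniform(*spec["halfwidth"])
    # peak-height parabola h * (1 - ((T - tv)/w)^2), expanded to a0+b0 T+c0 T^2
    c0 = -h / w**2
    b0 = 2.0 * h * tv / w**2
    a0 = h * (1.0 - tv**2 / w**2)
    return SpeciesTruth(
        species_id, a0=a0, b0=b0, c0=c0,
        suppression=suppression, n_transects=n_transects, archetype=archetype,
    )


def generate_community(
    config: SimulationConfig,
) -> tuple[TemperatureField, list[tuple[SpeciesTruth, SpeciesSurvey]]]:
    """Generate a temperature field plus ``n_species`` surveys with known truth.

    Species archetypes (warm-, cold-, mid-preferring and temperature-flat) are
    allocated in proportion to ``config.archetype_mix``, guaranteeing at least
    one species of every archetype with positive weight.  Fully deterministic
    under ``config.seed``.
    """
    root = np.random.SeedSequence(config.seed)
    field_seed, truth_seed, *survey_seeds = root.spawn(2 + config.n_species)
    field = generate_temperature_field(
        config.n_cells, config.temp_lo, config.temp_hi, seed=field_seed
    )

    names = [a for a, w in sorted(config.archetype_mix.items()) if w > 0]
    weights = np.array([config.archetype_mix[a] for a in names], dtype=float)
    weights /= weights.sum()
    counts = np.floor(weights * config.n_species).astype(int)
    counts = np.maximum(counts, 1)
    while counts.sum() > config.n_species:
        counts[np.argmax(counts)] -= 1
    while counts.sum() < config.n_species:
        counts[np.argmin(counts / weights)] += 1
    roster = [a for a, k in zip(names, counts) for _ in range(k)]

    truth_rng = np.random.default_rng(truth_seed)
    out = []
    for i, (archetype, sseed) in enumerate(zip(roster, survey_seeds)):
        truth = _sample_truth(
            f"sp{i:03d}_{archetype}", archetype, truth_rng,
            config.suppression, config.n_transects,
        )
        survey = generate_species_survey(field, truth, seed=sseed)
        out.append((truth, survey))
    return field, out
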