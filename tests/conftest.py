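import numpy as np
import pytest

from winterniche import (
    SpeciesTruth,
    SuppressionLaw,
    generate_species_survey,
    generate_temperature_field,
)


def peak_curve(vertex: float, height: float, halfwidth: float) -> tuple[float, float, float]:
    """Original-scale coefficients of height * (1 - ((T - vertex)/halfwidth)^2)."""
    c0 = -height / halfwidth**2
    b0 = 2.0 * height * vertex / halfwidth**2
    a0 = height * (1.0 - vertex**2 / halfwidth**2)
    return a0, b0, c0


@pytest.fixture(scope="session")
def small_field():
    return generate_temperature_field(200, -2.0, 10.0, seed=11)


@pytest.fixture(scope="session")
def warm_truth():
    a0, b0, c0 = peak_curve(vertex=6.0, height=0.6, halfwidth=7.0)
    return SpeciesTruth("warm_sp", a0=a0, b0=b0, c0=c0)


@pytest.fixture(scope="session")
def warm_survey(small_field, warm_truth):
    return generate_species_survey(small_field, warm_truth, seed=21)


@pytest.fixture(scope="session")
def oracle_truth():
    """No suppression, huge transect count: abundance ≈ the potential curve."""
    a0, b0, c0 = peak_curve(vertex=4.0, height=0.8, halfwidth=8.0)
    return SpeciesTruth(
        "oracle_sp", a0=a0, b0=b0, c0=c0,
        suppression=SuppressionLaw(kind="constant", value=1.0),
        n_transects=10**6,
    )
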