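import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lodsim import (
    IncidenceCurve,
    PopulationPRS,
    build_architecture,
    build_population,
    fixtures,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def life_table():
    return fixtures.fixture_life_table()


@pytest.fixture(scope="session")
def arch400():
    return build_architecture("common_low", 400)


@pytest.fixture(scope="session")
def pop400(arch400):
    return build_population(arch400)


@pytest.fixture(scope="session")
def cancer_curve():
    return fixtures.fixture_incidence("cancer_like")


@pytest.fixture(scope="session")
def low_risk_cancer_curve():
    """Logistic cancer curve deep in the proportional-risk regime.

    Plateau 0.002/yr gives a baseline lifetime risk of ~2.6%, comparable
    to the lowest-risk cancers, where lifetime risk scales linearly with
    the hazard ratio.
    """
    return IncidenceCurve(
        form="logistic", parameters={"a": 0.002, "k": 0.25, "t50": 70.0}, onset_age=40
    )


@pytest.fixture(scope="session")
def homogeneous_pop():
    """All risk scores exactly 1: the no-heterogeneity limit."""
    n = 101
    return PopulationPRS(
        values=np.ones(n),
        weights=np.full(n, 1.0 / n),
        normalization_reference=1.0,
        normalization_key="homogeneous",
    )


@pytest.fixture(scope="session")
def two_point_pop():
    """Equal-mass risk scores {1.5, 0.5} for hand-checkable recursions."""
    return PopulationPRS(
        values=np.array([1.5, 0.5]),
        weights=np.array([0.5, 0.5]),
        normalization_reference=1.0,
        normalization_key="two-point",
    )
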