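import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from snpassoc import STUDY_PANEL, SimulationConfig, simulate_cohort
from snpassoc import studydata


@pytest.fixture(scope="session")
def panel():
    return STUDY_PANEL


@pytest.fixture(scope="session")
def study_counts():
    return studydata.GENOTYPE_COUNTS


@pytest.fixture(scope="session")
def small_cohort():
    """60 cases / 90 controls with the default study-like generator."""
    cohort, truth = simulate_cohort(SimulationConfig(n_cases=60, n_controls=90, seed=11))
    return cohort, truth


@pytest.fixture(scope="session")
def medium_cohort():
    """500 cases / 500 controls, null effects, for recount-style oracles."""
    cfg = SimulationConfig(n_cases=250, n_controls=250, effect_model={}, seed=23)
    cohort, truth = simulate_cohort(cfg)
    return cohort, truth
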