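import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from akirank.config import CohortConfig  # noqa: E402


@pytest.fixture(scope="session")
def default_config() -> CohortConfig:
    return CohortConfig(n_per_arm=50, seed=11)


@pytest.fixture(scope="session")
def small_cohort(default_config):
    from akirank.cohort import generate_cohort

    return generate_cohort(default_config)


@pytest.fixture(scope="session")
def large_cohort():
    """Calibration-scale cohort (500/arm) shared across distributional tests."""
    from akirank.cohort import generate_cohort

    return generate_cohort(CohortConfig(n_per_arm=500, seed=7))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
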