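import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")

from femoffset import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small noisy cohort with ground truth, shared across tests."""
    config = CohortConfig(n_specimens=3, n_rater_rounds=2, seed=42)
    sets, truth = simulate_cohort(config)
    return config, sets, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
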