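import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A small two-group cohort with the default condition effects."""
    from dualsource.synthetic_data import CohortSpec, generate_cohort

    spec = CohortSpec(n_per_group=6, seed=42)
    trials, truth = generate_cohort(spec)
    return trials, truth
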