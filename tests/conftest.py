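import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=list(HealthCheck),
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def demo_cohort():
    """98-sample demo cohort with age, bmi and sex."""
    from batchbalance import simulate_basic_cohort

    return simulate_basic_cohort(98, seed=1)
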