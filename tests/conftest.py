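import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_cohort():
    """A small synthetic cohort shared across tests (seeded, moderate effect)."""
    from hlahom import CohortConfig, simulate_cohort

    cfg = CohortConfig(n_individuals=500, seed=11)
    typing, antibodies, panel = simulate_cohort(cfg)
    return cfg, typing, antibodies, panel
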