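import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def worked_fixture():
    """Hand-built 17-person cohort covering every rule branch."""
    from ddci.simulate import make_worked_fixture

    return make_worked_fixture()


@pytest.fixture(scope="session")
def small_cohort():
    """Simulated 4000-person cohort shared across tests (seed 123)."""
    from ddci.simulate import SimulationConfig, simulate_cohort

    return simulate_cohort(SimulationConfig(n_persons=4000, seed=123))
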