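import pytest

from snowcam.synthetic import SimulationConfig, simulate_network


@pytest.fixture(scope="session")
def small_network():
    """8-site, 1-year network used by unit tests that need a full bundle."""
    return simulate_network(SimulationConfig(n_sites=8, years=1, seed=5))


@pytest.fixture(scope="session")
def default_network():
    """The default study-scale network (133 sites, 2 years, seed 42)."""
    return simulate_network(SimulationConfig())
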