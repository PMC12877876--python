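import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_sim_tree():
    """One 60-cell completely sampled simulated tree, fixed seed."""
    from divtree import SimConfig, simulate_tree

    return simulate_tree(SimConfig(q=0.5, mu=1.0, rho=1.0, stop_size=60, seed=7))


@pytest.fixture(scope="session")
def medium_sim_tree():
    """A 150-cell completely sampled tree for heavier numerical checks."""
    from divtree import SimConfig, simulate_tree

    return simulate_tree(SimConfig(q=0.75, mu=1.0, rho=1.0, stop_size=150, seed=11))
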