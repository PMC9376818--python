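import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_dataset():
    """The default study conditions: 1000 genes, depth 200, background 5/kb."""
    from embryoz.simulate import SimulationConfig, simulate_dataset

    return simulate_dataset(SimulationConfig(n_genes=1000, seed=7))


@pytest.fixture(scope="session")
def small_dataset():
    from embryoz.simulate import SimulationConfig, simulate_dataset

    return simulate_dataset(SimulationConfig(n_genes=60, seed=3), with_sequence=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
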