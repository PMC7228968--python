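import numpy as np
import pytest

from leukotype.simulate import SimulationConfig, simulate_healthy_trajectory


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_genes=300, n_rp_genes=20, n_mito_genes=5,
        n_cells_per_population=(100, 100, 100), seed=42)


@pytest.fixture(scope="session")
def small_healthy(small_config):
    return simulate_healthy_trajectory(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
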