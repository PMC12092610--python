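import numpy as np
import pytest

from scgot.config import SimulationConfig
from scgot.simulate import simulate_cohort


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Two patients x 300 cells: enough structure for every stage, fast."""
    return SimulationConfig(n_patients=2, n_cells_per_patient=300, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
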