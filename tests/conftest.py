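import numpy as np
import pytest

from batdx import SimulationConfig, simulate_cohort
from batdx.types import DEFAULT_CONCENTRATIONS


@pytest.fixture(scope="session")
def concentrations():
    return np.asarray(DEFAULT_CONCENTRATIONS)


@pytest.fixture(scope="session")
def small_config():
    """Reduced cohort with the default group blocks — fast enough to fit
    every series inside the unit-test budget."""
    return SimulationConfig(n_controls=8, n_oas=5, n_urt_ang=5, n_anaph=5,
                            n_group_b=6, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def noise_free_cohort():
    cfg = SimulationConfig(n_controls=4, n_oas=3, n_urt_ang=3, n_anaph=3,
                           n_group_b=4, seed=11, noise_free=True)
    return cfg, simulate_cohort(cfg)
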