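import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from chillscape import SyntheticParams, make_grid, simulate_daily_obs


@pytest.fixture(scope="session")
def small_grid():
    return make_grid(9, seed=11)


@pytest.fixture(scope="session")
def quiet_params():
    """Noise-free parameters: the generator equals its closed-form mean."""
    return SyntheticParams(noise_sd=0.0, ar1_rho=0.0, seed=3)


@pytest.fixture(scope="session")
def obs_small(small_grid):
    """Nine cells, 1995-2000, defaults with a fixed seed."""
    return simulate_daily_obs(small_grid, 1995, 2000, SyntheticParams(seed=5))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
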