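import numpy as np
import pytest

from habtrack.grid import SpatialGrid
from habtrack.synthetic import default_colonies, generate_environment


@pytest.fixture(scope="session")
def colonies():
    return default_colonies()


@pytest.fixture(scope="session")
def env_small(colonies):
    """8-week environment on the default 100 km polar grid."""
    return generate_environment(seed=7, weeks=8, colonies=colonies)


@pytest.fixture(scope="session")
def small_grid():
    """Small local grid for fast KDE/overlap tests (40x40 cells of 50 km)."""
    return SpatialGrid(cell_km=50.0, half_extent_km=1000.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
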