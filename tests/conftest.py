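import numpy as np
import pytest

from landcarbon.grid_core import DEFAULT_CLASS_TABLE, LandUseGrid
from landcarbon.synthetic_data import make_benchmark


def grid_from_codes(codes, cell_size=30.0, nodata=-9999):
    return LandUseGrid(np.asarray(codes, dtype=np.int32), dict(DEFAULT_CLASS_TABLE), cell_size, nodata)


@pytest.fixture
def random_grid():
    """50×50 six-class random land-use grid, 30 m cells."""
    rng = np.random.default_rng(42)
    return grid_from_codes(rng.integers(1, 7, size=(50, 50)))


@pytest.fixture(scope="session")
def benchmark():
    """Study-shaped 128×128 benchmark bundle (shared, read-only)."""
    return make_benchmark(7, (128, 128))
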