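import numpy as np
import pytest

from trapliner.landscape import FOREST, OTHER_MATRIX, PASTURE, LandCoverMap, StreamNetwork


@pytest.fixture
def all_forest_map():
    return LandCoverMap(grid=np.full((40, 40), FOREST), resolution=5.0)


@pytest.fixture
def half_forest_map():
    """Left half forest, right half pasture, 100 x 100 cells at 5 m."""
    g = np.full((100, 100), PASTURE)
    g[:, :50] = FOREST
    return LandCoverMap(grid=g, resolution=5.0)


@pytest.fixture
def striped_map():
    """Alternating 10-m forest / other-matrix vertical bands."""
    g = np.full((80, 80), FOREST)
    for c0 in range(2, 80, 4):
        g[:, c0 : c0 + 2] = OTHER_MATRIX
    return LandCoverMap(grid=g, resolution=5.0)


@pytest.fixture
def random_map():
    rng = np.random.default_rng(42)
    g = rng.choice([FOREST, PASTURE, OTHER_MATRIX], size=(20, 20), p=[0.45, 0.45, 0.10])
    return LandCoverMap(grid=g, resolution=5.0)


@pytest.fixture
def simple_streams():
    return StreamNetwork((np.array([[0.0, 0.0], [10.0, 0.0]]),))
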