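import numpy as np
import pytest

import carbonscape as cs


@pytest.fixture(scope="session")
def density():
    return cs.guizhou_density_table()


@pytest.fixture(scope="session")
def small_fixture():
    """Two-epoch 80x80 synthetic landscape with drivers and known flows."""
    return cs.two_epoch_fixture(shape=(80, 80), seed=11)


@pytest.fixture()
def toy_map():
    """3x3 map with one nodata cell, cell_area 1 km²."""
    grid = np.array([[1, 1, 2], [2, 3, 0], [1, 2, 3]])
    return cs.ClassMap(grid=grid)
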