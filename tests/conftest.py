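import numpy as np
import pytest

from mapseg.map_io import BinaryMask, MapGrid, ProbabilityGrid, UnitCell


@pytest.fixture
def rng():
    return np.random.default_rng(20240627)


@pytest.fixture
def cubic_cell():
    return UnitCell(24.0, 24.0, 24.0)


@pytest.fixture
def random_prob_grid(rng, cubic_cell):
    """Random 24^3 probability grid used by the brute-force oracle tests."""
    return ProbabilityGrid(rng.random((24, 24, 24)), cubic_cell)


def make_grid(values, cell_edge=24.0):
    values = np.asarray(values)
    return MapGrid(values, UnitCell(cell_edge, cell_edge, cell_edge))


def make_mask(values, cell_edge=24.0):
    return BinaryMask(np.asarray(values), UnitCell(cell_edge, cell_edge, cell_edge))
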