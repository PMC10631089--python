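import numpy as np
import pytest

from mnscan import CaseTable, RegionMap, build_region_map, make_grid_geography


@pytest.fixture
def square4() -> RegionMap:
    """Four regions on the corners of a unit square."""
    return build_region_map([("A", 0, 0), ("B", 1, 0), ("C", 0, 1), ("D", 1, 1)])


@pytest.fixture
def grid3() -> RegionMap:
    """3x3 lattice with rook adjacency."""
    return make_grid_geography(3)


@pytest.fixture
def grid8() -> RegionMap:
    """8x8 lattice, the synthetic stand-in geography for study-scale runs."""
    return make_grid_geography(8)


@pytest.fixture
def two_region_table() -> CaseTable:
    """K=2 table with a clear inside/outside contrast."""
    return CaseTable(np.array([[9, 1], [5, 5]]))


@pytest.fixture
def uniform_table4() -> CaseTable:
    """Every region shares the same category distribution: no contrast."""
    return CaseTable(np.ones((4, 4), dtype=int))
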