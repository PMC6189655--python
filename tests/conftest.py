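import sys
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from panelagree import RatingsMatrix


def make_matrix(grid, categories=("0", "1"), feature_id="f", items=None, raters=None):
    """RatingsMatrix from a list-of-rows grid (None = missing)."""
    n_items = len(grid)
    n_raters = len(grid[0])
    items = items or [f"i{k+1}" for k in range(n_items)]
    raters = raters or [f"r{k+1}" for k in range(n_raters)]
    frame = pd.DataFrame(grid, index=items, columns=raters, dtype=object)
    return RatingsMatrix(feature_id, frame, tuple(categories))


@pytest.fixture
def known_grid():
    """4 items x 3 raters binary grid with AC1 = 1/3 exactly."""
    return [["1", "1", "0"], ["1", "1", "1"], ["0", "0", "0"], ["1", "0", "0"]]


@pytest.fixture
def known_matrix(known_grid):
    return make_matrix(known_grid)


@pytest.fixture
def unanimous_matrix():
    return make_matrix([["1"] * 5 for _ in range(10)])
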