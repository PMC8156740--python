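import numpy as np
import pytest

from nichesim.lattice import grid_from_array


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture
def random_grid(rng):
    """An 8x8 grid with ~30% cancer sites."""
    return grid_from_array((rng.random((8, 8)) < 0.3).astype(int))
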