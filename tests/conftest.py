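import numpy as np
import pytest

from bipnull import BipartiteIncidence


@pytest.fixture
def identity2() -> BipartiteIncidence:
    """2x2 checkerboard: k = d = [1, 1]."""
    return BipartiteIncidence(("r1", "r2"), ("c1", "c2"), np.eye(2, dtype=int))


@pytest.fixture
def forced_2x2() -> BipartiteIncidence:
    """[[1,1],[1,0]]: every probability forced to 0/1 by the bounds."""
    return BipartiteIncidence(("r1", "r2"), ("c1", "c2"), [[1, 1], [1, 0]])


@pytest.fixture
def two_blocks() -> BipartiteIncidence:
    """Two disjoint complete 2x2 blocks; max Barber Q = 0.5."""
    entries = np.kron(np.eye(2, dtype=int), np.ones((2, 2), dtype=int))
    return BipartiteIncidence(tuple("abcd"), tuple("wxyz"), entries)
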