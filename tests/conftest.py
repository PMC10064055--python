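import numpy as np
import pytest

from phyllonet import InteractionMatrix, OtuTable, simulate_tree


@pytest.fixture
def small_table():
    return OtuTable(["s1", "s2"], ["OTU_1", "OTU_2"], np.array([[5, 0], [3, 7]]))


@pytest.fixture
def tree11():
    return simulate_tree(11, seed=11)


@pytest.fixture
def random_interaction():
    """Sparse random 10x30 integer matrix without empty rows/columns."""
    rng = np.random.default_rng(42)
    w = rng.poisson(2.0, size=(10, 30))
    w[rng.random(w.shape) < 0.4] = 0
    for i in np.flatnonzero(w.sum(axis=1) == 0):
        w[i, rng.integers(30)] += 1
    for j in np.flatnonzero(w.sum(axis=0) == 0):
        w[rng.integers(10), j] += 1
    return InteractionMatrix(
        [f"p{i}" for i in range(10)], [f"f{j}" for j in range(30)], w.astype(float)
    )
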