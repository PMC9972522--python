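import numpy as np
import pytest

from contrastnet import SignedDifferenceGraph, WeightedNetwork


def random_signed_graph(n: int, rng: np.random.Generator, low=-1.0, high=1.0):
    """Complete signed graph with i.i.d. uniform pair weights."""
    w = rng.uniform(low, high, size=(n, n))
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    nodes = [f"n{i:02d}" for i in range(n)]
    return SignedDifferenceGraph(nodes, w)


def random_weighted_network(n: int, rng: np.random.Generator):
    w = rng.uniform(0.0, 1.0, size=(n, n))
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return WeightedNetwork([f"n{i:02d}" for i in range(n)], w)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def unit_triangle():
    """Unit-weight triangle on a, b, c."""
    w = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
    return SignedDifferenceGraph(["a", "b", "c"], w)


@pytest.fixture
def mixed_triangle():
    """Triangle with weights ab=+1, ac=+1, bc=-1."""
    w = np.array([[0, 1, 1], [1, 0, -1], [1, -1, 0]], dtype=float)
    return SignedDifferenceGraph(["a", "b", "c"], w)
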