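import numpy as np
import pytest

from stcarclust import AreaGraph, CountData, Partition


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def path3():
    """Path graph 1-2-3 (0-based indices)."""
    return AreaGraph(3, [(0, 1), (1, 2)])


@pytest.fixture
def grid2x2():
    """2x2 rook grid."""
    return AreaGraph(4, [(0, 1), (0, 2), (1, 3), (2, 3)])


@pytest.fixture
def small_graph():
    """A 6-node graph with a cycle and a chord."""
    return AreaGraph(6, [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (0, 5), (1, 4)])


def random_graph(n, rng, p=0.4):
    """Erdos-Renyi style random symmetric adjacency."""
    edges = [
        (i, j) for i in range(n) for j in range(i + 1, n) if rng.uniform() < p
    ]
    return AreaGraph(n, edges)


@pytest.fixture
def tiny_counts():
    Y = np.array([[4, 6], [8, 10], [2, 4]])
    E = np.array([[5.0, 5.0], [9.0, 9.0], [3.0, 3.0]])
    return CountData(Y=Y, E=E)


def three_level_partition(n):
    labels = np.ones(n, dtype=np.int64)
    labels[: n // 3] = 2
    labels[n // 3 : 2 * n // 3] = 3
    return Partition(labels, k=3)
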