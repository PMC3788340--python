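import numpy as np
import pytest

from connsweep import BaseGraphConfig, BinaryGraph, CohortSpec


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture()
def five_node_graph():
    """Fixture graph with edges {12, 13, 23, 34, 45} (1-based)."""
    a = np.zeros((5, 5), dtype=int)
    for i, j in [(0, 1), (0, 2), (1, 2), (2, 3), (3, 4)]:
        a[i, j] = a[j, i] = 1
    return BinaryGraph(adjacency=a)


@pytest.fixture()
def small_spec():
    """A cheap cohort spec for pipeline-level tests."""
    return CohortSpec(
        n_group_a=4,
        n_group_b=4,
        n_rois=40,
        base_graph=BaseGraphConfig(neighbors_k=6, rewire_prob=0.1),
        effect_rois=(36, 37, 38, 39, 40),
        seed=99,
    )


def ring_lattice(n: int, k: int) -> np.ndarray:
    """Ring lattice adjacency: each node tied to its k nearest neighbors."""
    a = np.zeros((n, n), dtype=int)
    for offset in range(1, k // 2 + 1):
        idx = np.arange(n)
        a[idx, (idx + offset) % n] = 1
        a[(idx + offset) % n, idx] = 1
    return a
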