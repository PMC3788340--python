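"""Degree-preserving random networks and small-world normalization.

Small-world metrics are only interpretable relative to random graphs with
the same degree sequence.  Nulls are produced by Maslov-Sneppen double-edge
swaps: pick two edges (a, b) and (c, d) with four distinct endpoints and
replace them with (a, d) and (c, b) unless either replacement already
exists.  Every node's degree and the total edge count are invariant under
the swap.  The inner loop is JIT-compiled; all randomness is drawn up front
from a numpy Generator so results are reproducible from the seed alone.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .graph import BinaryGraph, _bfs_distances, _clustering_terms, _efficiency_from_distances

logger = logging.getLogger(__name__)

__all__ = [
    "NullConfig",
    "NormalizedSmallWorld",
    "rewire_degree_preserving",
    "normalize_small_world",
]


@dataclass(frozen=True)
class NullConfig:
    """How many nulls to generate and how hard to randomize each one."""

    n_null: int = 100
    swap_factor: float = 10.0

    def __post_init__(self) -> None:
        if self.n_null < 1:
            raise ValueError("n_null must be >= 1")
        if self.swap_factor < 0:
            raise ValueError("swap_factor must be nonnegative")


@dataclass(frozen=True)
class NormalizedSmallWorld:
    """gamma = C_P/C_P^rand, lam = L_P/L_P^rand, sigma = gamma/lam."""

    gamma: float
    lam: float
    sigma: float
    c_rand: float
    l_rand: float
    n_null: int
    n_excluded: int = 0


@njit(cache=True)
def _swap_kernel(adj, edges, pick1, pick2, flip):  # pragma: no cover - JIT
    n_swapped = 0
    for t in range(pick1.size):
        i = pick1[t]
        j = pick2[t]
        if i == j:
            continue
        a = edges[i, 0]
        b = edges[i, 1]
        c = edges[j, 0]
        d = edges[j, 1]
        if flip[t]:
            c, d = d, c
        if a == c or a == d or b == c or b == d:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = 0
        adj[b, a] = 0
        adj[c, d] = 0
        adj[d, c] = 0
        adj[a, d] = 1
        adj[d, a] = 1
        adj[c, b] = 1
        adj[b, c] = 1
        edges[i, 0] = a
        edges[i, 1] = d
        edges[j, 0] = c
        edges[j, 1] = b
        n_swapped += 1
    return n_swapped


def rewire_degree_preserving(g: BinaryGraph, swap_factor: float = 10.0, seed: int = 0) -> BinaryGraph:
    """Maslov-Sneppen rewiring with ceil(swap_factor * |E|) attempted swaps.

    Degree sequence and edge count are preserved exactly.  If no attempted
    swap is legal (e.g. a triangle), the input graph is returned unchanged
    with a logged warning.
    """
    n_edges = g.n_edges
    if n_edges < 2:
        raise ValueError("rewiring needs at least two edges")
    attempts = int(math.ceil(swap_factor * n_edges))
    adj = g.adjacency.copy()
    if attempts == 0:
        return BinaryGraph(adjacency=adj, sparsity=g.sparsity)
    edges = np.ascontiguousarray(g.edge_list().astype(np.int64))
    rng = np.random.default_rng(seed)
    pick1 = rng.integers(0, n_edges, attempts)
    pick2 = rng.integers(0, n_edges, attempts)
    flip = rng.integers(0, 2, attempts).astype(np.bool_)
    n_swapped = _swap_kernel(adj, edges, pick1, pick2, flip)
    if n_swapped == 0:
        logger.warning(
            "rewire_degree_preserving: no legal swap found in %d attempts; "
            "returning the input graph",
            attempts,
        )
    return BinaryGraph(adjacency=adj, sparsity=g.sparsity)


def _cp_lp(adj: np.ndarray) -> tuple[float, float]:
    """Fast C_P and harmonic L_P for a null graph (no nodal quantities)."""
    e_i, deg = _clustering_terms(adj)
    denom = deg * (deg - 1) / 2.0
    terms = np.where(deg >= 2, e_i / np.where(denom > 0, denom, 1.0), 0.0)
    c_p = float(terms.mean())
    e_glob = _efficiency_from_distances(_bfs_distances(adj))
    l_p = 1.0 / e_glob if e_glob > 0 else math.inf
    return c_p, l_p


def normalize_small_world(
    g: BinaryGraph,
    n_null: int = 100,
    swap_factor: float = 10.0,
    seed: int = 0,
    real_c_p: float | None = None,
    real_l_p: float | None = None,
) -> NormalizedSmallWorld:
    """Normalize C_P and L_P against degree-matched rewired nulls.

    ``c_rand``/``l_rand`` are arithmetic means over the nulls; a null with
    C_P = 0 or infinite L_P is excluded from the means with a logged count.
    Pass ``real_c_p``/``real_l_p`` to avoid recomputing the input's metrics.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    if real_c_p is None or real_l_p is None:
        real_c_p, real_l_p = _cp_lp(g.adjacency)

    seeds = np.random.SeedSequence(seed).generate_state(n_null) % (2**31)
    c_vals, l_vals = [], []
    n_excluded = 0
    for k in range(n_null):
        null = rewire_degree_preserving(g, swap_factor=swap_factor, seed=int(seeds[k]))
        c_p, l_p = _cp_lp(null.adjacency)
        if c_p == 0.0 or not math.isfinite(l_p):
            n_excluded += 1
            continue
        c_vals.append(c_p)
        l_vals.append(l_p)
    if not c_vals:
        raise ValueError("all null networks were degenerate (C_P = 0 or L_P = inf)")
    if n_excluded:
        logger.warning("normalize_small_world: excluded %d degenerate null(s)", n_excluded)

    # exact mean for identical values so zero-swap normalization gives
    # gamma = lam = sigma = 1 exactly
    c_rand = c_vals[0] if len(set(c_vals)) == 1 else float(np.mean(c_vals))
    l_rand = l_vals[0] if len(set(l_vals)) == 1 else float(np.mean(l_vals))
    gamma = real_c_p / c_rand
    lam = real_l_p / l_rand
    return NormalizedSmallWorld(
        gamma=gamma,
        lam=lam,
        sigma=gamma / lam,
        c_rand=c_rand,
        l_rand=l_rand,
        n_null=n_null,
        n_excluded=n_excluded,
    )
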