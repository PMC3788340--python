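"""Sparsity-thresholded binary graphs and their global/nodal metrics.

Conventions implemented here (all over undirected, unweighted graphs):

* binarization keeps the K = round_half_up(S * N(N-1)/2) node pairs with the
  largest signed Fisher-z value, ties broken lexicographically by (i, j);
* clustering coefficient C_P averages E_i / (d_i (d_i - 1) / 2) over all
  nodes, with the term defined as 0 for degree < 2;
* characteristic path length uses the harmonic form L_P = 1 / E_glob, where
  E_glob is the mean inverse shortest-path length over ordered pairs (with
  1/inf = 0), so disconnected graphs stay finite; the arithmetic mean over
  reachable pairs is available behind ``path_length="arithmetic"``;
* local efficiency averages E_glob of each node's neighbor subgraph (0 for
  neighborhoods of fewer than two nodes);
* nodal betweenness counts each unordered pair once and is unnormalized
  (Freeman's definition), computed by Brandes-style dependency accumulation.

Shortest-path distances, path counts, and betweenness come from a JIT-
compiled all-sources BFS with Brandes accumulation over a CSR adjacency,
exact for unweighted graphs; the whole sweep touches tens of thousands of
graphs (33 subjects x 33 thresholds x ~20 nulls), so the inner loops matter.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from numba import njit

logger = logging.getLogger(__name__)

__all__ = [
    "BinaryGraph",
    "PathCensus",
    "GlobalMetrics",
    "NodalMetrics",
    "binarize_by_sparsity",
    "path_census",
    "global_metrics",
    "nodal_metrics",
]


@dataclass
class BinaryGraph:
    """Undirected unweighted graph as a symmetric 0/1 adjacency matrix."""

    adjacency: np.ndarray
    sparsity: Optional[float] = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.diag(a).any():
            raise ValueError("adjacency must have zero diagonal")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency must be 0/1")
        self.adjacency = a.astype(np.uint8)
        if self.sparsity is None:
            n = a.shape[0]
            self.sparsity = self.n_edges / (n * (n - 1) / 2)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(np.int64)

    def edge_list(self) -> np.ndarray:
        iu = np.triu_indices(self.n_nodes, 1)
        mask = self.adjacency[iu] == 1
        return np.column_stack([iu[0][mask], iu[1][mask]])


@dataclass
class PathCensus:
    """All-pairs shortest-path distances and path counts.

    ``distances[i, j]`` is the edge count of a shortest i-j path (+inf when
    unreachable, 0 on the diagonal); ``path_counts[i, j]`` is the number of
    distinct shortest paths (0 when unreachable, 1 on the diagonal).
    """

    distances: np.ndarray
    path_counts: np.ndarray
    betweenness: Optional[np.ndarray] = None


@dataclass(frozen=True)
class GlobalMetrics:
    c_p: float
    l_p: float
    e_glob: float
    e_loc: float


@dataclass
class NodalMetrics:
    degree: np.ndarray
    efficiency: np.ndarray
    betweenness: np.ndarray


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def binarize_by_sparsity(conn, s: float) -> BinaryGraph:
    """Threshold a connectivity matrix into a binary graph at sparsity ``s``.

    ``conn`` may be a ConnectivityMatrix (its signed z matrix is ranked) or a
    raw symmetric matrix.  Keeps the K = round_half_up(s * N(N-1)/2) largest
    entries; ties are broken lexicographically by (i, j) and a tie crossing
    the cut boundary is logged.
    """
    z = np.asarray(conn.z_matrix if hasattr(conn, "z_matrix") else conn, dtype=float)
    n = z.shape[0]
    m = n * (n - 1) // 2
    if not 0.0 < s < 1.0:
        raise ValueError("sparsity must lie in (0, 1)")
    k = _round_half_up(s * m)
    if k == 0:
        raise ValueError(f"sparsity {s} keeps zero edges on {n} nodes")
    if k > m:
        raise ValueError(f"sparsity {s} requests {k} edges but only {m} pairs exist")
    iu, ju = np.triu_indices(n, 1)
    vals = z[iu, ju]
    order = np.lexsort((ju, iu, -vals))
    if k < m and vals[order[k - 1]] == vals[order[k]]:
        logger.warning(
            "binarize_by_sparsity: tie at the cut boundary (z = %g); "
            "lexicographic (i, j) tie-break applied",
            vals[order[k - 1]],
        )
    sel = order[:k]
    a = np.zeros((n, n), dtype=np.uint8)
    a[iu[sel], ju[sel]] = 1
    a |= a.T
    return BinaryGraph(adjacency=a, sparsity=s)


@njit(cache=True)
def _bfs_census_kernel(indptr, indices, n, compute_btw):  # pragma: no cover - JIT
    """All-sources BFS over a CSR adjacency.

    Returns integer distances (-1 = unreachable), shortest-path counts, and
    (when requested) unnormalized betweenness counting each unordered pair
    once, via Brandes' dependency accumulation.
    """
    dist = np.full((n, n), -1, dtype=np.int32)
    sigma = np.zeros((n, n))
    btw = np.zeros(n)
    queue = np.empty(n, dtype=np.int32)
    delta = np.empty(n)
    for s in range(n):
        dist[s, s] = 0
        sigma[s, s] = 1.0
        queue[0] = s
        head, tail = 0, 1
        while head < tail:
            v = queue[head]
            head += 1
            dv = dist[s, v]
            for k in range(indptr[v], indptr[v + 1]):
                w = indices[k]
                if dist[s, w] < 0:
                    dist[s, w] = dv + 1
                    queue[tail] = w
                    tail += 1
                if dist[s, w] == dv + 1:
                    sigma[s, w] += sigma[s, v]
        if compute_btw:
            for v in range(n):
                delta[v] = 0.0
            for k in range(tail - 1, 0, -1):  # reverse BFS order, skip source
                w = queue[k]
                coeff = (1.0 + delta[w]) / sigma[s, w]
                dw = dist[s, w]
                for kk in range(indptr[w], indptr[w + 1]):
                    v = indices[kk]
                    if dist[s, v] == dw - 1:
                        delta[v] += sigma[s, v] * coeff
            for v in range(n):
                if v != s:
                    btw[v] += delta[v]
    return dist, sigma, btw / 2.0


@njit(cache=True)
def _local_efficiency_kernel(indptr, indices, n):  # pragma: no cover - JIT
    """E_glob of every node's neighbor subgraph (0 for fewer than 2 nodes)."""
    out = np.zeros(n)
    nbr = np.empty(n, dtype=np.int32)
    pos = np.full(n, -1, dtype=np.int32)
    dist = np.empty(n, dtype=np.int32)
    queue = np.empty(n, dtype=np.int32)
    for i in range(n):
        d = indptr[i + 1] - indptr[i]
        if d < 2:
            continue
        for k in range(d):
            v = indices[indptr[i] + k]
            nbr[k] = v
            pos[v] = k
        total = 0.0
        for s_local in range(d):
            for k in range(d):
                dist[k] = -1
            dist[s_local] = 0
            queue[0] = s_local
            head, tail = 0, 1
            while head < tail:
                vl = queue[head]
                head += 1
                v = nbr[vl]
                for kk in range(indptr[v], indptr[v + 1]):
                    wl = pos[indices[kk]]
                    if wl >= 0 and dist[wl] < 0:
                        dist[wl] = dist[vl] + 1
                        queue[tail] = wl
                        tail += 1
            for k in range(d):
                if k != s_local and dist[k] > 0:
                    total += 1.0 / dist[k]
        out[i] = total / (d * (d - 1))
        for k in range(d):
            pos[nbr[k]] = -1
    return out


def _to_csr(adj: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    rows, cols = np.nonzero(adj)
    indptr = np.zeros(adj.shape[0] + 1, dtype=np.int64)
    np.cumsum(np.bincount(rows, minlength=adj.shape[0]), out=indptr[1:])
    return indptr, cols.astype(np.int32)


def _bfs_distances(adj: np.ndarray) -> np.ndarray:
    """All-pairs BFS distances (float, +inf where unreachable)."""
    n = adj.shape[0]
    indptr, indices = _to_csr(adj)
    dist_i, _, _ = _bfs_census_kernel(indptr, indices, n, False)
    dist = dist_i.astype(float)
    dist[dist_i < 0] = np.inf
    return dist


def path_census(g: BinaryGraph, compute_betweenness: bool = False) -> PathCensus:
    """BFS distances and shortest-path counts from every source node."""
    n = g.n_nodes
    indptr, indices = _to_csr(g.adjacency)
    dist_i, sigma, btw = _bfs_census_kernel(indptr, indices, n, compute_betweenness)
    dist = dist_i.astype(float)
    dist[dist_i < 0] = np.inf
    return PathCensus(
        distances=dist, path_counts=sigma, betweenness=btw if compute_betweenness else None
    )


def _efficiency_from_distances(dist: np.ndarray) -> float:
    n = dist.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(dist) & off, 1.0 / np.where(dist > 0, dist, 1.0), 0.0)
    return float(inv.sum() / (n * (n - 1)))


def _clustering_terms(adj: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-node neighbor-subgraph edge counts E_i and degrees."""
    a = adj.astype(float)
    deg = a.sum(axis=1)
    e_i = ((a @ a) * a).sum(axis=1) / 2.0  # triangles through i = diag(A^3)/2
    return e_i, deg


def global_metrics(
    g: BinaryGraph, census: Optional[PathCensus] = None, path_length: str = "harmonic"
) -> GlobalMetrics:
    """Clustering, characteristic path length, global and local efficiency.

    ``path_length="harmonic"`` (default) takes L_P = 1/E_glob, the reciprocal
    mean-inverse-distance form, which remains finite on disconnected graphs;
    ``"arithmetic"`` averages finite distances over reachable pairs instead.
    """
    a = g.adjacency
    n = g.n_nodes
    dist = census.distances if census is not None else _bfs_distances(a)

    e_i, deg = _clustering_terms(a)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = deg * (deg - 1) / 2.0
        terms = np.where(deg >= 2, e_i / np.where(denom > 0, denom, 1.0), 0.0)
    c_p = float(terms.mean())

    e_glob = _efficiency_from_distances(dist)

    if path_length == "harmonic":
        l_p = 1.0 / e_glob if e_glob > 0 else math.inf
    elif path_length == "arithmetic":
        off = ~np.eye(n, dtype=bool)
        finite = np.isfinite(dist) & off
        l_p = float(dist[finite].mean()) if finite.any() else math.inf
    else:
        raise ValueError("path_length must be 'harmonic' or 'arithmetic'")

    indptr, indices = _to_csr(a)
    e_loc = float(_local_efficiency_kernel(indptr, indices, n).mean())

    return GlobalMetrics(c_p=c_p, l_p=l_p, e_glob=e_glob, e_loc=e_loc)


def nodal_metrics(g: BinaryGraph, census: Optional[PathCensus] = None) -> NodalMetrics:
    """Nodal degree, nodal efficiency, and nodal betweenness."""
    if census is None or census.betweenness is None:
        census = path_census(g, compute_betweenness=True)
    n = g.n_nodes
    dist = census.distances
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(dist) & off, 1.0 / np.where(dist > 0, dist, 1.0), 0.0)
    e_nod = inv.sum(axis=1) / (n - 1)
    return NodalMetrics(
        degree=g.degrees(),
        efficiency=e_nod,
        betweenness=census.betweenness,
    )
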