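"""Independent brute-force oracles for graph quantities.

These deliberately avoid the package's BFS/Brandes code paths: distances and
shortest-path counts come from adjacency-matrix powers (a length-k walk of
minimal length between two nodes is necessarily a simple path, and the k-th
power counts walks), betweenness from the sigma(j,i)*sigma(i,k) pair
identity evaluated naively over all triples, and the efficiency/clustering
quantities from plain Python loops over the distance matrix.  Only suitable
for small graphs.
"""

from __future__ import annotations

import math

import numpy as np


def distances_and_counts(adj: np.ndarray):
    """All-pairs shortest-path lengths and counts by matrix powers."""
    n = adj.shape[0]
    a = adj.astype(np.int64)
    dist = np.full((n, n), np.inf)
    counts = np.zeros((n, n))
    np.fill_diagonal(dist, 0.0)
    np.fill_diagonal(counts, 1.0)
    power = np.eye(n, dtype=np.int64)
    for k in range(1, n):
        power = power @ a
        new = np.isinf(dist) & (power > 0)
        dist[new] = k
        counts[new] = power[new]
        if not np.isinf(dist[~np.eye(n, dtype=bool)]).any():
            break
    return dist, counts


def betweenness(adj: np.ndarray) -> np.ndarray:
    """Unnormalized betweenness (each unordered pair once) over all triples:
    sigma_jk(i) = sigma(j,i) * sigma(i,k) when d(j,i) + d(i,k) = d(j,k)."""
    n = adj.shape[0]
    dist, counts = distances_and_counts(adj)
    btw = np.zeros(n)
    for i in range(n):
        for j in range(n):
            for k in range(j + 1, n):
                if i in (j, k) or not math.isfinite(dist[j, k]) or counts[j, k] == 0:
                    continue
                if dist[j, i] + dist[i, k] == dist[j, k]:
                    btw[i] += counts[j, i] * counts[i, k] / counts[j, k]
    return btw


def global_metrics(adj: np.ndarray):
    """(c_p, l_p harmonic, e_glob, e_loc) by direct loops."""
    n = adj.shape[0]
    dist, _ = distances_and_counts(adj)

    c_terms = []
    for i in range(n):
        nb = [j for j in range(n) if adj[i, j]]
        d = len(nb)
        if d < 2:
            c_terms.append(0.0)
            continue
        e_i = sum(adj[u, v] for ui, u in enumerate(nb) for v in nb[ui + 1 :])
        c_terms.append(e_i / (d * (d - 1) / 2))
    c_p = sum(c_terms) / n

    inv_sum = sum(
        1.0 / dist[i, j]
        for i in range(n)
        for j in range(n)
        if i != j and math.isfinite(dist[i, j])
    )
    e_glob = inv_sum / (n * (n - 1))
    l_p = 1.0 / e_glob if e_glob > 0 else math.inf

    e_loc_terms = []
    for i in range(n):
        nb = [j for j in range(n) if adj[i, j]]
        if len(nb) < 2:
            e_loc_terms.append(0.0)
            continue
        sub = adj[np.ix_(nb, nb)]
        sdist, _ = distances_and_counts(sub)
        m = len(nb)
        s = sum(
            1.0 / sdist[u, v]
            for u in range(m)
            for v in range(m)
            if u != v and math.isfinite(sdist[u, v])
        )
        e_loc_terms.append(s / (m * (m - 1)))
    e_loc = sum(e_loc_terms) / n

    return c_p, l_p, e_glob, e_loc


def nodal_efficiency(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    dist, _ = distances_and_counts(adj)
    out = np.zeros(n)
    for i in range(n):
        out[i] = sum(
            1.0 / dist[i, j] for j in range(n) if j != i and math.isfinite(dist[i, j])
        ) / (n - 1)
    return out


def random_adjacency(n: int, density: float, rng: np.random.Generator) -> np.ndarray:
    a = np.zeros((n, n), dtype=np.int64)
    iu = np.triu_indices(n, 1)
    mask = rng.random(iu[0].size) < density
    a[iu[0][mask], iu[1][mask]] = 1
    return a + a.T
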