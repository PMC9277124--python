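"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's own algorithms and third-party graph
routines: distances come from a naive queue-free BFS, triangles from triple
enumeration, betweenness from a layered shortest-path-count recursion, and
BH-FDR from a direct sort of the step-up definition.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations

import numpy as np


def bfs_distances(adj: np.ndarray, source: int) -> list[float]:
    n = adj.shape[0]
    dist = [float("inf")] * n
    dist[source] = 0
    frontier = [source]
    d = 0
    while frontier:
        d += 1
        nxt = []
        for u in frontier:
            for v in range(n):
                if adj[u, v] and dist[v] == float("inf"):
                    dist[v] = d
                    nxt.append(v)
        frontier = nxt
    return dist


def all_distances(adj: np.ndarray) -> list[list[float]]:
    return [bfs_distances(adj, s) for s in range(adj.shape[0])]


def clustering_by_triples(adj: np.ndarray) -> list[Fraction]:
    """Per-node clustering by exhaustive neighbor-pair enumeration."""
    n = adj.shape[0]
    out = []
    for i in range(n):
        nb = [j for j in range(n) if adj[i, j]]
        k = len(nb)
        if k < 2:
            out.append(Fraction(0))
            continue
        closed = sum(1 for a, b in combinations(nb, 2) if adj[a, b])
        out.append(Fraction(2 * closed, k * (k - 1)))
    return out


def path_length_connected_pairs(adj: np.ndarray) -> Fraction | None:
    d = all_distances(adj)
    n = adj.shape[0]
    vals = [d[i][j] for i in range(n) for j in range(n)
            if i != j and d[i][j] != float("inf")]
    if not vals:
        return None
    return Fraction(sum(int(v) for v in vals), len(vals))


def global_efficiency_pairs(adj: np.ndarray) -> Fraction:
    d = all_distances(adj)
    n = adj.shape[0]
    if n < 2:
        return Fraction(0)
    total = Fraction(0)
    for i in range(n):
        for j in range(n):
            if i != j and d[i][j] != float("inf"):
                total += Fraction(1, int(d[i][j]))
    return total / (n * (n - 1))


def nodal_efficiency_pairs(adj: np.ndarray) -> list[Fraction]:
    d = all_distances(adj)
    n = adj.shape[0]
    out = []
    for i in range(n):
        total = Fraction(0)
        for j in range(n):
            if i != j and d[i][j] != float("inf"):
                total += Fraction(1, int(d[i][j]))
        out.append(total / (n - 1) if n > 1 else Fraction(0))
    return out


def local_efficiency_subgraphs(adj: np.ndarray) -> Fraction:
    n = adj.shape[0]
    total = Fraction(0)
    for i in range(n):
        nb = [j for j in range(n) if adj[i, j]]
        if len(nb) < 2:
            continue
        sub = adj[np.ix_(nb, nb)]
        total += global_efficiency_pairs(sub)
    return total / n if n else Fraction(0)


def shortest_path_counts(adj: np.ndarray, s: int) -> tuple[list[float], list[int]]:
    """Distances and shortest-path counts from s by layer recursion."""
    n = adj.shape[0]
    dist = bfs_distances(adj, s)
    sigma = [0] * n
    sigma[s] = 1
    order = sorted((d, v) for v, d in enumerate(dist) if d != float("inf"))
    for d, v in order:
        if v == s:
            continue
        sigma[v] = sum(
            sigma[u] for u in range(n) if adj[u, v] and dist[u] == d - 1
        )
    return dist, sigma


def betweenness_by_pair_counting(adj: np.ndarray) -> list[Fraction]:
    """Unnormalized betweenness: sum over unordered pairs {s,t} of the
    fraction of s-t shortest paths through v, via sigma_sv * sigma_vt."""
    n = adj.shape[0]
    dist = {}
    sigma = {}
    for s in range(n):
        dist[s], sigma[s] = shortest_path_counts(adj, s)
    btw = [Fraction(0)] * n
    for s, t in combinations(range(n), 2):
        if dist[s][t] == float("inf") or sigma[s][t] == 0:
            continue
        for v in range(n):
            if v in (s, t) or dist[s][v] == float("inf") or dist[t][v] == float("inf"):
                continue
            if dist[s][v] + dist[t][v] == dist[s][t]:
                btw[v] += Fraction(sigma[s][v] * sigma[t][v], sigma[s][t])
    return btw


def pearson_two_pass(x, y) -> float:
    x = list(map(float, x))
    y = list(map(float, y))
    mx = sum(x) / len(x)
    my = sum(y) / len(y)
    dx = [v - mx for v in x]
    dy = [v - my for v in y]
    num = sum(a * b for a, b in zip(dx, dy))
    den = (sum(a * a for a in dx) * sum(b * b for b in dy)) ** 0.5
    return num / den


def bh_reference(p_values, q: float):
    """Step-up BH: adjusted p by cumulative min from the largest rank."""
    p = list(map(float, p_values))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    reject = [a <= q for a in adj]
    return adj, reject


def random_graph(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    a = (rng.random((n, n)) < p).astype(np.uint8)
    a = np.triu(a, 1)
    return a + a.T
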