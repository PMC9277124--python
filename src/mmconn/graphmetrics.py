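"""Global and nodal graph-theoretic properties of binary brain networks.

All metrics are defined on undirected, unweighted graphs (networks are
binarized before analysis).  Path-based quantities follow two conventions,
stated once here:

* the characteristic path length L averages shortest-path distances over
  *connected* ordered pairs only, and the fraction of disconnected pairs is
  surfaced alongside;
* efficiency-type metrics average 1/d over *all* ordered pairs with
  1/infinity = 0, so disconnection is absorbed naturally.

Small-world normalization (gamma = C/C_null, lambda = L/L_null,
sigma = gamma/lambda) uses an ensemble of degree-preserving randomizations
built by repeated double-edge swaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .netbuild import BinaryNetwork

__all__ = [
    "GlobalMetrics",
    "NodalMetrics",
    "NullEnsemble",
    "clustering_coefficient",
    "shortest_path_metrics",
    "global_efficiency",
    "local_efficiency",
    "nodal_efficiency",
    "betweenness_centrality",
    "null_ensemble",
    "small_world_indices",
    "global_metrics",
    "nodal_metrics",
]

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


def _adj(G) -> np.ndarray:
    """Accept a BinaryNetwork or a plain 0/1 adjacency array."""
    a = G.adjacency if isinstance(G, BinaryNetwork) else np.asarray(G)
    return (a != 0).astype(np.uint8)


@dataclass
class GlobalMetrics:
    """Whole-network properties at one threshold."""

    clustering_mean: float
    path_length: float
    gamma: float
    lam: float
    sigma: float
    e_glob: float
    e_loc: float
    disconnected_pair_fraction: float

    def as_dict(self) -> dict[str, float]:
        return {
            "clustering": self.clustering_mean,
            "path_length": self.path_length,
            "gamma": self.gamma,
            "lambda": self.lam,
            "sigma": self.sigma,
            "e_loc": self.e_loc,
            "e_glob": self.e_glob,
            "disconnected_pair_fraction": self.disconnected_pair_fraction,
        }


@dataclass
class NodalMetrics:
    """Per-region properties at one threshold."""

    e_nod: np.ndarray
    betweenness: np.ndarray


@dataclass
class NullEnsemble:
    """Degree-preserving randomizations of one network."""

    members: list[np.ndarray]
    n_networks: int
    swaps_per_edge: int
    seed: int | None
    #: True when no valid double-edge swap exists (e.g. a star graph); the
    #: members are then verbatim copies of the original.
    degenerate: bool = False


def clustering_coefficient(G) -> tuple[np.ndarray, float]:
    """Per-node clustering 2*T_i / (k_i (k_i - 1)) and its mean over all nodes.

    T_i counts triangles through node i; nodes of degree < 2 score 0.
    """
    a = _adj(G).astype(np.float64)
    k = a.sum(axis=1)
    tri = ((a @ a) * a).sum(axis=1) / 2.0
    denom = k * (k - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, 2.0 * tri / denom, 0.0)
    return c, float(c.mean()) if c.size else 0.0


def _distance_matrix(a: np.ndarray) -> np.ndarray:
    """All-pairs BFS distances; inf marks disconnected pairs."""
    n = a.shape[0]
    if n == 0:
        return np.zeros((0, 0))
    if not a.any():
        d = np.full((n, n), np.inf)
        np.fill_diagonal(d, 0.0)
        return d
    if _HAVE_NUMBA:
        raw = _bfs_all_pairs(np.ascontiguousarray(a, dtype=np.uint8))
        d = raw.astype(np.float64)
        d[raw < 0] = np.inf
        return d
    return shortest_path(csr_matrix(a), method="D", directed=False, unweighted=True)


def shortest_path_metrics(G) -> tuple[np.ndarray, float, float]:
    """Distance matrix, characteristic path length, disconnected-pair fraction.

    L is the mean distance over connected ordered pairs only; for a graph with
    no edges L is returned as NaN with a disconnected fraction of 1.
    """
    a = _adj(G)
    d = _distance_matrix(a)
    n = a.shape[0]
    if n < 2:
        return d, float("nan"), 0.0
    off = ~np.eye(n, dtype=bool)
    dv = d[off]
    finite = np.isfinite(dv)
    frac_disc = 1.0 - finite.mean()
    L = float(dv[finite].mean()) if finite.any() else float("nan")
    return d, L, float(frac_disc)


def _char_path_length(a: np.ndarray) -> float:
    """Mean BFS distance over connected ordered pairs (NaN if no edges)."""
    d = _distance_matrix(a)
    n = a.shape[0]
    if n < 2:
        return float("nan")
    off = ~np.eye(n, dtype=bool)
    dv = d[off]
    finite = np.isfinite(dv)
    return float(dv[finite].mean()) if finite.any() else float("nan")


def _efficiency_from_distances(d: np.ndarray) -> float:
    n = d.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d[off]
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.mean())


def global_efficiency(G) -> float:
    """Mean of 1/d(i, j) over all ordered pairs, with 1/infinity = 0."""
    return _efficiency_from_distances(_distance_matrix(_adj(G)))


@njit(cache=True)
def _local_efficiency_kernel(adj):  # pragma: no cover - numba
    n = adj.shape[0]
    total = 0.0
    nb = np.empty(n, dtype=np.int32)
    for i in range(n):
        deg = 0
        for v in range(n):
            if adj[i, v] == 1:
                nb[deg] = v
                deg += 1
        if deg < 2:
            continue
        # BFS within the neighbor-induced subgraph from every neighbor
        dist = np.empty(deg, dtype=np.int32)
        queue = np.empty(deg, dtype=np.int32)
        inv_sum = 0.0
        for s in range(deg):
            for t in range(deg):
                dist[t] = -1
            dist[s] = 0
            queue[0] = s
            head = 0
            tail = 1
            while head < tail:
                u = queue[head]
                head += 1
                du = dist[u]
                for t in range(deg):
                    if dist[t] < 0 and adj[nb[u], nb[t]] == 1:
                        dist[t] = du + 1
                        queue[tail] = t
                        tail += 1
            for t in range(deg):
                if t != s and dist[t] > 0:
                    inv_sum += 1.0 / dist[t]
        total += inv_sum / (deg * (deg - 1))
    return total / n


def local_efficiency(G) -> float:
    """Mean over nodes of the global efficiency of each neighbor subgraph.

    Nodes with fewer than two neighbors contribute 0.
    """
    a = _adj(G)
    n = a.shape[0]
    if n == 0:
        return 0.0
    if _HAVE_NUMBA:
        return float(_local_efficiency_kernel(np.ascontiguousarray(a)))
    eff = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(a[i])
        if nb.size < 2:
            continue
        sub = a[np.ix_(nb, nb)]
        eff[i] = _efficiency_from_distances(_distance_matrix(sub))
    return float(eff.mean())


def nodal_efficiency(G) -> np.ndarray:
    """E_nod(i) = (1/(N-1)) * sum_j 1/d(i, j): the inverse harmonic mean of a
    node's shortest-path distances to all other nodes.  Isolated nodes get 0.
    """
    a = _adj(G)
    n = a.shape[0]
    if n < 2:
        return np.zeros(n)
    d = _distance_matrix(a)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1) / (n - 1)


def betweenness_centrality(G) -> np.ndarray:
    """Unnormalized shortest-path betweenness.

    For each node v: sum over unordered pairs {s, t} (s, t != v) of
    sigma_st(v) / sigma_st, where sigma counts shortest paths.
    """
    import igraph as ig

    a = _adj(G)
    n = a.shape[0]
    edges = np.argwhere(np.triu(a, k=1))
    g = ig.Graph(n=n, edges=[tuple(e) for e in edges], directed=False)
    return np.asarray(g.betweenness(), dtype=float)


@njit(cache=True)
def _bfs_all_pairs(adj):  # pragma: no cover - numba
    """Dense all-pairs BFS distances; -1 marks disconnected pairs."""
    n = adj.shape[0]
    dist = np.full((n, n), -1, dtype=np.int32)
    queue = np.empty(n, dtype=np.int32)
    for s in range(n):
        dist[s, s] = 0
        queue[0] = s
        head = 0
        tail = 1
        while head < tail:
            u = queue[head]
            head += 1
            du = dist[s, u]
            for v in range(n):
                if adj[u, v] == 1 and dist[s, v] < 0:
                    dist[s, v] = du + 1
                    queue[tail] = v
                    tail += 1
    return dist


@njit(cache=True)
def _swap_kernel(adj, edges, picks, flips):  # pragma: no cover - numba
    """In-place double-edge swaps; returns the number of accepted swaps."""
    n_ok = 0
    for t in range(picks.shape[0]):
        e1 = picks[t, 0]
        e2 = picks[t, 1]
        if e1 == e2:
            continue
        a = edges[e1, 0]
        b = edges[e1, 1]
        c = edges[e2, 0]
        d = edges[e2, 1]
        if flips[t] == 1:
            c, d = d, c
        # propose replacing (a,b),(c,d) with (a,d),(c,b)
        if a == d or c == b:
            continue
        if adj[a, d] == 1 or adj[c, b] == 1:
            continue
        adj[a, b] = 0
        adj[b, a] = 0
        adj[c, d] = 0
        adj[d, c] = 0
        adj[a, d] = 1
        adj[d, a] = 1
        adj[c, b] = 1
        adj[b, c] = 1
        edges[e1, 0] = a
        edges[e1, 1] = d
        edges[e2, 0] = c
        edges[e2, 1] = b
        n_ok += 1
    return n_ok


def _randomized_copy(a: np.ndarray, edges: np.ndarray, swaps_per_edge: int,
                     rng: np.random.Generator) -> tuple[np.ndarray, int]:
    adj = a.copy()
    e = edges.copy()
    attempts = swaps_per_edge * e.shape[0]
    picks = rng.integers(0, e.shape[0], size=(attempts, 2))
    flips = rng.integers(0, 2, size=attempts)
    n_ok = _swap_kernel(adj, e, picks, flips)
    return adj, int(n_ok)


def null_ensemble(G, m: int = 100, seed=None, swaps_per_edge: int = 10) -> NullEnsemble:
    """M degree-preserving randomizations via repeated double-edge swaps.

    Each member attempts ``swaps_per_edge * |E|`` swaps, rejecting proposals
    that would create self-loops or multi-edges.  Graphs admitting no valid
    swap (e.g. stars) come back as verbatim copies with ``degenerate=True``.
    """
    a = _adj(G)
    edges = np.argwhere(np.triu(a, k=1)).astype(np.int64)
    if edges.shape[0] < 2:
        raise ValueError("null ensemble requires a graph with at least 2 edges")
    rng = np.random.default_rng(seed)
    members: list[np.ndarray] = []
    total_ok = 0
    for _ in range(m):
        adj, n_ok = _randomized_copy(a, edges, swaps_per_edge, rng)
        members.append(adj)
        total_ok += n_ok
    return NullEnsemble(
        members=members,
        n_networks=m,
        swaps_per_edge=swaps_per_edge,
        seed=seed,
        degenerate=(total_ok == 0),
    )


def small_world_indices(G, ensemble: NullEnsemble) -> tuple[float, float, float]:
    """gamma = C/mean(C_null), lambda = L/mean(L_null), sigma = gamma/lambda.

    L uses the connected-pairs convention in both the real network and the
    nulls.  A degenerate ensemble (zero mean null clustering or path length)
    raises.
    """
    if not ensemble.members:
        raise ValueError("empty null ensemble")
    _, c_real = clustering_coefficient(G)
    l_real = _char_path_length(_adj(G))
    c_null = np.array([clustering_coefficient(mbr)[1] for mbr in ensemble.members])
    l_null = np.array([_char_path_length(mbr) for mbr in ensemble.members])
    c_bar = float(np.nanmean(c_null))
    l_bar = float(np.nanmean(l_null))
    if c_bar == 0.0 or l_bar == 0.0 or not np.isfinite(c_bar) or not np.isfinite(l_bar):
        raise ValueError("degenerate null ensemble: zero mean clustering or path length")
    gamma = c_real / c_bar
    lam = l_real / l_bar
    return float(gamma), float(lam), float(gamma / lam)


def global_metrics(G, null_m: int = 100, seed=None, swaps_per_edge: int = 10,
                   ensemble: NullEnsemble | None = None) -> GlobalMetrics:
    """All whole-network properties of one binary network.

    Builds (or reuses) a degree-preserving null ensemble for the normalized
    indices; gamma/lambda/sigma come back NaN for graphs too degenerate to
    normalize (fewer than 2 edges, or a null with no triangles).
    """
    a = _adj(G)
    _, c_mean = clustering_coefficient(a)
    d = _distance_matrix(a)
    n = a.shape[0]
    off = ~np.eye(n, dtype=bool)
    dv = d[off]
    finite = np.isfinite(dv)
    L = float(dv[finite].mean()) if finite.any() else float("nan")
    frac_disc = 1.0 - float(finite.mean()) if n > 1 else 0.0
    e_glob = _efficiency_from_distances(d)
    e_loc = local_efficiency(a)
    gamma = lam = sigma = float("nan")
    try:
        if ensemble is None:
            ensemble = null_ensemble(a, m=null_m, seed=seed, swaps_per_edge=swaps_per_edge)
        gamma, lam, sigma = small_world_indices(a, ensemble)
    except ValueError:
        pass
    return GlobalMetrics(
        clustering_mean=c_mean,
        path_length=L,
        gamma=gamma,
        lam=lam,
        sigma=sigma,
        e_glob=e_glob,
        e_loc=e_loc,
        disconnected_pair_fraction=frac_disc,
    )


def nodal_metrics(G) -> NodalMetrics:
    """Per-region nodal efficiency and betweenness of one binary network."""
    return NodalMetrics(
        e_nod=nodal_efficiency(G),
        betweenness=betweenness_centrality(G),
    )
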