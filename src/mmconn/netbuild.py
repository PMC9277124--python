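"""Connectivity-matrix construction and threshold-based binarization.

The functional arm turns per-region BOLD-like time series into a Fisher-Z
correlation matrix; the structural arm validates externally supplied
FA-weighted (fractional anisotropy, a 0-1 diffusion measure) adjacency
matrices.  Both are reduced to undirected, unweighted graphs either by a
sparsity threshold (keep the strongest fraction of all possible edges) or by
an absolute FA cutoff, and swept over a threshold range so that downstream
metrics can be examined as a function of network density.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TimeSeriesMatrix",
    "ConnectivityMatrix",
    "BinaryNetwork",
    "functional_connectivity",
    "validate_structural",
    "binarize_sparsity",
    "binarize_fa",
    "threshold_sweep",
    "default_sparsity_thresholds",
    "default_fa_thresholds",
    "read_matrix_tsv",
    "write_matrix_tsv",
]

#: Pearson r is clamped to +/- this value before the Fisher transform so that
#: perfectly (anti)correlated inputs map to a finite Z-score.
FISHER_CLAMP = 1.0 - 1e-7

#: Maximum tolerated asymmetry in a structural input before it is rejected
#: (smaller asymmetries are repaired by averaging the two triangles).
STRUCTURAL_ASYMMETRY_TOL = 1e-8


def _as_labels(labels, n: int) -> list[str]:
    if labels is None:
        width = len(str(n))
        return [f"R{i:0{width}d}" for i in range(n)]
    labels = [str(x) for x in labels]
    if len(labels) != n:
        raise ValueError(f"expected {n} region labels, got {len(labels)}")
    return labels


@dataclass
class TimeSeriesMatrix:
    """Per-subject ROI signals: a regions x timepoints real matrix."""

    values: np.ndarray
    region_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D (regions x timepoints) matrix")
        if self.values.shape[1] < 2:
            raise ValueError("time series needs at least 2 timepoints")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains non-finite values")
        self.region_labels = _as_labels(self.region_labels, self.values.shape[0])

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    def zero_variance_regions(self) -> list[str]:
        """Labels of regions with constant signal."""
        span = np.ptp(self.values, axis=1)
        return [lab for lab, s in zip(self.region_labels, span) if s == 0.0]


@dataclass
class ConnectivityMatrix:
    """Symmetric weighted adjacency.

    ``mode='functional'`` holds Fisher-Z transformed correlations (any sign);
    ``mode='structural'`` holds FA weights in [0, 1).
    """

    values: np.ndarray
    mode: str
    region_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mode not in ("functional", "structural"):
            raise ValueError(f"unknown mode {self.mode!r}")
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if np.abs(v - v.T).max(initial=0.0) > 1e-10:
            raise ValueError("connectivity matrix not symmetric within 1e-10")
        if np.abs(np.diag(v)).max(initial=0.0) != 0.0:
            raise ValueError("connectivity matrix diagonal must be zero")
        if self.mode == "structural":
            off = v[~np.eye(v.shape[0], dtype=bool)]
            if off.size and (off.min() < 0.0 or off.max() >= 1.0):
                raise ValueError("structural weights must lie in [0, 1)")
        self.region_labels = _as_labels(self.region_labels, v.shape[0])

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass
class BinaryNetwork:
    """Thresholded undirected, unweighted graph with threshold provenance."""

    adjacency: np.ndarray
    threshold_kind: str  # 'sparsity' | 'fa'
    threshold_value: float
    mode: str  # source connectivity mode
    region_labels: list[str] | None = None
    #: True when a sparsity target could not be met because too few positive
    #: weights were available.
    shortfall: bool = False

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        a = (a != 0).astype(np.uint8)
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.diag(a).any():
            raise ValueError("adjacency diagonal must be zero")
        self.adjacency = a
        self.region_labels = _as_labels(self.region_labels, a.shape[0])

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def density(self) -> float:
        n = self.n_nodes
        return 0.0 if n < 2 else self.n_edges / (n * (n - 1) / 2)

    def edge_list(self) -> np.ndarray:
        """(E, 2) array of 0-based (i, j) pairs with i < j."""
        return np.argwhere(np.triu(self.adjacency, k=1))


def functional_connectivity(ts: TimeSeriesMatrix) -> ConnectivityMatrix:
    """Pairwise Pearson correlation of region time series, Fisher-Z transformed.

    r is clamped to +/-(1 - 1e-7) before atanh so degenerate (perfectly
    correlated) pairs stay finite; the diagonal is set to zero.
    """
    bad = ts.zero_variance_regions()
    if bad:
        raise ValueError(
            "correlation undefined for zero-variance regions: " + ", ".join(bad)
        )
    r = np.corrcoef(ts.values)
    r = np.clip(r, -FISHER_CLAMP, FISHER_CLAMP)
    z = np.arctanh(r)
    z = (z + z.T) / 2.0  # scrub float asymmetry from corrcoef
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(z, mode="functional", region_labels=ts.region_labels)


def validate_structural(matrix, region_labels=None) -> ConnectivityMatrix:
    """Validate an FA-weighted matrix: square, near-symmetric, entries in [0, 1).

    Asymmetries up to 1e-8 are repaired by averaging the two triangles; the
    diagonal is zeroed unconditionally.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("structural matrix must be square")
    if not np.all(np.isfinite(m)):
        raise ValueError("structural matrix contains non-finite values")
    asym = np.abs(m - m.T).max(initial=0.0)
    if asym > STRUCTURAL_ASYMMETRY_TOL:
        raise ValueError(f"structural matrix asymmetry {asym:.3g} exceeds tolerance")
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 0.0)
    off_mask = ~np.eye(m.shape[0], dtype=bool)
    bad = np.argwhere(off_mask & ((m < 0.0) | (m >= 1.0)))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"{bad.shape[0]} FA entries outside [0, 1); first at ({i}, {j}) = {m[i, j]:.4g}"
        )
    return ConnectivityMatrix(m, mode="structural", region_labels=region_labels)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def binarize_sparsity(C: ConnectivityMatrix, s: float) -> BinaryNetwork:
    """Keep the K = round(s * N(N-1)/2) strongest positive weights as edges.

    Only positive Fisher-Z weights are ranked; negative correlations never
    form edges.  If fewer than K positive weights exist the network keeps all
    of them and is flagged (``shortfall=True``).  Ties at the cutoff are
    broken by lexicographic (i, j) order for determinism.
    """
    if not 0.0 < s < 1.0:
        raise ValueError(f"sparsity must be in (0, 1), got {s}")
    if C.mode != "functional":
        raise ValueError("sparsity binarization expects a functional matrix")
    n = C.n_regions
    iu, ju = np.triu_indices(n, k=1)
    w = C.values[iu, ju]
    k_target = _round_half_up(s * n * (n - 1) / 2.0)
    pos = w > 0.0
    iu, ju, w = iu[pos], ju[pos], w[pos]
    # primary key: weight descending; then i, then j ascending
    order = np.lexsort((ju, iu, -w))
    keep = order[:k_target]
    shortfall = w.size < k_target
    adj = np.zeros((n, n), dtype=np.uint8)
    adj[iu[keep], ju[keep]] = 1
    adj |= adj.T
    return BinaryNetwork(
        adj,
        threshold_kind="sparsity",
        threshold_value=float(s),
        mode=C.mode,
        region_labels=C.region_labels,
        shortfall=shortfall,
    )


def binarize_fa(C: ConnectivityMatrix, t: float) -> BinaryNetwork:
    """Edge (i, j) present iff FA weight strictly exceeds the threshold t."""
    if not 0.0 < t < 1.0:
        raise ValueError(f"FA threshold must be in (0, 1), got {t}")
    if C.mode != "structural":
        raise ValueError("FA binarization expects a structural matrix")
    adj = (C.values > t).astype(np.uint8)
    np.fill_diagonal(adj, 0)
    return BinaryNetwork(
        adj,
        threshold_kind="fa",
        threshold_value=float(t),
        mode=C.mode,
        region_labels=C.region_labels,
    )


def default_sparsity_thresholds() -> np.ndarray:
    """Sparsity sweep 26%..50% in steps of 1% (25 networks)."""
    return np.round(np.arange(26, 51) / 100.0, 2)


def default_fa_thresholds() -> np.ndarray:
    """FA sweep 0.20..0.42 in steps of 0.02 (12 networks)."""
    return np.round(np.arange(20, 43, 2) / 100.0, 2)


def threshold_sweep(C: ConnectivityMatrix, kind: str, thresholds=None) -> list[BinaryNetwork]:
    """Binarize one connectivity matrix at every threshold of a sweep.

    Sparsity sweeps are nested by construction: the edge set at a lower
    sparsity is a subset of the edge set at any higher sparsity.
    """
    if kind == "sparsity":
        if thresholds is None:
            thresholds = default_sparsity_thresholds()
        return [binarize_sparsity(C, float(s)) for s in thresholds]
    if kind == "fa":
        if thresholds is None:
            thresholds = default_fa_thresholds()
        return [binarize_fa(C, float(t)) for t in thresholds]
    raise ValueError(f"unknown threshold kind {kind!r}")


def read_matrix_tsv(path) -> np.ndarray:
    """Read a plain tab-delimited numeric matrix (no header, '.' decimal)."""
    m = np.loadtxt(path, delimiter="\t", ndmin=2)
    return m


def write_matrix_tsv(path, matrix: np.ndarray) -> None:
    np.savetxt(path, np.asarray(matrix, dtype=float), delimiter="\t", fmt="%.10g")
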