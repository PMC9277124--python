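"""Node-attack resilience: global-efficiency decay under node deletion.

Resilience is probed by deleting nodes one at a time — either in descending
order of betweenness computed once on the intact network (targeted attack)
or in uniformly random order averaged over replicates (random attack) — and
recording global efficiency after each deletion.

Deleted nodes are *isolated* rather than removed: the node set and the
efficiency denominator N(N-1) stay fixed for the whole curve, so values are
comparable across steps and the targeted curve is monotone non-increasing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graphmetrics import _adj, _distance_matrix, betweenness_centrality

__all__ = ["AttackCurve", "targeted_attack", "random_attack", "attack_auc"]


@dataclass
class AttackCurve:
    """Global efficiency after 0..N node deletions (fractions of N removed)."""

    removal_fractions: np.ndarray
    efficiency: np.ndarray
    attack_kind: str  # 'targeted' | 'random'
    replicates: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        self.removal_fractions = np.asarray(self.removal_fractions, dtype=float)
        self.efficiency = np.asarray(self.efficiency, dtype=float)
        if self.removal_fractions.shape != self.efficiency.shape:
            raise ValueError("removal_fractions and efficiency lengths differ")


def _fixed_denominator_efficiency(a: np.ndarray, n_total: int) -> float:
    """Sum of 1/d over ordered pairs of the full node set / (N(N-1))."""
    if n_total < 2 or not a.any():
        return 0.0
    d = _distance_matrix(a)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n_total * (n_total - 1)))


def _attack_curve(a: np.ndarray, order: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    work = a.copy()
    eff = np.empty(n + 1)
    eff[0] = _fixed_denominator_efficiency(work, n)
    for step, node in enumerate(order, start=1):
        work[node, :] = 0
        work[:, node] = 0
        eff[step] = _fixed_denominator_efficiency(work, n) if work.any() else 0.0
    return eff


def targeted_attack(G) -> AttackCurve:
    """Delete nodes in descending betweenness order (computed once, on the
    intact network; ties broken by ascending node index) and record global
    efficiency after each deletion.
    """
    a = _adj(G)
    n = a.shape[0]
    btw = betweenness_centrality(a)
    order = np.lexsort((np.arange(n), -btw))
    eff = _attack_curve(a, order)
    return AttackCurve(
        removal_fractions=np.arange(n + 1) / n,
        efficiency=eff,
        attack_kind="targeted",
    )


def random_attack(G, replicates: int = 100, seed=None) -> AttackCurve:
    """Delete nodes in uniformly random order; average efficiency across
    replicates at each step.  Deterministic given the seed.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    a = _adj(G)
    n = a.shape[0]
    rng = np.random.default_rng(seed)
    acc = np.zeros(n + 1)
    for _ in range(replicates):
        order = rng.permutation(n)
        acc += _attack_curve(a, order)
    return AttackCurve(
        removal_fractions=np.arange(n + 1) / n,
        efficiency=acc / replicates,
        attack_kind="random",
        replicates=replicates,
        seed=seed,
    )


def attack_auc(curve: AttackCurve) -> float:
    """Trapezoidal area under efficiency vs removal fraction, normalized by
    the intact-network efficiency.  0 for an initially empty network.
    """
    e0 = curve.efficiency[0]
    if e0 == 0.0:
        return 0.0
    return float(np.trapezoid(curve.efficiency, curve.removal_fractions) / e0)
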