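"""Group inference: permutation tests, BH-FDR correction, score correlation.

The group statistic is the difference of group means (patient minus
control).  Two-sided p-values use the add-one convention
p = (#{|perm| >= |observed|} + 1) / (n_perm + 1), so no reported p can fall
below 1/(n_perm + 1) and a permutation test can never return an exact zero.

Multiplicity is handled per family with Benjamini-Hochberg step-up FDR:
across the thresholds of one global metric within one modality, and across
all regions for nodal tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupComparisonResult",
    "ClinicalCorrelation",
    "permutation_test",
    "permutation_test_many",
    "sweep_comparison",
    "nodal_comparison",
    "fdr_bh",
    "clinical_correlation",
    "comparisons_to_frame",
]

_CMP_TOL = 1e-12  # guards >= comparisons against float round-off


@dataclass
class GroupComparisonResult:
    """One permutation comparison (patient mean minus control mean)."""

    metric: str
    threshold_kind: str
    threshold: float
    region: str | None
    observed_diff: float
    p_perm: float
    p_fdr: float
    significant: bool
    patient_mean: float
    patient_sd: float
    control_mean: float
    control_sd: float


@dataclass
class ClinicalCorrelation:
    """Pearson correlation of one region's metric with the clinical score."""

    region: str
    r: float
    p: float
    n: int


def _perm_indices(n: int, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """(n_perm, n) array of permutation index rows."""
    return np.argsort(rng.random((n_perm, n)), axis=1)


def permutation_test_many(values: np.ndarray, n_a: int, n_perm: int,
                          seed=None) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized permutation tests for m variables sharing one label vector.

    ``values`` is (m, n) with the first ``n_a`` columns from group A.  The
    same label permutations are applied to every row, the standard choice
    when testing many network metrics on one subject sample.  Returns
    (observed diffs, two-sided p-values), each of length m.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    m, n = values.shape
    if not 0 < n_a < n:
        raise ValueError("both groups must be nonempty")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    obs = values[:, :n_a].mean(axis=1) - values[:, n_a:].mean(axis=1)
    rng = np.random.default_rng(seed)
    idx = _perm_indices(n, n_perm, rng)
    perm_vals = values[:, idx]  # (m, n_perm, n)
    diffs = perm_vals[:, :, :n_a].mean(axis=2) - perm_vals[:, :, n_a:].mean(axis=2)
    exceed = (np.abs(diffs) >= np.abs(obs)[:, None] - _CMP_TOL).sum(axis=1)
    p = (exceed + 1.0) / (n_perm + 1.0)
    return obs, p


def permutation_test(a, b, n_perm: int, seed=None) -> tuple[float, float]:
    """Two-sided permutation test of the difference of group means.

    Group labels are shuffled ``n_perm`` times;
    p = (#{|perm| >= |observed|} + 1) / (n_perm + 1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])[None, :]
    obs, p = permutation_test_many(pooled, a.size, n_perm, seed=seed)
    return float(obs[0]), float(p[0])


def fdr_bh(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR.

    Returns (adjusted p-values, rejection mask at level q).  Adjusted values
    are monotone by the cumulative-minimum-from-the-largest-rank rule.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def _group_arrays(frame: pd.DataFrame, value_col: str = "value") -> tuple[np.ndarray, np.ndarray]:
    pat = frame.loc[frame["group"] == "patient", value_col].to_numpy(dtype=float)
    con = frame.loc[frame["group"] == "control", value_col].to_numpy(dtype=float)
    return pat, con


def _one_result(metric, kind, thr, region, pat, con, n_perm, seed) -> GroupComparisonResult:
    obs, p = permutation_test(pat, con, n_perm=n_perm, seed=seed)
    return GroupComparisonResult(
        metric=metric,
        threshold_kind=kind,
        threshold=float(thr),
        region=region,
        observed_diff=obs,
        p_perm=p,
        p_fdr=np.nan,
        significant=False,
        patient_mean=float(pat.mean()),
        patient_sd=float(pat.std(ddof=1)) if pat.size > 1 else 0.0,
        control_mean=float(con.mean()),
        control_sd=float(con.std(ddof=1)) if con.size > 1 else 0.0,
    )


def _apply_fdr(results: list[GroupComparisonResult], q: float) -> list[GroupComparisonResult]:
    if not results:
        return results
    p_adj, reject = fdr_bh([r.p_perm for r in results], q=q)
    for r, pa, rej in zip(results, p_adj, reject):
        r.p_fdr = float(pa)
        r.significant = bool(rej)
    return results


def _check_complete(table: pd.DataFrame, keys: list[str]) -> None:
    counts = table.groupby(keys, observed=True)["subject_id"].nunique()
    n_subj = table["subject_id"].nunique()
    missing = counts[counts != n_subj]
    if len(missing):
        raise ValueError(
            "missing subject/threshold combinations for: "
            + ", ".join(str(ix) for ix in missing.index[:10])
        )


def sweep_comparison(table: pd.DataFrame, metric: str, n_perm: int = 5000,
                     seed=None, q: float = 0.05) -> list[GroupComparisonResult]:
    """Patient-vs-control permutation test of one global metric at every
    threshold of a sweep, BH-FDR corrected across the thresholds.

    ``table`` is a long-format metric table for one modality with columns
    subject_id, group, threshold_kind, threshold, metric, value.
    """
    sub = table[table["metric"] == metric]
    if sub.empty:
        raise ValueError(f"metric {metric!r} not present in table")
    kinds = sub["threshold_kind"].unique()
    if len(kinds) != 1:
        raise ValueError("sweep_comparison expects a single threshold kind")
    _check_complete(sub, ["threshold"])
    rng = np.random.default_rng(seed)
    results = []
    for thr in sorted(sub["threshold"].unique()):
        frame = sub[sub["threshold"] == thr]
        pat, con = _group_arrays(frame)
        results.append(
            _one_result(metric, kinds[0], thr, None, pat, con, n_perm,
                        int(rng.integers(2**31)))
        )
    return _apply_fdr(results, q)


def nodal_comparison(table: pd.DataFrame, n_perm: int = 5000, seed=None,
                     q: float = 0.05) -> list[GroupComparisonResult]:
    """Region-wise permutation tests of a nodal metric at one fixed
    threshold, BH-FDR corrected across regions; results ordered by p.

    ``table`` holds one metric at one threshold with columns subject_id,
    group, threshold_kind, threshold, metric, region, value.
    """
    thrs = table["threshold"].unique()
    if len(thrs) != 1:
        raise ValueError("nodal_comparison expects exactly one threshold")
    metrics = table["metric"].unique()
    if len(metrics) != 1:
        raise ValueError("nodal_comparison expects exactly one metric")
    _check_complete(table, ["region"])
    kind = table["threshold_kind"].iloc[0]
    # shared permutations across regions: one label shuffle per iteration
    pivot = table.pivot_table(index="region", columns="subject_id",
                              values="value", sort=True)
    groups = table.drop_duplicates("subject_id").set_index("subject_id")["group"]
    pat_ids = [s for s in pivot.columns if groups[s] == "patient"]
    con_ids = [s for s in pivot.columns if groups[s] == "control"]
    ordered = pivot[pat_ids + con_ids].to_numpy(dtype=float)
    obs, p = permutation_test_many(ordered, len(pat_ids), n_perm, seed=seed)
    results = []
    for i, region in enumerate(pivot.index):
        pat = ordered[i, : len(pat_ids)]
        con = ordered[i, len(pat_ids):]
        results.append(
            GroupComparisonResult(
                metric=metrics[0],
                threshold_kind=kind,
                threshold=float(thrs[0]),
                region=str(region),
                observed_diff=float(obs[i]),
                p_perm=float(p[i]),
                p_fdr=np.nan,
                significant=False,
                patient_mean=float(pat.mean()),
                patient_sd=float(pat.std(ddof=1)) if pat.size > 1 else 0.0,
                control_mean=float(con.mean()),
                control_sd=float(con.std(ddof=1)) if con.size > 1 else 0.0,
            )
        )
    results = _apply_fdr(results, q)
    return sorted(results, key=lambda r: (r.p_perm, r.region))


def clinical_correlation(region_values: pd.DataFrame, scores,
                         regions=None) -> list[ClinicalCorrelation]:
    """Pearson correlation between per-subject regional values and clinical
    scores, per region.

    ``region_values`` is (subjects x regions); intended use is the patient
    group only, restricted to regions flagged by the nodal comparison.
    """
    scores = np.asarray(scores, dtype=float)
    if len(scores) != len(region_values):
        raise ValueError("one score per subject required")
    if len(scores) < 3:
        raise ValueError("correlation requires at least 3 subjects")
    if scores.std() == 0.0:
        raise ValueError("clinical scores have zero variance; correlation undefined")
    cols = list(region_values.columns) if regions is None else list(regions)
    out = []
    for region in cols:
        x = region_values[region].to_numpy(dtype=float)
        r, p = sps.pearsonr(x, scores)
        out.append(ClinicalCorrelation(region=str(region), r=float(r),
                                       p=float(p), n=len(scores)))
    return out


def comparisons_to_frame(results: list[GroupComparisonResult]) -> pd.DataFrame:
    """Flatten comparison results to a DataFrame (Table-style output)."""
    return pd.DataFrame(
        {
            "metric": [r.metric for r in results],
            "threshold_kind": [r.threshold_kind for r in results],
            "threshold": [r.threshold for r in results],
            "region": [r.region if r.region is not None else "" for r in results],
            "patient_mean": [r.patient_mean for r in results],
            "patient_sd": [r.patient_sd for r in results],
            "control_mean": [r.control_mean for r in results],
            "control_sd": [r.control_sd for r in results],
            "observed_diff": [r.observed_diff for r in results],
            "p_perm": [r.p_perm for r in results],
            "p_fdr": [r.p_fdr for r in results],
            "significant": [r.significant for r in results],
        }
    )
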