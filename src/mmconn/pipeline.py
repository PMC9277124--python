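"""End-to-end orchestration: cohort -> networks -> metrics -> inference.

A run is described by a :class:`RunConfig` (synthetic cohort or an existing
manifest, threshold sweeps, fixed thresholds for nodal/attack analyses,
permutation and null-model settings, master seed, output directory).  All
randomness is derived deterministically from the master seed and stable
indices (stage, subject, threshold), so reruns with the same config are
byte-identical and stages can be rerun in isolation.

Outputs (tab-separated, fixed column order, ``%.12g`` floats):

* ``metrics_global.tsv``  — subject x threshold global properties (long)
* ``metrics_nodal.tsv``   — subject x region nodal properties at the fixed
  thresholds (long)
* ``comparisons.tsv``     — per-threshold group permutation tests, FDR per
  metric/modality family
* ``nodal_comparisons.tsv`` — per-region tests at the fixed thresholds,
  FDR across regions
* ``attack_curves.tsv``, ``attack_group_curves.tsv``, ``attack_auc.tsv``
* ``correlations.tsv``    — patient-only score correlations for flagged
  regions
* ``summary.json``        — config hash, seeds, significant-finding counts
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._version import __version__
from .graphmetrics import global_metrics, nodal_metrics
from .manifest import SubjectRecord, read_manifest
from .netbuild import (
    ConnectivityMatrix,
    TimeSeriesMatrix,
    binarize_fa,
    binarize_sparsity,
    default_fa_thresholds,
    default_sparsity_thresholds,
    functional_connectivity,
    read_matrix_tsv,
    threshold_sweep,
    validate_structural,
    write_matrix_tsv,
)
from .resilience import attack_auc, random_attack, targeted_attack
from .stats import (
    clinical_correlation,
    comparisons_to_frame,
    nodal_comparison,
    permutation_test,
    sweep_comparison,
)
from .synthdata import CohortConfig, write_cohort

__all__ = ["RunConfig", "RunResult", "run_pipeline"]

GLOBAL_COMPARISON_METRICS = ["gamma", "lambda", "sigma", "e_loc", "e_glob"]

# stage tags mixed into per-call RNG seeds
_ST_METRICS = 1
_ST_COMPARE = 2
_ST_ATTACK = 3

_FLOAT_FMT = "%.12g"


@dataclass
class RunConfig:
    """Everything needed to reproduce one analysis run."""

    outdir: str
    cohort: CohortConfig | None = None
    manifest_path: str | None = None
    sparsity_thresholds: tuple[float, ...] = tuple(default_sparsity_thresholds())
    fa_thresholds: tuple[float, ...] = tuple(default_fa_thresholds())
    fixed_sparsity: float = 0.26
    fixed_fa: float = 0.42
    n_perm: int = 5000
    q: float = 0.05
    null_m: int = 100
    swaps_per_edge: int = 10
    attack_replicates: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.cohort is None) == (self.manifest_path is None):
            raise ValueError("provide exactly one of cohort config or manifest path")
        for t in (*self.sparsity_thresholds, *self.fa_thresholds,
                  self.fixed_sparsity, self.fixed_fa):
            if not 0.0 < t < 1.0:
                raise ValueError(f"thresholds must lie in (0, 1), got {t}")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not 0.0 < self.q < 1.0:
            raise ValueError("q must be in (0, 1)")
        if self.null_m < 1 or self.attack_replicates < 1:
            raise ValueError("null_m and attack_replicates must be >= 1")

    @classmethod
    def reduced(cls, outdir, seed: int = 0, **overrides) -> "RunConfig":
        """Reduced-scale profile: 60-region synthetic cohort, 1,000
        permutations, 10-network null ensembles, 25 attack replicates."""
        kwargs = dict(
            outdir=str(outdir),
            cohort=CohortConfig.reduced(seed=seed),
            n_perm=1000,
            null_m=10,
            attack_replicates=25,
            seed=seed,
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("outdir")
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunResult:
    """In-memory view of a pipeline run's outputs."""

    outdir: Path
    records: list[SubjectRecord]
    metrics_global: pd.DataFrame
    metrics_nodal: pd.DataFrame
    comparisons: pd.DataFrame
    nodal_comparisons: pd.DataFrame
    attack_curves: pd.DataFrame
    attack_group_curves: pd.DataFrame
    attack_auc: pd.DataFrame
    correlations: pd.DataFrame
    summary: dict


def _seed(config: RunConfig, *parts: int) -> list[int]:
    return [config.seed, *parts]


def load_subject_data(
    records: list[SubjectRecord],
) -> dict[str, list[ConnectivityMatrix]]:
    """Read every subject's files and build connectivity matrices per arm.

    A modality is included only when every subject provides its file.
    """
    out: dict[str, list[ConnectivityMatrix]] = {}
    if all(r.ts_path for r in records):
        out["functional"] = [
            functional_connectivity(TimeSeriesMatrix(read_matrix_tsv(r.ts_path)))
            for r in records
        ]
    if all(r.fa_path for r in records):
        out["structural"] = [
            validate_structural(read_matrix_tsv(r.fa_path)) for r in records
        ]
    if not out:
        raise ValueError("no modality is complete across all subjects")
    return out


def _modality_setup(config: RunConfig, modality: str):
    if modality == "functional":
        return "sparsity", list(config.sparsity_thresholds), config.fixed_sparsity
    return "fa", list(config.fa_thresholds), config.fixed_fa


def stage_metrics(
    records: list[SubjectRecord],
    conns: dict[str, list[ConnectivityMatrix]],
    config: RunConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject threshold sweeps: global metrics at every threshold plus
    nodal metrics (nodal efficiency, betweenness) at the fixed threshold."""
    grows, nrows = [], []
    for modality, matrices in conns.items():
        kind, thresholds, fixed = _modality_setup(config, modality)
        mod_ix = 0 if modality == "functional" else 1
        if fixed not in thresholds:
            raise ValueError(f"fixed {kind} threshold {fixed} must be in the sweep")
        for si, (rec, C) in enumerate(zip(records, matrices)):
            nets = threshold_sweep(C, kind, thresholds)
            for ti, net in enumerate(nets):
                gm = global_metrics(
                    net,
                    null_m=config.null_m,
                    swaps_per_edge=config.swaps_per_edge,
                    seed=_seed(config, _ST_METRICS, mod_ix, si, ti),
                )
                for metric, value in gm.as_dict().items():
                    grows.append(
                        (rec.subject_id, rec.group, modality, kind,
                         thresholds[ti], metric, value)
                    )
                if thresholds[ti] == fixed:
                    nm = nodal_metrics(net)
                    labels = C.region_labels
                    for region, e, b in zip(labels, nm.e_nod, nm.betweenness):
                        nrows.append(
                            (rec.subject_id, rec.group, modality, kind, fixed,
                             "e_nod", region, e)
                        )
                        nrows.append(
                            (rec.subject_id, rec.group, modality, kind, fixed,
                             "betweenness", region, b)
                        )
    gcols = ["subject_id", "group", "modality", "threshold_kind", "threshold",
             "metric", "value"]
    ncols = gcols[:5] + ["metric", "region", "value"]
    return pd.DataFrame(grows, columns=gcols), pd.DataFrame(nrows, columns=ncols)


def stage_compare(
    metrics_global: pd.DataFrame,
    metrics_nodal: pd.DataFrame,
    config: RunConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group permutation tests: each global metric across its sweep (FDR per
    metric/modality family) and nodal efficiency across regions at the fixed
    thresholds (FDR across regions)."""
    comp_frames, nodal_frames = [], []
    for mi, modality in enumerate(sorted(metrics_global["modality"].unique())):
        sub = metrics_global[metrics_global["modality"] == modality]
        for gi, metric in enumerate(GLOBAL_COMPARISON_METRICS):
            results = sweep_comparison(
                sub, metric, n_perm=config.n_perm,
                seed=_seed(config, _ST_COMPARE, 0, mi, gi), q=config.q,
            )
            frame = comparisons_to_frame(results)
            frame.insert(0, "modality", modality)
            comp_frames.append(frame)
        nsub = metrics_nodal[
            (metrics_nodal["modality"] == modality)
            & (metrics_nodal["metric"] == "e_nod")
        ]
        if not nsub.empty:
            results = nodal_comparison(
                nsub, n_perm=config.n_perm,
                seed=_seed(config, _ST_COMPARE, 1, mi), q=config.q,
            )
            frame = comparisons_to_frame(results)
            frame.insert(0, "modality", modality)
            nodal_frames.append(frame)
    return (
        pd.concat(comp_frames, ignore_index=True),
        pd.concat(nodal_frames, ignore_index=True),
    )


def stage_attack(
    records: list[SubjectRecord],
    conns: dict[str, list[ConnectivityMatrix]],
    config: RunConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Targeted and random attacks on each subject's fixed-threshold
    network, per-subject AUC, group-mean curves, and a group AUC test."""
    curve_rows, auc_rows = [], []
    summary: dict = {}
    for modality, matrices in conns.items():
        kind, _, fixed = _modality_setup(config, modality)
        mod_ix = 0 if modality == "functional" else 1
        binarize = binarize_sparsity if kind == "sparsity" else binarize_fa
        for si, (rec, C) in enumerate(zip(records, matrices)):
            net = binarize(C, fixed)
            curves = {
                "targeted": targeted_attack(net),
                "random": random_attack(
                    net,
                    replicates=config.attack_replicates,
                    seed=_seed(config, _ST_ATTACK, mod_ix, si),
                ),
            }
            for akind, curve in curves.items():
                for f, e in zip(curve.removal_fractions, curve.efficiency):
                    curve_rows.append(
                        (rec.subject_id, rec.group, modality, akind, f, e)
                    )
                auc_rows.append(
                    (rec.subject_id, rec.group, modality, akind, attack_auc(curve))
                )
    curves_df = pd.DataFrame(
        curve_rows,
        columns=["subject_id", "group", "modality", "attack_kind",
                 "fraction_removed", "efficiency"],
    )
    auc_df = pd.DataFrame(
        auc_rows, columns=["subject_id", "group", "modality", "attack_kind", "auc"]
    )
    group_df = (
        curves_df.groupby(
            ["modality", "attack_kind", "group", "fraction_removed"], observed=True
        )["efficiency"]
        .mean()
        .reset_index()
        .sort_values(["modality", "attack_kind", "group", "fraction_removed"])
        .reset_index(drop=True)
    )
    for (modality, akind), sub in auc_df.groupby(["modality", "attack_kind"],
                                                 observed=True):
        pat = sub.loc[sub["group"] == "patient", "auc"].to_numpy()
        con = sub.loc[sub["group"] == "control", "auc"].to_numpy()
        if pat.size and con.size:
            mod_ix = 0 if modality == "functional" else 1
            kind_ix = 0 if akind == "targeted" else 1
            obs, p = permutation_test(
                pat, con, n_perm=config.n_perm,
                seed=_seed(config, _ST_ATTACK, 9, mod_ix, kind_ix),
            )
            summary[f"{modality}_{akind}_auc_diff"] = obs
            summary[f"{modality}_{akind}_auc_p"] = p
    return curves_df, group_df, auc_df, summary


def stage_correlate(
    records: list[SubjectRecord],
    metrics_nodal: pd.DataFrame,
    nodal_comparisons: pd.DataFrame,
    config: RunConfig,
) -> pd.DataFrame:
    """Patient-only Pearson correlation between the clinical score and nodal
    efficiency of every region flagged by the nodal comparison."""
    scores = {r.subject_id: r.hamd for r in records if r.group == "patient"}
    rows = []
    have_scores = (
        len(scores) >= 3
        and all(v is not None for v in scores.values())
        and np.std(list(scores.values())) > 0
    )
    for modality in sorted(nodal_comparisons["modality"].unique()):
        flagged = nodal_comparisons[
            (nodal_comparisons["modality"] == modality)
            & nodal_comparisons["significant"]
        ]["region"].tolist()
        if not flagged or not have_scores:
            continue
        sub = metrics_nodal[
            (metrics_nodal["modality"] == modality)
            & (metrics_nodal["metric"] == "e_nod")
            & (metrics_nodal["subject_id"].isin(scores))
        ]
        pivot = sub.pivot_table(index="subject_id", columns="region",
                                values="value", sort=True)
        score_vec = [scores[s] for s in pivot.index]
        for cc in clinical_correlation(pivot, score_vec, flagged):
            rows.append((modality, cc.region, cc.r, cc.p, cc.n))
    return pd.DataFrame(rows, columns=["modality", "region", "r", "p", "n"])


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full analysis and write every artifact to the run
    directory.  Rerunning with an identical config is byte-identical."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.cohort is not None:
        cohort_dir = outdir / "cohort"
        write_cohort(config.cohort, cohort_dir)
        records = read_manifest(cohort_dir / "manifest.csv")
    else:
        records = read_manifest(config.manifest_path)
    if not any(r.group == "patient" for r in records) or not any(
        r.group == "control" for r in records
    ):
        raise ValueError("comparison runs need both patient and control subjects")

    conns = load_subject_data(records)
    metrics_global, metrics_nodal = stage_metrics(records, conns, config)
    comparisons, nodal_comparisons = stage_compare(metrics_global, metrics_nodal, config)
    attack_curves, attack_group, attack_aucs, attack_summary = stage_attack(
        records, conns, config
    )
    correlations = stage_correlate(records, metrics_nodal, nodal_comparisons, config)

    _write(metrics_global, outdir / "metrics_global.tsv")
    _write(metrics_nodal, outdir / "metrics_nodal.tsv")
    _write(comparisons, outdir / "comparisons.tsv")
    _write(nodal_comparisons, outdir / "nodal_comparisons.tsv")
    _write(attack_curves, outdir / "attack_curves.tsv")
    _write(attack_group, outdir / "attack_group_curves.tsv")
    _write(attack_aucs, outdir / "attack_auc.tsv")
    _write(correlations, outdir / "correlations.tsv")

    sig_counts = (
        comparisons[comparisons["significant"]]
        .groupby(["modality", "metric"], observed=True)
        .size()
    )
    summary = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "master_seed": config.seed,
        "n_subjects": len(records),
        "n_patients": sum(r.group == "patient" for r in records),
        "n_controls": sum(r.group == "control" for r in records),
        "modalities": sorted(conns),
        "significant_thresholds": {
            f"{m}_{g}": int(c) for (m, g), c in sig_counts.items()
        },
        "significant_regions": {
            m: int(
                (
                    nodal_comparisons[nodal_comparisons["modality"] == m][
                        "significant"
                    ]
                ).sum()
            )
            for m in sorted(nodal_comparisons["modality"].unique())
        },
        "attack": attack_summary,
        "n_correlations": int(len(correlations)),
    }
    (outdir / "summary.json").write_text(json.dumps(summary, sort_keys=True, indent=2))
    return RunResult(
        outdir=outdir,
        records=records,
        metrics_global=metrics_global,
        metrics_nodal=metrics_nodal,
        comparisons=comparisons,
        nodal_comparisons=nodal_comparisons,
        attack_curves=attack_curves,
        attack_group_curves=attack_group,
        attack_auc=attack_aucs,
        correlations=correlations,
        summary=summary,
    )


def write_connectivity(records: list[SubjectRecord], outdir) -> list[Path]:
    """The ``build`` stage as files: one Fisher-Z and/or validated-FA matrix
    TSV per subject."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for rec in records:
        if rec.ts_path:
            C = functional_connectivity(TimeSeriesMatrix(read_matrix_tsv(rec.ts_path)))
            p = outdir / f"{rec.subject_id}_fz.tsv"
            write_matrix_tsv(p, C.values)
            written.append(p)
        if rec.fa_path:
            C = validate_structural(read_matrix_tsv(rec.fa_path))
            p = outdir / f"{rec.subject_id}_fa.tsv"
            write_matrix_tsv(p, C.values)
            written.append(p)
    return written
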