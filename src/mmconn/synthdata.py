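"""Synthetic two-group cohorts with known, recoverable planted effects.

The generator emulates the study design the analysis pipeline targets: a
patient group (default 42) and a control group (default 38), each subject
carrying a regions x timepoints BOLD-like time-series matrix (functional
arm) and an FA-weighted symmetric connectivity matrix (structural arm),
plus a HAMD-like clinical score.

The shared backbone is a Watts-Strogatz small-world graph (ring lattice of
mean degree k, rewired with probability p), chosen because the downstream
analysis is framed around small-world indices.  Planted group effects:

* functional: correlations on edges incident to a set of affected regions
  are multiplied by an attenuation factor in patients.  Affected regions
  default to the highest-betweenness nodes of the backbone — the hub
  carriers of the rewired "shortcut" edges — so attenuation lengthens
  shortest paths, depresses the affected regions' nodal efficiency, and
  makes the patient networks more fragile under targeted attack;
* structural: the Beta-distributed FA mean is shifted on affected edges in
  patients;
* clinical: the score is a linear function of a designated region's nodal
  efficiency plus Gaussian noise, truncated at 0 and rounded to one decimal
  like a rating-scale total.

Everything is bit-deterministic given the config (including its seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from statsmodels.stats.correlation_tools import corr_clipped, corr_nearest

from .graphmetrics import betweenness_centrality, nodal_efficiency
from .manifest import SubjectRecord, write_manifest
from .netbuild import (
    ConnectivityMatrix,
    TimeSeriesMatrix,
    binarize_sparsity,
    functional_connectivity,
    write_matrix_tsv,
)

__all__ = [
    "FunctionalEffect",
    "StructuralEffect",
    "ScoreModel",
    "CohortConfig",
    "GroundTruth",
    "CohortGenerationError",
    "generate_functional_cohort",
    "generate_structural_cohort",
    "generate_clinical_scores",
    "write_cohort",
]

#: Eigenvalue floor used when projecting a target matrix to a valid
#: correlation matrix.
PD_EIGEN_FLOOR = 1e-8

#: Score model applied to control subjects when a cohort is written to disk:
#: healthy-range scores independent of network state.
CONTROL_SCORE_BASELINE = (2.5, 1.5)  # mean, SD

# independent deterministic RNG streams derived from the config seed
_STREAM_GRAPH = 0
_STREAM_FUNCTIONAL = 1
_STREAM_STRUCTURAL = 2
_STREAM_SCORES = 3


class CohortGenerationError(ValueError):
    """A cohort config that cannot produce a valid cohort."""


@dataclass(frozen=True)
class FunctionalEffect:
    """Planted functional effect: attenuate (factor < 1) or amplify
    (factor > 1) target correlations on edges incident to affected regions.

    ``regions=None`` selects the ``n_affected`` highest-betweenness backbone
    regions (ties by index).  ``factor=1`` or an empty region set is a no-op.
    """

    regions: tuple[int, ...] | None = None
    n_affected: int = 10
    factor: float = 0.3

    @property
    def is_noop(self) -> bool:
        return self.factor == 1.0 or (self.regions is not None and not self.regions)


@dataclass(frozen=True)
class StructuralEffect:
    """Planted structural effect: shift the FA Beta mean on affected edges."""

    regions: tuple[int, ...] | None = None
    n_affected: int = 10
    fa_shift: float = 0.05

    @property
    def is_noop(self) -> bool:
        return self.fa_shift == 0.0 or (self.regions is not None and not self.regions)


@dataclass(frozen=True)
class ScoreModel:
    """score = intercept + slope * reference + N(0, noise_sd), truncated at 0
    and rounded to one decimal.

    The reference is the nodal efficiency of a designated region
    (``reference_region=None`` designates the first affected region) at a
    fixed sparsity.  The default sparsity sits mid-sweep, where a lesioned
    hub is still connected so its nodal efficiency varies continuously
    across subjects; at the strictest threshold the lesion largely
    disconnects the hub, which is the deficit the nodal tests detect.  The
    default slope/intercept/noise are calibrated on the reduced 60-region
    profile to give a patient score mean near 9.9, SD near 4.9 and a
    generating score-reference correlation near 0.4.
    """

    slope: float = 28.0
    intercept: float = -4.9
    noise_sd: float = 4.5
    reference_region: int | None = None
    reference_sparsity: float = 0.38


@dataclass(frozen=True)
class CohortConfig:
    """Study-design constants for one synthetic cohort."""

    n_patients: int = 42
    n_controls: int = 38
    n_regions: int = 246
    n_timepoints: int = 230  # 240 acquired volumes minus 10 discarded
    base_graph: str = "watts_strogatz"
    mean_degree: int = 124
    p_rewire: float = 0.1
    edge_correlation: float = 0.4
    fn_effect: FunctionalEffect = field(default_factory=FunctionalEffect)
    sn_effect: StructuralEffect = field(default_factory=StructuralEffect)
    fa_mean: float = 0.35
    fa_concentration: float = 50.0
    score_model: ScoreModel = field(default_factory=ScoreModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_patients, self.n_controls, self.n_regions) < 2:
            raise ValueError("all counts must be >= 2")
        if self.n_timepoints < 20:
            raise ValueError("n_timepoints must be >= 20")
        if not 0.0 < self.edge_correlation < 1.0:
            raise ValueError("edge_correlation must be in (0, 1)")
        if not 0.0 < self.fa_mean < 1.0:
            raise ValueError("fa_mean must be in (0, 1)")
        if self.fa_concentration <= 0.0:
            raise ValueError("fa_concentration must be positive")
        if self.score_model.noise_sd < 0.0:
            raise ValueError("score noise SD must be >= 0")
        if self.base_graph != "watts_strogatz":
            raise ValueError(f"unknown base_graph {self.base_graph!r}")
        if not (2 <= self.mean_degree < self.n_regions and self.mean_degree % 2 == 0):
            raise ValueError("mean_degree must be even and in [2, n_regions)")
        if not 0.0 <= self.p_rewire <= 1.0:
            raise ValueError("p_rewire must be in [0, 1]")

    @classmethod
    def reduced(cls, seed: int = 0, n_regions: int = 60, **overrides) -> "CohortConfig":
        """A reduced-region profile (default 60 regions) preserving the group
        sizes and effect structure of the full design; backbone degree is
        scaled to keep the same edge density (about half of all pairs, so the
        sparsity sweep selects among backbone edges rather than noise)."""
        density = 124 / 245  # full-profile backbone density
        k = int(round(density * (n_regions - 1) / 2)) * 2
        kwargs = dict(n_regions=n_regions, mean_degree=max(k, 4), seed=seed)
        kwargs.update(overrides)
        return cls(**kwargs)

    def region_labels(self) -> list[str]:
        width = len(str(self.n_regions))
        return [f"R{i:0{width}d}" for i in range(self.n_regions)]


@dataclass
class GroundTruth:
    """Recovery oracle: what was planted, for downstream validation."""

    true_graph_patient: np.ndarray
    true_graph_control: np.ndarray
    affected_regions: tuple[int, ...]
    affected_edges: tuple[tuple[int, int], ...]
    score_slope: float

    def to_json(self, path) -> None:
        n = self.true_graph_control.shape[0]
        payload = {
            "n_regions": n,
            "affected_regions": list(self.affected_regions),
            "affected_edges": [list(e) for e in self.affected_edges],
            "score_slope": self.score_slope,
            "true_edges_control": np.argwhere(
                np.triu(self.true_graph_control, k=1)
            ).tolist(),
            "true_edges_patient": np.argwhere(
                np.triu(self.true_graph_patient, k=1)
            ).tolist(),
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        n = payload["n_regions"]

        def as_adj(edges):
            a = np.zeros((n, n), dtype=np.uint8)
            for i, j in edges:
                a[i, j] = a[j, i] = 1
            return a

        return cls(
            true_graph_patient=as_adj(payload["true_edges_patient"]),
            true_graph_control=as_adj(payload["true_edges_control"]),
            affected_regions=tuple(payload["affected_regions"]),
            affected_edges=tuple(tuple(e) for e in payload["affected_edges"]),
            score_slope=payload["score_slope"],
        )


def _rng(config: CohortConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _watts_strogatz(n: int, k: int, p: float, rng: np.random.Generator) -> np.ndarray:
    """Ring lattice of even degree k with each right-hand edge rewired to a
    uniformly random non-duplicate target with probability p."""
    adj = np.zeros((n, n), dtype=np.uint8)
    for d in range(1, k // 2 + 1):
        for i in range(n):
            j = (i + d) % n
            adj[i, j] = adj[j, i] = 1
    for d in range(1, k // 2 + 1):
        for i in range(n):
            j = (i + d) % n
            if rng.random() >= p:
                continue
            # rewire edge (i, j) to (i, t)
            candidates = np.flatnonzero(adj[i] == 0)
            candidates = candidates[candidates != i]
            if candidates.size == 0:
                continue
            t = int(rng.choice(candidates))
            adj[i, j] = adj[j, i] = 0
            adj[i, t] = adj[t, i] = 1
    return adj


def _affected_regions(adj: np.ndarray, regions, n_affected: int) -> tuple[int, ...]:
    if regions is not None:
        bad = [r for r in regions if not 0 <= r < adj.shape[0]]
        if bad:
            raise CohortGenerationError(f"affected regions out of range: {bad}")
        return tuple(int(r) for r in regions)
    btw = betweenness_centrality(adj)
    order = np.lexsort((np.arange(adj.shape[0]), -btw))
    return tuple(int(i) for i in sorted(order[:n_affected]))


def _incident_edges(adj: np.ndarray, regions: tuple[int, ...]) -> tuple[tuple[int, int], ...]:
    mask = np.zeros(adj.shape[0], dtype=bool)
    mask[list(regions)] = True
    edges = np.argwhere(np.triu(adj, k=1))
    keep = mask[edges[:, 0]] | mask[edges[:, 1]]
    return tuple((int(i), int(j)) for i, j in edges[keep])


def _project_to_correlation(target: np.ndarray, label: str) -> np.ndarray:
    """Project a symmetric target to a valid (positive-definite) correlation
    matrix: eigenvalue clipping at a small floor plus unit-diagonal
    renormalization, with a nearest-correlation fallback for stubborn cases.
    """
    repaired = corr_clipped(target, threshold=PD_EIGEN_FLOOR)
    try:
        np.linalg.cholesky(repaired)
        return repaired
    except np.linalg.LinAlgError:
        pass
    repaired = corr_nearest(target, threshold=PD_EIGEN_FLOOR, n_fact=200)
    try:
        np.linalg.cholesky(repaired)
    except np.linalg.LinAlgError as exc:
        raise CohortGenerationError(
            f"cannot repair {label} target correlation matrix to positive "
            f"definiteness; config is too aggressive"
        ) from exc
    return repaired


def _target_correlations(config: CohortConfig, backbone: np.ndarray,
                         affected: tuple[int, ...]) -> tuple[np.ndarray, np.ndarray]:
    r = config.edge_correlation
    base = np.eye(config.n_regions) + r * backbone.astype(float)
    control = _project_to_correlation(base, "control")
    if config.fn_effect.is_noop:
        return control, control
    mask = np.zeros(config.n_regions, dtype=bool)
    mask[list(affected)] = True
    edge_scale = np.ones_like(base)
    incident = (mask[:, None] | mask[None, :]) & (backbone > 0)
    edge_scale[incident] = config.fn_effect.factor
    patient_base = np.eye(config.n_regions) + (r * backbone.astype(float)) * edge_scale
    patient = _project_to_correlation(patient_base, "patient")
    return control, patient


def _subject_records(config: CohortConfig) -> list[SubjectRecord]:
    width = len(str(max(config.n_patients, config.n_controls)))
    recs = [
        SubjectRecord(subject_id=f"patient_{i + 1:0{width}d}", group="patient")
        for i in range(config.n_patients)
    ]
    recs += [
        SubjectRecord(subject_id=f"control_{i + 1:0{width}d}", group="control")
        for i in range(config.n_controls)
    ]
    return recs


def generate_functional_cohort(
    config: CohortConfig,
) -> tuple[list[SubjectRecord], list[TimeSeriesMatrix], GroundTruth]:
    """Per-subject time series drawn from zero-mean multivariate normals.

    The control target correlation equals ``edge_correlation`` on backbone
    edges and 0 elsewhere (projected to the nearest valid correlation
    matrix); patients use the same backbone with the functional effect
    applied.  Patient records come first, then controls.
    """
    backbone = _watts_strogatz(
        config.n_regions, config.mean_degree, config.p_rewire, _rng(config, _STREAM_GRAPH)
    )
    affected = _affected_regions(
        backbone, config.fn_effect.regions, config.fn_effect.n_affected
    )
    control_corr, patient_corr = _target_correlations(config, backbone, affected)
    chol = {
        "control": np.linalg.cholesky(control_corr),
        "patient": np.linalg.cholesky(patient_corr),
    }
    rng = _rng(config, _STREAM_FUNCTIONAL)
    labels = config.region_labels()
    records = _subject_records(config)
    series = []
    for rec in records:
        x = chol[rec.group] @ rng.standard_normal(
            (config.n_regions, config.n_timepoints)
        )
        series.append(TimeSeriesMatrix(x, region_labels=labels))
    truth = GroundTruth(
        true_graph_patient=backbone.copy(),
        true_graph_control=backbone.copy(),
        affected_regions=affected,
        affected_edges=_incident_edges(backbone, affected),
        score_slope=config.score_model.slope,
    )
    return records, series, truth


def generate_structural_cohort(
    config: CohortConfig,
) -> tuple[list[SubjectRecord], list[ConnectivityMatrix], GroundTruth]:
    """Per-subject FA-weighted symmetric matrices.

    FA weights on backbone edges are Beta-distributed with mean ``fa_mean``
    (shifted by the structural effect on affected edges in patients) and
    concentration ``fa_concentration``; non-edges are 0.
    """
    backbone = _watts_strogatz(
        config.n_regions, config.mean_degree, config.p_rewire, _rng(config, _STREAM_GRAPH)
    )
    affected = _affected_regions(
        backbone, config.sn_effect.regions, config.sn_effect.n_affected
    )
    patient_mean = config.fa_mean + config.sn_effect.fa_shift
    if not 0.0 < patient_mean < 1.0:
        raise CohortGenerationError(
            f"sn_effect shifts the FA mean to {patient_mean:.3g}, outside (0, 1)"
        )
    edges = np.argwhere(np.triu(backbone, k=1))
    mask = np.zeros(config.n_regions, dtype=bool)
    mask[list(affected)] = True
    edge_affected = mask[edges[:, 0]] | mask[edges[:, 1]]
    nu = config.fa_concentration
    means = {
        "control": np.full(edges.shape[0], config.fa_mean),
        "patient": np.where(
            edge_affected & ~config.sn_effect.is_noop, patient_mean, config.fa_mean
        ),
    }
    rng = _rng(config, _STREAM_STRUCTURAL)
    labels = config.region_labels()
    records = _subject_records(config)
    matrices = []
    for rec in records:
        mu = means[rec.group]
        w = rng.beta(mu * nu, (1.0 - mu) * nu)
        m = np.zeros((config.n_regions, config.n_regions))
        m[edges[:, 0], edges[:, 1]] = w
        m += m.T
        matrices.append(
            ConnectivityMatrix(m, mode="structural", region_labels=labels)
        )
    truth = GroundTruth(
        true_graph_patient=backbone.copy(),
        true_graph_control=backbone.copy(),
        affected_regions=affected,
        affected_edges=_incident_edges(backbone, affected),
        score_slope=config.score_model.slope,
    )
    return records, matrices, truth


def generate_clinical_scores(
    subjects: list[SubjectRecord], nodal_reference, config: CohortConfig
) -> list[SubjectRecord]:
    """Scores linear in a per-subject reference value plus Gaussian noise,
    truncated at 0 and rounded to one decimal.  One reference per subject."""
    ref = np.asarray(nodal_reference, dtype=float)
    if ref.shape != (len(subjects),):
        raise ValueError("exactly one nodal reference value per subject required")
    sm = config.score_model
    rng = _rng(config, _STREAM_SCORES)
    noise = rng.normal(0.0, sm.noise_sd, size=len(subjects)) if sm.noise_sd > 0 else np.zeros(len(subjects))
    raw = sm.intercept + sm.slope * ref + noise
    scores = np.round(np.maximum(raw, 0.0), 1)
    return [rec.with_score(float(s)) for rec, s in zip(subjects, scores)]


def reference_nodal_efficiency(series: list[TimeSeriesMatrix], region: int,
                               sparsity: float = 0.38) -> np.ndarray:
    """Nodal efficiency of one region per subject, at a fixed sparsity."""
    vals = []
    for ts in series:
        net = binarize_sparsity(functional_connectivity(ts), sparsity)
        vals.append(nodal_efficiency(net)[region])
    return np.asarray(vals)


def write_cohort(config: CohortConfig, outdir) -> tuple[list[SubjectRecord], GroundTruth]:
    """Generate both arms, score the subjects and write everything to disk.

    Layout: ``ts/<id>_ts.tsv`` (regions x timepoints), ``fa/<id>_fa.tsv``
    (N x N), ``manifest.csv`` and ``ground_truth.json``.  Patient scores
    follow the config score model, driven by the designated region's nodal
    efficiency at the score model's reference sparsity; controls draw
    healthy-range baseline scores independent of network state.
    """
    outdir = Path(outdir)
    (outdir / "ts").mkdir(parents=True, exist_ok=True)
    (outdir / "fa").mkdir(parents=True, exist_ok=True)
    records, series, truth = generate_functional_cohort(config)
    _, matrices, _ = generate_structural_cohort(config)

    n_pat = config.n_patients
    sm = config.score_model
    ref_region = (
        truth.affected_regions[0] if sm.reference_region is None else sm.reference_region
    )
    pat_ref = reference_nodal_efficiency(
        series[:n_pat], ref_region, sparsity=sm.reference_sparsity
    )
    patients = generate_clinical_scores(records[:n_pat], pat_ref, config)

    base_mean, base_sd = CONTROL_SCORE_BASELINE
    rng = _rng(config, _STREAM_SCORES + 1000)
    ctrl_scores = np.round(
        np.maximum(rng.normal(base_mean, base_sd, size=config.n_controls), 0.0), 1
    )
    controls = [
        rec.with_score(float(s)) for rec, s in zip(records[n_pat:], ctrl_scores)
    ]

    final = []
    for rec, ts, fa in zip(patients + controls, series, matrices):
        ts_path = outdir / "ts" / f"{rec.subject_id}_ts.tsv"
        fa_path = outdir / "fa" / f"{rec.subject_id}_fa.tsv"
        write_matrix_tsv(ts_path, ts.values)
        write_matrix_tsv(fa_path, fa.values)
        final.append(replace(rec, ts_path=str(ts_path), fa_path=str(fa_path)))
    write_manifest(outdir / "manifest.csv", final)
    truth.to_json(outdir / "ground_truth.json")
    return final, truth
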