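import json

import numpy as np
import pytest

from mmconn.manifest import read_manifest
from mmconn.synthdata import (
    CohortConfig,
    CohortGenerationError,
    FunctionalEffect,
    GroundTruth,
    ScoreModel,
    StructuralEffect,
    generate_clinical_scores,
    generate_functional_cohort,
    generate_structural_cohort,
    write_cohort,
    _target_correlations,
    _watts_strogatz,
    _affected_regions,
)


def small_config(seed=0, **overrides):
    kwargs = dict(
        n_patients=5, n_controls=4, n_regions=30, mean_degree=6,
        edge_correlation=0.4, seed=seed,
    )
    kwargs.update(overrides)
    return CohortConfig(**kwargs)


class TestConfigValidation:
    def test_default_matches_study_design(self):
        cfg = CohortConfig()
        assert (cfg.n_patients, cfg.n_controls) == (42, 38)
        assert (cfg.n_regions, cfg.n_timepoints) == (246, 230)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_patients=1),
            dict(n_timepoints=10),
            dict(edge_correlation=1.2),
            dict(fa_mean=1.1),
            dict(mean_degree=7),  # odd degree has no ring lattice
            dict(p_rewire=1.5),
            dict(base_graph="erdos"),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CohortConfig(**kwargs)

    def test_reduced_profile_scales_backbone_density(self):
        cfg = CohortConfig.reduced(seed=3)
        assert cfg.n_regions == 60
        density_full = 124 / 245
        density_reduced = cfg.mean_degree / (cfg.n_regions - 1)
        assert density_reduced == pytest.approx(density_full, abs=0.02)


class TestFunctionalCohort:
    def test_noop_effect_gives_identical_group_targets(self):
        cfg = small_config(fn_effect=FunctionalEffect(factor=1.0))
        backbone = _watts_strogatz(30, 6, 0.1, np.random.default_rng([0, 0]))
        affected = _affected_regions(backbone, None, 10)
        control, patient = _target_correlations(cfg, backbone, affected)
        assert np.array_equal(control, patient)

    def test_default_config_shapes(self):
        records, series, truth = generate_functional_cohort(CohortConfig(seed=1))
        assert len(records) == 80
        assert sum(r.group == "patient" for r in records) == 42
        assert sum(r.group == "control" for r in records) == 38
        assert all(ts.values.shape == (246, 230) for ts in series[:2])

    def test_pooled_edge_correlation_recovers_target(self):
        # Monte-Carlo against the generator's own target on a mild backbone
        cfg = small_config(seed=7, n_patients=100, n_controls=100,
                          fn_effect=FunctionalEffect(factor=1.0))
        records, series, truth = generate_functional_cohort(cfg)
        edges = np.argwhere(np.triu(truth.true_graph_control, k=1))
        acc = np.zeros(len(edges))
        for ts in series:
            r = np.corrcoef(ts.values)
            acc += r[edges[:, 0], edges[:, 1]]
        mean_edge_r = (acc / len(series)).mean()
        assert mean_edge_r == pytest.approx(0.4, abs=0.05)

    def test_bit_deterministic_given_seed(self):
        _, s1, t1 = generate_functional_cohort(small_config(seed=5))
        _, s2, t2 = generate_functional_cohort(small_config(seed=5))
        assert all(np.array_equal(a.values, b.values) for a, b in zip(s1, s2))
        assert t1.affected_regions == t2.affected_regions

    def test_different_seeds_differ(self):
        _, s1, _ = generate_functional_cohort(small_config(seed=5))
        _, s2, _ = generate_functional_cohort(small_config(seed=6))
        assert not np.array_equal(s1[0].values, s2[0].values)

    def test_affected_regions_are_recorded_and_in_range(self):
        _, _, truth = generate_functional_cohort(small_config(seed=2))
        assert len(truth.affected_regions) == 10
        assert all(0 <= r < 30 for r in truth.affected_regions)
        for i, j in truth.affected_edges:
            assert truth.true_graph_control[i, j] == 1
            assert i in truth.affected_regions or j in truth.affected_regions


class TestStructuralCohort:
    def test_matrices_symmetric_zero_diagonal_in_range(self):
        _, mats, _ = generate_structural_cohort(small_config(seed=3))
        for m in mats:
            v = m.values
            assert np.array_equal(v, v.T)
            assert np.all(np.diag(v) == 0)
            assert v.min() >= 0.0 and v.max() < 1.0

    def test_edge_weight_mean_matches_beta_target(self):
        cfg = small_config(seed=4, fa_mean=0.5,
                           sn_effect=StructuralEffect(fa_shift=0.0))
        _, mats, truth = generate_structural_cohort(cfg)
        edges = np.argwhere(np.triu(truth.true_graph_control, k=1))
        w = np.concatenate([m.values[edges[:, 0], edges[:, 1]] for m in mats])
        assert w.size >= 500
        assert w.mean() == pytest.approx(0.5, abs=0.03)

    def test_noop_effect_groups_identical_in_law(self):
        cfg = small_config(seed=5, n_patients=60, n_controls=60,
                           sn_effect=StructuralEffect(fa_shift=0.0))
        recs, mats, truth = generate_structural_cohort(cfg)
        edges = np.argwhere(np.triu(truth.true_graph_control, k=1))
        pat = np.concatenate([m.values[edges[:, 0], edges[:, 1]]
                              for m, r in zip(mats, recs) if r.group == "patient"])
        con = np.concatenate([m.values[edges[:, 0], edges[:, 1]]
                              for m, r in zip(mats, recs) if r.group == "control"])
        assert pat.mean() == pytest.approx(con.mean(), abs=0.01)
        assert pat.std() == pytest.approx(con.std(), abs=0.01)

    def test_shift_pushing_mean_out_of_range_rejected(self):
        cfg = small_config(fa_mean=0.9, sn_effect=StructuralEffect(fa_shift=0.2))
        with pytest.raises(CohortGenerationError):
            generate_structural_cohort(cfg)

    def test_planted_shift_raises_affected_edge_weights(self):
        cfg = small_config(seed=6, n_patients=60, n_controls=60,
                           sn_effect=StructuralEffect(fa_shift=0.05))
        recs, mats, truth = generate_structural_cohort(cfg)
        aff = np.array(truth.affected_edges)
        pat = np.concatenate([m.values[aff[:, 0], aff[:, 1]]
                              for m, r in zip(mats, recs) if r.group == "patient"])
        con = np.concatenate([m.values[aff[:, 0], aff[:, 1]]
                              for m, r in zip(mats, recs) if r.group == "control"])
        assert pat.mean() - con.mean() == pytest.approx(0.05, abs=0.01)


class TestClinicalScores:
    def test_noiseless_identity_model(self):
        cfg = small_config(score_model=ScoreModel(slope=1.0, intercept=0.0,
                                                  noise_sd=0.0))
        records, _, _ = generate_functional_cohort(cfg)
        ref = np.array([0.31, 0.0, -0.2, 0.459, 12.34])
        scored = generate_clinical_scores(records[:5], ref, cfg)
        assert [r.hamd for r in scored] == [0.3, 0.0, 0.0, 0.5, 12.3]

    def test_zero_slope_scores_independent_of_reference(self):
        cfg = small_config(
            seed=9, n_patients=300, n_controls=2,
            score_model=ScoreModel(slope=0.0, intercept=10.0, noise_sd=3.0),
        )
        records, _, _ = generate_functional_cohort(cfg)
        rng = np.random.default_rng(0)
        ref = rng.uniform(0.2, 0.8, 300)
        scored = generate_clinical_scores(records[:300], ref, cfg)
        scores = np.array([r.hamd for r in scored])
        r = np.corrcoef(ref, scores)[0, 1]
        assert abs(r) < 0.12

    def test_reference_length_must_match(self):
        cfg = small_config()
        records, _, _ = generate_functional_cohort(cfg)
        with pytest.raises(ValueError):
            generate_clinical_scores(records[:3], [0.1, 0.2], cfg)

    def test_default_calibration_targets_hamd_moments(self):
        # patient HAMD should land near the 9.9 +/- 4.9 design target,
        # pooled over three reduced cohorts generated in memory
        from mmconn.synthdata import reference_nodal_efficiency

        scores = []
        for seed in range(3):
            cfg = CohortConfig.reduced(seed=seed)
            records, series, truth = generate_functional_cohort(cfg)
            ref = reference_nodal_efficiency(
                series[:42], truth.affected_regions[0],
                cfg.score_model.reference_sparsity,
            )
            scored = generate_clinical_scores(records[:42], ref, cfg)
            scores.extend(r.hamd for r in scored)
        scores = np.asarray(scores)
        assert scores.mean() == pytest.approx(9.94, abs=1.0)
        assert scores.std(ddof=1) == pytest.approx(4.93, abs=1.0)


class TestWriteCohort:
    def test_round_trip_on_disk(self, tmp_path):
        cfg = small_config(seed=8)
        records, truth = write_cohort(cfg, tmp_path)
        back = read_manifest(tmp_path / "manifest.csv")
        assert [r.subject_id for r in back] == [r.subject_id for r in records]
        assert all(r.hamd is not None and r.hamd >= 0 for r in back)
        gt = GroundTruth.from_json(tmp_path / "ground_truth.json")
        assert gt.affected_regions == truth.affected_regions
        assert np.array_equal(gt.true_graph_control, truth.true_graph_control)
        ts = np.loadtxt(back[0].ts_path, delimiter="\t")
        assert ts.shape == (30, 230)
        fa = np.loadtxt(back[0].fa_path, delimiter="\t")
        assert fa.shape == (30, 30)
        assert np.allclose(fa, fa.T)

    def test_rewritten_cohort_is_byte_identical(self, tmp_path):
        cfg = small_config(seed=8)
        write_cohort(cfg, tmp_path / "a")
        write_cohort(cfg, tmp_path / "b")
        for name in ["manifest.csv", "ground_truth.json"]:
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()
        a0 = sorted((tmp_path / "a" / "ts").iterdir())[0]
        b0 = sorted((tmp_path / "b" / "ts").iterdir())[0]
        assert a0.read_bytes() == b0.read_bytes()
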