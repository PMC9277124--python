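import numpy as np
import pandas as pd
import pytest

from mmconn.stats import (
    clinical_correlation,
    fdr_bh,
    nodal_comparison,
    permutation_test,
    permutation_test_many,
    sweep_comparison,
)

import oracles


class TestPermutationTest:
    def test_constant_data_gives_zero_diff_and_p_one(self):
        obs, p = permutation_test([3.0] * 10, [3.0] * 8, n_perm=200, seed=0)
        assert obs == 0.0
        assert p == 1.0

    def test_p_never_below_add_one_floor(self, rng):
        a = rng.normal(10.0, 1.0, 40)
        b = rng.normal(0.0, 1.0, 40)
        obs, p = permutation_test(a, b, n_perm=999, seed=1)
        assert p == pytest.approx(1 / 1000)
        assert obs == pytest.approx(a.mean() - b.mean())

    def test_strong_separation_detected(self, rng):
        a = rng.normal(2.0, 1.0, 40)
        b = rng.normal(0.0, 1.0, 40)
        _, p = permutation_test(a, b, n_perm=5000, seed=2)
        assert p <= 0.001

    def test_invariant_to_adding_a_constant(self, rng):
        a = rng.normal(0.3, 1.0, 20)
        b = rng.normal(0.0, 1.0, 25)
        _, p1 = permutation_test(a, b, n_perm=500, seed=3)
        _, p2 = permutation_test(a + 17.5, b + 17.5, n_perm=500, seed=3)
        assert p1 == p2

    def test_stable_under_group_label_ordering(self, rng):
        a = rng.normal(0.5, 1.0, 25)
        b = rng.normal(0.0, 1.0, 25)
        _, p1 = permutation_test(a, b, n_perm=4000, seed=4)
        _, p2 = permutation_test(b, a, n_perm=4000, seed=5)
        assert abs(p1 - p2) < 0.02

    def test_type_i_error_calibrated(self, rng):
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            a = rng.standard_normal(20)
            b = rng.standard_normal(20)
            _, p = permutation_test(a, b, n_perm=200, seed=int(rng.integers(2**31)))
            hits += p < 0.05
        assert 0.01 <= hits / n_rep <= 0.10

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            permutation_test([], [1.0, 2.0], n_perm=10, seed=0)

    def test_vectorized_matches_scalar_api(self, rng):
        vals = rng.standard_normal((5, 30))
        obs_m, p_m = permutation_test_many(vals, 14, n_perm=300, seed=9)
        for i in range(5):
            obs_s, p_s = permutation_test(vals[i, :14], vals[i, 14:],
                                          n_perm=300, seed=9)
            assert obs_s == pytest.approx(obs_m[i])


class TestFdrBh:
    def test_uniform_ladder_example(self):
        adj, rej = fdr_bh([0.01, 0.02, 0.03, 0.04], q=0.05)
        assert adj == pytest.approx([0.04, 0.04, 0.04, 0.04])
        assert rej.all()

    def test_two_value_example(self):
        adj, _ = fdr_bh([0.001, 0.5], q=0.05)
        assert adj == pytest.approx([0.002, 0.5])

    def test_single_p_unchanged(self):
        adj, rej = fdr_bh([0.03], q=0.05)
        assert adj == pytest.approx([0.03])
        assert rej[0]

    def test_empty_input(self):
        adj, rej = fdr_bh([], q=0.05)
        assert adj.size == 0 and rej.size == 0

    def test_matches_sort_based_reference_on_random_vectors(self, rng):
        for _ in range(300):
            m = int(rng.integers(1, 40))
            p = rng.uniform(1e-6, 1.0, m)
            adj, rej = fdr_bh(p, q=0.05)
            ref_adj, ref_rej = oracles.bh_reference(p, 0.05)
            assert adj == pytest.approx(ref_adj)
            assert list(rej) == ref_rej

    def test_adjusted_never_below_raw(self, rng):
        p = rng.uniform(0, 1, 25)
        adj, _ = fdr_bh(p, q=0.1)
        assert np.all(adj >= p - 1e-15)


def _metric_table(rng, n_pat=10, n_con=8, thresholds=(0.2, 0.3, 0.4),
                  metric="lambda", shift=0.0):
    rows = []
    for thr in thresholds:
        for i in range(n_pat):
            rows.append((f"p{i}", "patient", "sparsity", thr, metric,
                         rng.standard_normal() + shift))
        for i in range(n_con):
            rows.append((f"c{i}", "control", "sparsity", thr, metric,
                         rng.standard_normal()))
    return pd.DataFrame(rows, columns=["subject_id", "group", "threshold_kind",
                                       "threshold", "metric", "value"])


class TestSweepComparison:
    def test_one_result_per_threshold_with_family_fdr(self, rng):
        table = _metric_table(rng, shift=2.0)
        results = sweep_comparison(table, "lambda", n_perm=300, seed=0)
        assert len(results) == 3
        assert all(r.p_fdr >= r.p_perm - 1e-15 for r in results)
        assert all(r.significant for r in results)  # strong planted shift

    def test_single_threshold_reduces_to_plain_permutation_test(self, rng):
        table = _metric_table(rng, thresholds=(0.3,))
        results = sweep_comparison(table, "lambda", n_perm=300, seed=1)
        assert len(results) == 1
        assert results[0].p_fdr == results[0].p_perm

    def test_missing_combination_is_an_error(self, rng):
        table = _metric_table(rng)
        table = table.drop(table.index[0])
        with pytest.raises(ValueError, match="missing"):
            sweep_comparison(table, "lambda", n_perm=50, seed=0)

    def test_unknown_metric_rejected(self, rng):
        with pytest.raises(ValueError):
            sweep_comparison(_metric_table(rng), "sigma", n_perm=50, seed=0)


def _nodal_table(rng, n_regions=12, affected=(0, 1, 2), effect=-2.0,
                 n_pat=15, n_con=12):
    rows = []
    for r in range(n_regions):
        region = f"R{r:02d}"
        for i in range(n_pat):
            delta = effect if r in affected else 0.0
            rows.append((f"p{i}", "patient", "sparsity", 0.26, "e_nod", region,
                         rng.standard_normal() + delta))
        for i in range(n_con):
            rows.append((f"c{i}", "control", "sparsity", 0.26, "e_nod", region,
                         rng.standard_normal()))
    return pd.DataFrame(rows, columns=["subject_id", "group", "threshold_kind",
                                       "threshold", "metric", "region", "value"])


class TestNodalComparison:
    def test_planted_regions_recovered_and_sorted_by_p(self, rng):
        results = nodal_comparison(_nodal_table(rng), n_perm=500, seed=0)
        assert len(results) == 12
        flagged = {r.region for r in results if r.significant}
        assert {"R00", "R01", "R02"} <= flagged
        ps = [r.p_perm for r in results]
        assert ps == sorted(ps)
        top = results[0]
        assert top.observed_diff < 0
        assert top.patient_mean < top.control_mean

    def test_identical_groups_give_p_one(self):
        rows = []
        for i in range(6):
            rows.append((f"p{i}", "patient", "sparsity", 0.26, "e_nod", "R0", 1.5))
        for i in range(6):
            rows.append((f"c{i}", "control", "sparsity", 0.26, "e_nod", "R0", 1.5))
        table = pd.DataFrame(rows, columns=["subject_id", "group", "threshold_kind",
                                            "threshold", "metric", "region", "value"])
        results = nodal_comparison(table, n_perm=200, seed=0)
        assert results[0].p_perm == 1.0
        assert results[0].observed_diff == 0.0

    def test_mixed_thresholds_rejected(self, rng):
        table = _nodal_table(rng)
        table.loc[table.index[0], "threshold"] = 0.3
        with pytest.raises(ValueError):
            nodal_comparison(table, n_perm=50, seed=0)


class TestClinicalCorrelation:
    def test_exact_linear_relation_gives_r_one(self):
        vals = pd.DataFrame({"R0": [0.1, 0.2, 0.3, 0.4, 0.5]})
        out = clinical_correlation(vals, [1, 2, 3, 4, 5])
        assert out[0].r == pytest.approx(1.0)

    def test_worked_example_r_08(self):
        vals = pd.DataFrame({"R0": [1, 2, 3, 4, 5]})
        out = clinical_correlation(vals, [2, 1, 4, 3, 5])
        assert out[0].r == pytest.approx(0.8)
        assert out[0].n == 5

    def test_matches_two_pass_oracle(self, rng):
        x = rng.standard_normal(20)
        y = 0.4 * x + rng.standard_normal(20)
        out = clinical_correlation(pd.DataFrame({"R0": x}), y)
        assert out[0].r == pytest.approx(oracles.pearson_two_pass(x, y), abs=1e-12)

    def test_zero_variance_scores_rejected(self):
        vals = pd.DataFrame({"R0": [0.1, 0.2, 0.3]})
        with pytest.raises(ValueError, match="zero variance"):
            clinical_correlation(vals, [2.0, 2.0, 2.0])

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            clinical_correlation(pd.DataFrame({"R0": [0.1, 0.2]}), [1.0, 2.0])

    def test_region_subset_is_respected(self, rng):
        vals = pd.DataFrame({"R0": rng.standard_normal(10),
                             "R1": rng.standard_normal(10)})
        out = clinical_correlation(vals, rng.standard_normal(10), regions=["R1"])
        assert [c.region for c in out] == ["R1"]
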