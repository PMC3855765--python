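"""Group statistics: group/subject fits, permutation test, classical layers."""

import numpy as np
import pytest

from bnec.exceptions import DataError, DegenerateInputError, ParameterError
from bnec.gbn import markov_equivalent
from bnec.search import search_bic_optimal
from bnec.stats import (
    fit_group_bn,
    fit_subject_bns,
    pearson_correlation,
    permutation_test_edges,
    spearman_correlation,
    standardize_columns,
    two_sample_ttest,
)
from bnec.synthetic import CohortTimeSeries, SubjectSeries, default_truth

from conftest import build_cohort


class TestTTest:
    def test_printed_toy_value(self):
        res = two_sample_ttest([1, 2, 3], [4, 5, 6])
        assert res.statistic == pytest.approx(-3.674, abs=1e-3)

    def test_identical_groups(self):
        res = two_sample_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p_value == pytest.approx(1.0)

    def test_swapping_groups_flips_sign(self, rng):
        a, b = rng.standard_normal(10), rng.standard_normal(12) + 1
        r1 = two_sample_ttest(a, b)
        r2 = two_sample_ttest(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_degenerate_variance(self):
        with pytest.raises(DegenerateInputError):
            two_sample_ttest([1.0, 1.0], [2.0, 2.0])


class TestCorrelations:
    def test_pearson_perfect_lines(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_correlation(x, 2 * x + 1).coefficient == pytest.approx(1.0)
        assert pearson_correlation(x, -x).coefficient == pytest.approx(-1.0)

    def test_pearson_matches_covariance_formula(self, rng):
        x, y = rng.standard_normal(30), rng.standard_normal(30)
        r = pearson_correlation(x, y).coefficient
        oracle = ((x - x.mean()) @ (y - y.mean())) / (
            np.sqrt(((x - x.mean()) ** 2).sum()) * np.sqrt(((y - y.mean()) ** 2).sum())
        )
        assert r == pytest.approx(oracle, abs=1e-10)

    def test_spearman_monotone(self):
        x = np.array([1.0, 2.0, 3.0, 10.0])
        assert spearman_correlation(x, np.exp(x)).coefficient == pytest.approx(1.0)

    def test_spearman_hand_enumeration(self):
        res = spearman_correlation([1, 2, 3], [3, 1, 2])
        assert res.coefficient == pytest.approx(-0.5)

    def test_spearman_midrank_oracle_with_ties(self, rng):
        x = rng.integers(0, 4, size=25).astype(float)
        y = rng.integers(0, 4, size=25).astype(float)
        import scipy.stats

        rho = spearman_correlation(x, y).coefficient
        rx, ry = scipy.stats.rankdata(x), scipy.stats.rankdata(y)
        oracle = pearson_correlation(rx, ry).coefficient
        assert rho == pytest.approx(oracle, abs=1e-10)

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateInputError):
            pearson_correlation([1, 1, 1], [1, 2, 3])
        with pytest.raises(ParameterError):
            spearman_correlation([1, 2], [1, 2])


class TestGroupFit:
    def test_affine_rescaling_invariance(self, five_node_null_bn):
        dag, params = five_node_null_bn
        ts = build_cohort({"g": (dag, params, 4)}, 150, seed=1)
        scaled = []
        for i, s in enumerate(ts.subjects):
            factor = 3.0 + i
            scaled.append(
                SubjectSeries(s.subject_id, s.group, s.data * factor + 11.0)
            )
        ts2 = CohortTimeSeries(ts.region_names, tuple(scaled))
        r1, p1 = fit_group_bn(ts, "g", seed=0, restarts=10)
        r2, p2 = fit_group_bn(ts2, "g", seed=0, restarts=10)
        assert r1.dag == r2.dag
        assert r1.score == pytest.approx(r2.score, abs=1e-6)

    def test_duplicated_subject_matches_single_subject_structure(
        self, five_node_null_bn
    ):
        dag, params = five_node_null_bn
        ts = build_cohort({"g": (dag, params, 1)}, 400, seed=2)
        dup = CohortTimeSeries(
            ts.region_names,
            (
                ts.subjects[0],
                SubjectSeries("copy", "g", ts.subjects[0].data.copy()),
            ),
        )
        res_group, _ = fit_group_bn(dup, "g", seed=0, restarts=10)
        z = standardize_columns(ts.subjects[0].data)
        res_single = search_bic_optimal(z, nodes=ts.region_names, restarts=10, seed=0)
        assert res_group.dag == res_single.dag

    def test_group_fit_recovers_truth_class(self):
        dag, params = default_truth()
        ts = build_cohort({"ctrl": (dag, params, 17)}, 190, seed=11)
        res, fitted = fit_group_bn(ts, "ctrl", seed=0, restarts=50)
        assert markov_equivalent(res.dag, dag)
        # strong weights recovered to ~sampling precision
        for (p, c) in (("dMPFC", "lIPL"), ("rLTC", "lLTC")):
            if p in res.dag.parents[c]:
                assert fitted.weights[c][p] == pytest.approx(
                    params.weights[c][p], abs=0.1
                )

    def test_single_subject_group_rejected(self, five_node_null_bn):
        dag, params = five_node_null_bn
        ts = build_cohort({"g": (dag, params, 1)}, 100, seed=3)
        with pytest.raises(DataError):
            fit_group_bn(ts, "g")


class TestSubjectFits:
    def test_single_subject_cohort(self, five_node_null_bn):
        dag, params = five_node_null_bn
        ts = build_cohort({"g": (dag, params, 1)}, 100, seed=4)
        fits = fit_subject_bns(ts, seed=0)
        assert len(fits) == 1
        assert fits[0].ci_table.scope == fits[0].subject_id

    def test_long_series_recover_truth_with_low_spread(self, five_node_null_bn):
        dag, params = five_node_null_bn
        ts = build_cohort({"g": (dag, params, 5)}, 5000, seed=5)
        fits = fit_subject_bns(ts, seed=0, restarts=10)
        true_ci = [len(dag.parents[r]) for r in dag.nodes]
        cis = np.array([f.ci_table.ci for f in fits])
        assert np.abs(cis.mean(axis=0) - true_ci).max() <= 0.4

    def test_study_length_series_show_between_subject_spread(self):
        dag, params = default_truth()
        ts = build_cohort({"g": (dag, params, 10)}, 190, seed=6)
        fits = fit_subject_bns(ts, seed=0, restarts=10)
        cis = np.array([f.ci_table.ci for f in fits])
        assert cis.std(axis=0).sum() > 0

    def test_short_series_rejected(self, five_node_null_bn):
        dag, params = five_node_null_bn
        ts = build_cohort({"g": (dag, params, 2)}, 19, seed=7)
        with pytest.raises(DataError):
            fit_subject_bns(ts)


class TestPermutation:
    def test_identical_groups_give_null_results(self, five_node_null_bn):
        dag, params = five_node_null_bn
        base = build_cohort({"A": (dag, params, 5)}, 120, seed=8)
        mirrored = list(base.subjects) + [
            SubjectSeries(s.subject_id.replace("A", "B"), "B", s.data.copy())
            for s in base.subjects
        ]
        ts = CohortTimeSeries(base.region_names, tuple(mirrored))
        res = permutation_test_edges(ts, n_permutations=99, seed=0, restarts=3)
        assert np.allclose(res.diff, 0.0)
        assert float(min(res.p_a_gt_b.min(), res.p_b_gt_a.min())) > 0.05

    def test_label_swap_swaps_pvalues_exactly(self, five_node_null_bn):
        dag, params = five_node_null_bn
        ts = build_cohort({"A": (dag, params, 4), "B": (dag, params, 4)}, 120, seed=9)
        swapped = CohortTimeSeries(
            ts.region_names,
            tuple(
                SubjectSeries(s.subject_id, "B" if s.group == "A" else "A", s.data)
                for s in ts.subjects
            ),
        )
        r1 = permutation_test_edges(ts, n_permutations=30, seed=5, restarts=3,
                                    group_a="A", group_b="B")
        r2 = permutation_test_edges(swapped, n_permutations=30, seed=5, restarts=3,
                                    group_a="A", group_b="B")
        assert np.array_equal(r1.p_a_gt_b, r2.p_b_gt_a)
        assert np.array_equal(r1.p_b_gt_a, r2.p_a_gt_b)
        assert np.allclose(r1.weights_a, r2.weights_b)

    def test_pvalues_in_unit_interval_and_smoothed(self, five_node_null_bn):
        dag, params = five_node_null_bn
        ts = build_cohort({"A": (dag, params, 3), "B": (dag, params, 3)}, 100, seed=10)
        res = permutation_test_edges(ts, n_permutations=19, seed=1, restarts=2)
        for p in (res.p_a_gt_b, res.p_b_gt_a):
            assert np.all(p >= 1 / 20) and np.all(p <= 1.0)

    def test_small_groups_rejected(self, five_node_null_bn):
        dag, params = five_node_null_bn
        ts = build_cohort({"A": (dag, params, 2), "B": (dag, params, 1)}, 100, seed=11)
        with pytest.raises(DataError):
            permutation_test_edges(ts, n_permutations=5)

    def test_result_table_has_all_ordered_pairs(self, five_node_null_bn):
        dag, params = five_node_null_bn
        ts = build_cohort({"A": (dag, params, 3), "B": (dag, params, 3)}, 100, seed=12)
        res = permutation_test_edges(ts, n_permutations=9, seed=2, restarts=2)
        df = res.to_frame()
        assert len(df) == 5 * 4
        assert np.allclose(df["diff"], df["weight_a"] - df["weight_b"])
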