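"""Core linear Gaussian network: fitting, likelihood, BIC, joint, sampling."""

import math

import numpy as np
import pytest
import scipy.stats

from bnec.exceptions import (
    DegenerateVarianceError,
    ParameterError,
    RankDeficiencyError,
)
from bnec.gbn import (
    DAGStructure,
    GBNParameters,
    bic_score,
    fit_ml_parameters,
    implied_joint,
    log_likelihood,
    markov_equivalent,
    sample_from_bn,
)
from bnec.synthetic import random_dag


def _standardized(n, seed):
    x = np.random.default_rng(seed).standard_normal(n)
    return (x - x.mean()) / x.std()


class TestDAGStructure:
    def test_rejects_cycle(self):
        with pytest.raises(Exception):
            DAGStructure.from_edges(("A", "B"), [("A", "B"), ("B", "A")])

    def test_rejects_self_parent(self):
        with pytest.raises(ParameterError):
            DAGStructure(("A",), {"A": frozenset({"A"})})

    def test_adjacency_matches_edges(self):
        dag = DAGStructure.from_edges(("A", "B", "C"), [("A", "C"), ("B", "C")])
        a = dag.adjacency_matrix()
        assert a[0, 2] == 1 and a[1, 2] == 1 and a.sum() == 2

    def test_markov_equivalence_two_node(self):
        d1 = DAGStructure.from_edges(("A", "B"), [("A", "B")])
        d2 = DAGStructure.from_edges(("A", "B"), [("B", "A")])
        assert markov_equivalent(d1, d2)

    def test_collider_breaks_equivalence(self):
        chain = DAGStructure.from_edges(("A", "B", "C"), [("A", "B"), ("B", "C")])
        collider = DAGStructure.from_edges(("A", "B", "C"), [("A", "B"), ("C", "B")])
        assert not markov_equivalent(chain, collider)


class TestFitML:
    def test_root_node_closed_form(self):
        dag = DAGStructure(("X",), {})
        params = fit_ml_parameters(np.array([[1.0], [2.0], [3.0]]), dag)
        assert params.mean["X"] == pytest.approx(2.0)
        assert params.variance["X"] == pytest.approx(2.0 / 3.0)

    def test_exact_linear_dependence_flagged_degenerate(self):
        dag = DAGStructure.from_edges(("X", "Y"), [("X", "Y")])
        x = np.array([-1.0, 0.0, 1.0])
        data = np.column_stack([x, 2.0 * x])
        params = fit_ml_parameters(data, dag)
        assert params.weights["Y"]["X"] == pytest.approx(2.0)
        assert params.variance["Y"] == 0.0
        assert "Y" in params.degenerate

    def test_matches_normal_equations_oracle(self, rng):
        dag, _ = random_dag(5, 0.5, (0.2, 0.9), seed=rng)
        data = rng.standard_normal((200, 5))
        params = fit_ml_parameters(data, dag)
        idx = {n: i for i, n in enumerate(dag.nodes)}
        for node in dag.nodes:
            pa = sorted(dag.parents[node])
            if not pa:
                continue
            design = np.column_stack(
                [np.ones(200)] + [data[:, idx[p]] for p in pa]
            )
            beta, *_ = np.linalg.lstsq(design, data[:, idx[node]], rcond=None)
            for j, p in enumerate(pa):
                assert params.weights[node][p] == pytest.approx(beta[j + 1], abs=1e-8)

    def test_collinear_parents_rejected(self):
        dag = DAGStructure.from_edges(
            ("A", "B", "C"), [("A", "C"), ("B", "C")]
        )
        a = np.random.default_rng(0).standard_normal(50)
        data = np.column_stack([a, a, a + 1.0])
        with pytest.raises(RankDeficiencyError, match="C"):
            fit_ml_parameters(data, dag)

    def test_too_few_samples_rejected(self):
        dag = DAGStructure.from_edges(("A", "B"), [("A", "B")])
        with pytest.raises(ParameterError):
            fit_ml_parameters(np.zeros((2, 2)), dag)


class TestLogLikelihood:
    def test_closed_form_at_ml_point(self):
        # standardized sample: ML mean 0, ML variance 1
        dag = DAGStructure(("X",), {})
        data = _standardized(100, seed=4)[:, None]
        params = fit_ml_parameters(data, dag)
        expected = -(100 / 2) * (math.log(2 * math.pi) + 1)
        assert log_likelihood(data, dag, params) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(-141.894, abs=1e-3)

    @pytest.mark.parametrize("seed", range(5))
    def test_factorization_equals_dense_gaussian(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 7))
        dag, params = random_dag(k, 0.5, (0.2, 0.8), seed=rng, random_sign=True)
        data = sample_from_bn(dag, params, 50, rng)
        joint = implied_joint(dag, params)
        dense = scipy.stats.multivariate_normal(
            mean=joint.mean, cov=joint.covariance
        ).logpdf(data).sum()
        assert log_likelihood(data, dag, params) == pytest.approx(dense, abs=1e-8)

    def test_duplicating_rows_doubles_loglik(self, chain_bn):
        dag, params = chain_bn
        data = sample_from_bn(dag, params, 40, 7)
        ll = log_likelihood(data, dag, params)
        assert log_likelihood(np.vstack([data, data]), dag, params) == pytest.approx(
            2 * ll, abs=1e-8
        )

    def test_zero_variance_is_an_error(self):
        dag = DAGStructure.from_edges(("X", "Y"), [("X", "Y")])
        params = GBNParameters(
            mean={"X": 0.0, "Y": 0.0},
            variance={"X": 1.0, "Y": 0.0},
            weights={"X": {}, "Y": {"X": 2.0}},
        )
        data = np.random.default_rng(1).standard_normal((10, 2))
        with pytest.raises(DegenerateVarianceError):
            log_likelihood(data, dag, params)

    def test_ml_fit_is_a_likelihood_maximum(self, rng):
        dag, gen = random_dag(4, 0.6, (0.3, 0.8), seed=rng)
        data = sample_from_bn(dag, gen, 300, rng)
        params = fit_ml_parameters(data, dag)
        base = log_likelihood(data, dag, params)
        for node in dag.nodes:
            for parent in dag.parents[node]:
                for eps in (-1e-3, 1e-3):
                    w = {c: dict(params.weights[c]) for c in dag.nodes}
                    w[node][parent] += eps
                    perturbed = GBNParameters(
                        mean=dict(params.mean),
                        variance=dict(params.variance),
                        weights=w,
                    )
                    assert log_likelihood(data, dag, perturbed) <= base + 1e-12


class TestBIC:
    def test_single_node_closed_form(self):
        dag = DAGStructure(("X",), {})
        data = _standardized(100, seed=11)[:, None]
        expected = -(100 / 2) * (math.log(2 * math.pi) + 1) - math.log(100)
        assert bic_score(data, dag) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(-146.499, abs=1e-3)

    def test_strong_edge_beats_empty_graph(self, rng):
        x = rng.standard_normal(500)
        y = x + 1e-3 * rng.standard_normal(500)
        data = np.column_stack([x, y])
        with_edge = DAGStructure.from_edges(("X", "Y"), [("X", "Y")])
        empty = DAGStructure(("X", "Y"), {})
        assert bic_score(data, with_edge) > bic_score(data, empty)

    @pytest.mark.parametrize("seed", range(5))
    def test_score_equivalence_of_markov_equivalent_dags(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.standard_normal((80, 2)) @ np.array([[1.0, 0.6], [0.0, 1.0]])
        fwd = DAGStructure.from_edges(("X", "Y"), [("X", "Y")])
        bwd = DAGStructure.from_edges(("X", "Y"), [("Y", "X")])
        assert bic_score(data, fwd) == pytest.approx(bic_score(data, bwd), abs=1e-8)


class TestImpliedJoint:
    def test_single_node(self):
        dag = DAGStructure(("X",), {})
        params = GBNParameters(mean={"X": 3.0}, variance={"X": 2.0}, weights={"X": {}})
        joint = implied_joint(dag, params)
        assert joint.mean[0] == 3.0
        assert joint.covariance[0, 0] == pytest.approx(2.0)

    def test_two_node_closed_form(self):
        dag = DAGStructure.from_edges(("X", "Y"), [("X", "Y")])
        params = GBNParameters(
            mean={"X": 0.0, "Y": 0.0},
            variance={"X": 1.0, "Y": 1.0},
            weights={"X": {}, "Y": {"X": 2.0}},
        )
        cov = implied_joint(dag, params).covariance
        assert np.allclose(cov, [[1.0, 2.0], [2.0, 5.0]])

    def test_matches_monte_carlo(self, rng):
        dag, params = random_dag(6, 0.4, (0.3, 0.8), seed=rng, random_sign=True)
        joint = implied_joint(dag, params)
        sample = sample_from_bn(dag, params, 10**6, rng)
        emp = np.cov(sample, rowvar=False, bias=True)
        rel = np.linalg.norm(emp - joint.covariance) / np.linalg.norm(joint.covariance)
        assert rel < 0.01


class TestSampling:
    def test_seeded_determinism(self, chain_bn):
        dag, params = chain_bn
        a = sample_from_bn(dag, params, 100, 42)
        b = sample_from_bn(dag, params, 100, 42)
        assert np.array_equal(a, b)

    def test_zero_weights_give_uncorrelated_columns(self):
        dag = DAGStructure(("A", "B", "C"), {})
        params = GBNParameters(
            mean={n: 0.0 for n in dag.nodes},
            variance={n: 1.0 for n in dag.nodes},
            weights={n: {} for n in dag.nodes},
        )
        x = sample_from_bn(dag, params, 10**6, 3)
        corr = np.corrcoef(x, rowvar=False)
        assert np.max(np.abs(corr - np.eye(3))) < 0.01

    def test_fit_sample_fit_round_trip(self, rng):
        dag, params = random_dag(5, 0.5, (0.4, 0.8), seed=rng)
        n = 10**5
        data = sample_from_bn(dag, params, n, rng)
        refit = fit_ml_parameters(data, dag)
        for node in dag.nodes:
            for p, b in params.weights[node].items():
                # 3 Monte-Carlo standard errors, crudely bounded by 3/sqrt(n)·c
                assert refit.weights[node][p] == pytest.approx(b, abs=0.05)
            assert refit.variance[node] == pytest.approx(
                params.variance[node], rel=0.05
            )
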