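"""Linear Gaussian Bayesian networks over named brain regions.

A Bayesian network here is a directed acyclic graph (DAG) whose nodes are
region-of-interest (ROI) time-series variables.  Each node ``X_i`` is
conditionally Gaussian given its parents::

    X_i | pa(X_i) ~ N( m_i + sum_j b_ij * (x_j - m_j),  v_i )

with ``m_i`` the unconditional mean, ``v_i`` the conditional variance and
``b_ij`` a linear connectivity coefficient from parent ``X_j``.  The joint
distribution implied by the factorization over the DAG is a multivariate
Gaussian, which makes maximum-likelihood fitting a set of per-node linear
regressions and makes the implied joint available in closed form.

This module holds the numerical core: structures (:class:`DAGStructure`),
parameters (:class:`GBNParameters`), ML fitting, log-likelihood, the BIC
network score, the implied joint Gaussian, and ancestral sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import (
    AcyclicityError,
    DegenerateVarianceError,
    ParameterError,
    RankDeficiencyError,
)

_LOG_2PI = math.log(2.0 * math.pi)

# Relative condition-number bound above which a parent Gram matrix is
# treated as collinear rather than silently solved.
_COND_LIMIT = 1e12


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DAGStructure:
    """A directed acyclic graph over named regions: the EC pattern.

    Parameters
    ----------
    nodes
        Ordered region labels; the order fixes matrix/column conventions.
    parents
        Mapping from node to the frozenset of its parent nodes.  Nodes
        absent from the mapping have no parents.
    """

    nodes: tuple[str, ...]
    parents: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        nodes = tuple(self.nodes)
        object.__setattr__(self, "nodes", nodes)
        if len(set(nodes)) != len(nodes):
            raise ParameterError("duplicate node labels in DAG")
        known = set(nodes)
        norm: dict[str, frozenset[str]] = {}
        for child, pset in dict(self.parents).items():
            if child not in known:
                raise ParameterError(f"parent set given for unknown node {child!r}")
            pset = frozenset(pset)
            unknown = pset - known
            if unknown:
                raise ParameterError(
                    f"node {child!r} lists unknown parents {sorted(unknown)}"
                )
            if child in pset:
                raise ParameterError(f"node {child!r} cannot be its own parent")
            norm[child] = pset
        for n in nodes:
            norm.setdefault(n, frozenset())
        object.__setattr__(self, "parents", norm)
        if not nx.is_directed_acyclic_graph(self.to_networkx()):
            raise AcyclicityError("parent sets contain a directed cycle")

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_edges(
        cls, nodes: Sequence[str], edges: Iterable[tuple[str, str]]
    ) -> "DAGStructure":
        parents: dict[str, set[str]] = {n: set() for n in nodes}
        for parent, child in edges:
            parents[child].add(parent)
        return cls(tuple(nodes), {c: frozenset(p) for c, p in parents.items()})

    # -- views ---------------------------------------------------------------

    def edges(self) -> list[tuple[str, str]]:
        """Sorted (parent, child) pairs."""
        return sorted(
            (p, c) for c in self.nodes for p in self.parents[c]
        )

    @property
    def n_edges(self) -> int:
        return sum(len(self.parents[c]) for c in self.nodes)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for c in self.nodes:
            g.add_edges_from((p, c) for p in self.parents[c])
        return g

    def topological_order(self) -> list[str]:
        order = list(nx.lexicographical_topological_sort(self.to_networkx()))
        return order

    def adjacency_matrix(self) -> np.ndarray:
        """0/1 matrix A with A[i, j] = 1 iff nodes[i] -> nodes[j]."""
        idx = {n: i for i, n in enumerate(self.nodes)}
        a = np.zeros((len(self.nodes), len(self.nodes)), dtype=int)
        for c in self.nodes:
            for p in self.parents[c]:
                a[idx[p], idx[c]] = 1
        return a

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DAGStructure):
            return NotImplemented
        return self.nodes == other.nodes and dict(self.parents) == dict(other.parents)

    def skeleton(self) -> frozenset[frozenset[str]]:
        """Undirected adjacencies."""
        return frozenset(frozenset(e) for e in self.edges())

    def v_structures(self) -> frozenset[tuple[str, str, str]]:
        """Colliders p1 -> c <- p2 with p1, p2 non-adjacent (p1 < p2)."""
        skel = self.skeleton()
        out = set()
        for c in self.nodes:
            ps = sorted(self.parents[c])
            for i in range(len(ps)):
                for j in range(i + 1, len(ps)):
                    if frozenset((ps[i], ps[j])) not in skel:
                        out.add((ps[i], c, ps[j]))
        return frozenset(out)


def markov_equivalent(a: DAGStructure, b: DAGStructure) -> bool:
    """Same skeleton and same v-structures (Verma–Pearl criterion)."""
    if set(a.nodes) != set(b.nodes):
        return False
    return a.skeleton() == b.skeleton() and a.v_structures() == b.v_structures()


@dataclass(frozen=True)
class GBNParameters:
    """Per-node mean, conditional variance and parent weights.

    ``weights[child][parent]`` is the linear connectivity coefficient from
    ``parent`` into ``child``; keys must match the DAG's parent sets exactly.
    ``degenerate`` lists nodes whose ML conditional variance collapsed to
    zero (perfect linear dependence on parents) — these fits are stored but
    poison likelihood evaluation.
    """

    mean: Mapping[str, float]
    variance: Mapping[str, float]
    weights: Mapping[str, Mapping[str, float]]
    degenerate: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for node, v in self.variance.items():
            if v < 0:
                raise ParameterError(f"negative variance for node {node!r}")

    def validate_against(self, dag: DAGStructure) -> None:
        for n in dag.nodes:
            if n not in self.mean or n not in self.variance:
                raise ParameterError(f"parameters missing for node {n!r}")
            wkeys = frozenset(self.weights.get(n, {}))
            if wkeys != dag.parents[n]:
                raise ParameterError(
                    f"weight keys {sorted(wkeys)} for node {n!r} do not match "
                    f"parent set {sorted(dag.parents[n])}"
                )

    def weight_matrix(self, dag: DAGStructure) -> np.ndarray:
        """W[i, j] = coefficient from nodes[i] into nodes[j] (0 if no edge)."""
        idx = {n: i for i, n in enumerate(dag.nodes)}
        w = np.zeros((len(dag.nodes), len(dag.nodes)))
        for c in dag.nodes:
            for p, b in self.weights.get(c, {}).items():
                w[idx[p], idx[c]] = b
        return w


@dataclass(frozen=True)
class ImpliedGaussian:
    """The multivariate normal implied by a (DAG, parameters) pair."""

    nodes: tuple[str, ...]
    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self) -> None:
        cov = np.asarray(self.covariance, dtype=float)
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ParameterError("covariance must be symmetric")
        object.__setattr__(self, "covariance", cov)
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))


# ---------------------------------------------------------------------------
# data alignment helper
# ---------------------------------------------------------------------------


def _aligned_matrix(data: "np.ndarray | pd.DataFrame", nodes: Sequence[str]) -> np.ndarray:
    """Return a float matrix whose columns follow ``nodes``.

    DataFrames are reindexed by column name; bare arrays are trusted to be
    aligned already.
    """
    if isinstance(data, pd.DataFrame):
        missing = [n for n in nodes if n not in data.columns]
        if missing:
            raise ParameterError(f"data is missing columns {missing}")
        mat = data.loc[:, list(nodes)].to_numpy(dtype=float)
    else:
        mat = np.asarray(data, dtype=float)
        if mat.ndim != 2 or mat.shape[1] != len(nodes):
            raise ParameterError(
                f"expected a 2-D array with {len(nodes)} columns, got shape {mat.shape}"
            )
    if not np.all(np.isfinite(mat)):
        raise ParameterError("data contains NaN or infinite values")
    return mat


# ---------------------------------------------------------------------------
# fitting and scoring
# ---------------------------------------------------------------------------


def fit_ml_parameters(
    data: "np.ndarray | pd.DataFrame", dag: DAGStructure
) -> GBNParameters:
    """Maximum-likelihood parameters of ``dag`` on ``data``.

    Each node is regressed (with intercept) on its parents; the reported
    variance is the ML (divide-by-N) residual variance and the reported mean
    is the node's sample mean, which under the intercept-included regression
    is exactly the fitted unconditional mean.
    """
    x = _aligned_matrix(data, dag.nodes)
    n = x.shape[0]
    max_pa = max((len(dag.parents[c]) for c in dag.nodes), default=0)
    if n <= max_pa + 1:
        raise ParameterError(
            f"need more than {max_pa + 1} samples to fit parent sets of size {max_pa}"
        )
    means = x.mean(axis=0)
    xc = x - means
    scatter = (xc.T @ xc) / n  # ML covariance

    idx = {node: i for i, node in enumerate(dag.nodes)}
    mean: dict[str, float] = {}
    variance: dict[str, float] = {}
    weights: dict[str, dict[str, float]] = {}
    degenerate: set[str] = set()
    for node in dag.nodes:
        i = idx[node]
        pa = sorted(dag.parents[node])
        mean[node] = float(means[i])
        if not pa:
            weights[node] = {}
            v = float(scatter[i, i])
        else:
            pi = [idx[p] for p in pa]
            gram = scatter[np.ix_(pi, pi)]
            if np.linalg.cond(gram) > _COND_LIMIT:
                raise RankDeficiencyError(
                    f"parents of node {node!r} are collinear: {pa}"
                )
            b = np.linalg.solve(gram, scatter[pi, i])
            weights[node] = {p: float(bj) for p, bj in zip(pa, b)}
            v = float(scatter[i, i] - scatter[i, pi] @ b)
        # residual variance below numerical noise means an exact linear
        # dependence on the parents: store 0 and flag the node
        if v < 1e-12 * max(scatter[i, i], 1.0):
            v = 0.0
            degenerate.add(node)
        variance[node] = v
    return GBNParameters(
        mean=mean, variance=variance, weights=weights, degenerate=frozenset(degenerate)
    )


def _residuals(
    x: np.ndarray, dag: DAGStructure, params: GBNParameters
) -> dict[str, np.ndarray]:
    idx = {node: i for i, node in enumerate(dag.nodes)}
    out: dict[str, np.ndarray] = {}
    for node in dag.nodes:
        i = idx[node]
        r = x[:, i] - params.mean[node]
        for p, b in params.weights.get(node, {}).items():
            r = r - b * (x[:, idx[p]] - params.mean[p])
        out[node] = r
    return out


def log_likelihood(
    data: "np.ndarray | pd.DataFrame", dag: DAGStructure, params: GBNParameters
) -> float:
    """Sum over samples of the log joint density under the factorized model.

    Equals the log-density of the implied multivariate Gaussian evaluated on
    the same rows (a tested invariant).  A node with zero conditional
    variance cannot be evaluated and raises
    :class:`~bnec.exceptions.DegenerateVarianceError`.
    """
    params.validate_against(dag)
    x = _aligned_matrix(data, dag.nodes)
    n = x.shape[0]
    total = 0.0
    for node, resid in _residuals(x, dag, params).items():
        v = params.variance[node]
        if v <= 0.0:
            kind = "nonzero" if float(np.max(np.abs(resid), initial=0.0)) > 1e-12 else "zero"
            raise DegenerateVarianceError(
                f"node {node!r} has zero conditional variance ({kind} residuals); "
                "the Gaussian density is unbounded there"
            )
        total += -0.5 * n * (_LOG_2PI + math.log(v)) - 0.5 * float(resid @ resid) / v
    return total


def n_free_parameters(dag: DAGStructure) -> int:
    """Intercept + variance + one weight per parent, per node."""
    return sum(len(dag.parents[c]) + 2 for c in dag.nodes)


def bic_score(data: "np.ndarray | pd.DataFrame", dag: DAGStructure) -> float:
    """Schwarz network score: maximized log-likelihood − (d/2)·ln N.

    Larger is better.  ``d`` counts one intercept, one variance and one
    weight per parent for every node.  The maximized log-likelihood has the
    closed form −(N/2)·Σ_i (ln(2π v̂_i) + 1) at the ML variances v̂.
    """
    x = _aligned_matrix(data, dag.nodes)
    n = x.shape[0]
    params = fit_ml_parameters(x, dag)
    if params.degenerate:
        raise DegenerateVarianceError(
            f"degenerate ML fit (zero variance) for nodes {sorted(params.degenerate)}"
        )
    ll = -0.5 * n * sum(
        _LOG_2PI + math.log(params.variance[c]) + 1.0 for c in dag.nodes
    )
    return ll - 0.5 * n_free_parameters(dag) * math.log(n)


# ---------------------------------------------------------------------------
# implied joint and sampling
# ---------------------------------------------------------------------------


def implied_joint(dag: DAGStructure, params: GBNParameters) -> ImpliedGaussian:
    """Mean and covariance of the multivariate Gaussian the BN encodes.

    Writing the structural equations as ``x − m = Wᵀ(x − m) + ε`` with
    ``W[p, c]`` the parent-to-child weight matrix and ``ε ~ N(0, diag(v))``,
    the centred solution is ``(I − Wᵀ)⁻¹ ε`` so the covariance is
    ``(I − Wᵀ)⁻¹ diag(v) (I − Wᵀ)⁻ᵀ``.
    """
    params.validate_against(dag)
    k = len(dag.nodes)
    w = params.weight_matrix(dag)
    u = np.eye(k) - w.T
    inv = np.linalg.solve(u, np.eye(k))
    d = np.diag([params.variance[n] for n in dag.nodes])
    cov = inv @ d @ inv.T
    cov = 0.5 * (cov + cov.T)
    mean = np.array([params.mean[n] for n in dag.nodes])
    return ImpliedGaussian(nodes=dag.nodes, mean=mean, covariance=cov)


def sample_from_bn(
    dag: DAGStructure,
    params: GBNParameters,
    n: int,
    seed: "int | np.random.Generator | np.random.SeedSequence",
) -> np.ndarray:
    """Ancestral sampling: draw ``n`` joint samples in topological order.

    Returns an (n, len(nodes)) array with columns in ``dag.nodes`` order.
    Deterministic for a fixed seed.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    params.validate_against(dag)
    rng = np.random.default_rng(seed)
    idx = {node: i for i, node in enumerate(dag.nodes)}
    out = np.empty((n, len(dag.nodes)))
    for node in dag.topological_order():
        i = idx[node]
        loc = np.full(n, params.mean[node])
        for p, b in params.weights.get(node, {}).items():
            loc += b * (out[:, idx[p]] - params.mean[p])
        v = params.variance[node]
        if v > 0:
            out[:, i] = loc + math.sqrt(v) * rng.standard_normal(n)
        else:
            out[:, i] = loc
    return out
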