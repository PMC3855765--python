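"""Between-group and brain–behavior statistics.

Group-level networks are learned from per-subject standardized series
concatenated along time; subject-level networks give per-subject
convergence-index distributions.  Group differences in directed connection
weights are assessed by a randomized permutation test: subjects are
relabeled into two groups of the original sizes, both group networks are
re-learned from scratch, and the weight differences recomputed — the
reference distribution for two one-sided p-values per ordered region pair
(absent edges carry weight zero, so disappearing or reversing connections
are covered by the same statistic).  Classical layers — two-sample
t-tests on FC and CI, Pearson and Spearman correlations — ride on scipy.

Permutation p-values use add-one smoothing, ``(#{extreme} + 1)/(B + 1)``,
with ties counted as extreme, so they are never zero and the test is
conservative under the null.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .exceptions import DataError, DegenerateInputError, ParameterError
from .gbn import GBNParameters
from .metrics import ConvergenceIndexTable, classify_regions, convergence_index
from .search import (
    LocalScores,
    SearchResult,
    parameters_from_scores,
    search_from_stats,
)
from .synthetic import CohortTimeSeries


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AssociationResult:
    """A correlation between two named variables."""

    x_name: str
    y_name: str
    coefficient: float
    p_value: float
    n: int
    method: str

    def __post_init__(self) -> None:
        if abs(self.coefficient) > 1 + 1e-12:
            raise ParameterError("|coefficient| must be <= 1")


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    p_value: float
    n_a: int
    n_b: int


@dataclass(frozen=True)
class EdgeComparisonResult:
    """Permutation outcome for one ordered region pair."""

    parent: str
    child: str
    weight_a: float
    weight_b: float
    diff: float
    p_a_gt_b: float
    p_b_gt_a: float
    n_permutations: int
    seed: int


@dataclass(frozen=True)
class EdgePermutationSummary:
    """All ordered pairs of one permutation run, plus the group fits."""

    nodes: tuple[str, ...]
    group_a: str
    group_b: str
    weights_a: np.ndarray
    weights_b: np.ndarray
    p_a_gt_b: np.ndarray
    p_b_gt_a: np.ndarray
    n_permutations: int
    seed: int
    result_a: SearchResult
    result_b: SearchResult

    @property
    def diff(self) -> np.ndarray:
        return self.weights_a - self.weights_b

    def results(self) -> list[EdgeComparisonResult]:
        out = []
        k = len(self.nodes)
        for i in range(k):
            for j in range(k):
                if i == j:
                    continue
                out.append(
                    EdgeComparisonResult(
                        parent=self.nodes[i],
                        child=self.nodes[j],
                        weight_a=float(self.weights_a[i, j]),
                        weight_b=float(self.weights_b[i, j]),
                        diff=float(self.diff[i, j]),
                        p_a_gt_b=float(self.p_a_gt_b[i, j]),
                        p_b_gt_a=float(self.p_b_gt_a[i, j]),
                        n_permutations=self.n_permutations,
                        seed=self.seed,
                    )
                )
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "parent": r.parent,
                    "child": r.child,
                    "weight_a": r.weight_a,
                    "weight_b": r.weight_b,
                    "diff": r.diff,
                    "p_a_gt_b": r.p_a_gt_b,
                    "p_b_gt_a": r.p_b_gt_a,
                }
                for r in self.results()
            ]
        )


@dataclass(frozen=True)
class SubjectFit:
    subject_id: str
    group: str
    result: SearchResult
    parameters: GBNParameters
    ci_table: ConvergenceIndexTable


# ---------------------------------------------------------------------------
# standardization and sufficient statistics
# ---------------------------------------------------------------------------


def standardize_columns(x: np.ndarray, names: Sequence[str] | None = None) -> np.ndarray:
    """Zero-mean, unit-variance columns (population std)."""
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    if np.any(sd <= 0):
        which = (
            [names[i] for i in np.flatnonzero(sd <= 0)]
            if names is not None
            else list(np.flatnonzero(sd <= 0))
        )
        raise DegenerateInputError(f"constant columns cannot be standardized: {which}")
    return (x - mu) / sd


def subject_grams(cohort: CohortTimeSeries) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-subject Gram matrices of standardized series.

    Returns ``(grams, n_rows, labels)`` where ``grams[s]`` is XᵀX of
    subject ``s`` after column standardization.  Pooling a subset of
    subjects then reduces to summing their Grams — the covariance algebra
    that makes permutation re-fits cheap.
    """
    grams = []
    n_rows = []
    labels = []
    for s in cohort.subjects:
        z = standardize_columns(s.data, cohort.region_names)
        grams.append(z.T @ z)
        n_rows.append(z.shape[0])
        labels.append(s.group)
    return np.array(grams), np.array(n_rows), np.array(labels)


def _pooled_cov(grams: np.ndarray, n_rows: np.ndarray, idx: np.ndarray) -> tuple[np.ndarray, int]:
    n = int(n_rows[idx].sum())
    cov = grams[idx].sum(axis=0) / n
    return cov, n


# ---------------------------------------------------------------------------
# group and subject network fits
# ---------------------------------------------------------------------------


def fit_group_bn(
    cohort: CohortTimeSeries,
    group: str,
    seed: int = 0,
    restarts: int = 50,
    max_parents: int = 8,
) -> tuple[SearchResult, GBNParameters]:
    """Learn one group's network from concatenated standardized subjects.

    Each subject's columns are standardized (so amplitude differences and
    per-subject affine rescalings drop out), subjects are concatenated
    along time, the structure is learned by the candidate-restricted BIC
    search, and parameters are the ML fit on the pooled matrix.
    """
    members = cohort.subjects_in(group)
    if len(members) < 2:
        raise DataError(f"group {group!r} has fewer than 2 subjects")
    grams, n_rows, labels = subject_grams(cohort)
    idx = np.flatnonzero(labels == group)
    cov, n = _pooled_cov(grams, n_rows, idx)
    result, scores = search_from_stats(
        cov, n, cohort.region_names, restarts=restarts, seed=seed,
        max_parents=max_parents,
    )
    params = parameters_from_scores(result.dag, scores)
    return result, params


def fit_subject_bns(
    cohort: CohortTimeSeries,
    seed: int = 0,
    restarts: int = 10,
    max_parents: int = 8,
) -> list[SubjectFit]:
    """Independent structure learning per subject, with CI tables."""
    fits = []
    for s in cohort.subjects:
        if s.data.shape[0] < 20:
            raise DataError(
                f"subject {s.subject_id!r} has fewer than 20 timepoints"
            )
        z = standardize_columns(s.data, cohort.region_names)
        n = z.shape[0]
        cov = (z.T @ z) / n
        result, scores = search_from_stats(
            cov, n, cohort.region_names, restarts=restarts, seed=seed,
            max_parents=max_parents,
        )
        params = parameters_from_scores(result.dag, scores)
        ci = classify_regions(convergence_index(result.dag, scope=s.subject_id))
        fits.append(
            SubjectFit(
                subject_id=s.subject_id,
                group=s.group,
                result=result,
                parameters=params,
                ci_table=ci,
            )
        )
    return fits


# ---------------------------------------------------------------------------
# permutation test on directed connection weights
# ---------------------------------------------------------------------------


def _weights_from_stats(
    cov: np.ndarray,
    n: int,
    nodes: tuple[str, ...],
    restarts: int,
    fit_entropy: list[int],
    max_parents: int,
) -> tuple[np.ndarray, SearchResult, LocalScores]:
    result, scores = search_from_stats(
        cov, n, nodes, restarts=restarts, seed=np.random.SeedSequence(fit_entropy),
        max_parents=max_parents,
    )
    params = parameters_from_scores(result.dag, scores)
    return params.weight_matrix(result.dag), result, scores


def permutation_test_edges(
    cohort: CohortTimeSeries,
    n_permutations: int = 1000,
    seed: int = 0,
    restarts: int = 10,
    max_parents: int = 8,
    group_a: str | None = None,
    group_b: str | None = None,
) -> EdgePermutationSummary:
    """Permutation test for group differences in directed weights.

    The observed statistic per ordered pair is the group-A minus group-B
    ML weight (zero when the learned network lacks the edge).  For each of
    ``n_permutations`` seeded relabelings preserving group sizes, both
    group networks are re-learned and the differences recorded; one-sided
    add-one-smoothed p-values are reported in both directions.

    The relabeling permutes the label vector itself, so swapping the two
    group labels in the input exactly swaps ``p_a_gt_b`` and ``p_b_gt_a``.
    """
    if n_permutations < 1:
        raise ParameterError("n_permutations must be >= 1")
    groups = cohort.groups()
    if group_a is None or group_b is None:
        if len(groups) != 2:
            raise DataError(
                f"cohort has groups {groups}; specify group_a and group_b"
            )
        group_a, group_b = groups
    for g in (group_a, group_b):
        if len(cohort.subjects_in(g)) < 2:
            raise DataError(f"group {g!r} has fewer than 2 subjects")

    grams, n_rows, labels = subject_grams(cohort)
    nodes = cohort.region_names
    keep = np.isin(labels, [group_a, group_b])
    grams, n_rows, labels = grams[keep], n_rows[keep], labels[keep]

    # one fixed fitting stream for every fit: identical restart orderings in
    # the observed and all permuted fits keeps the statistic exchangeable
    fit_entropy = [int(seed) & 0x7FFFFFFF, 0xB1C]

    def both(lab: np.ndarray) -> np.ndarray:
        wa, _, _ = _weights_from_stats(
            *_pooled_cov(grams, n_rows, np.flatnonzero(lab == group_a)),
            nodes, restarts, fit_entropy, max_parents,
        )
        wb, _, _ = _weights_from_stats(
            *_pooled_cov(grams, n_rows, np.flatnonzero(lab == group_b)),
            nodes, restarts, fit_entropy, max_parents,
        )
        return wa - wb

    cov_a, n_a = _pooled_cov(grams, n_rows, np.flatnonzero(labels == group_a))
    cov_b, n_b = _pooled_cov(grams, n_rows, np.flatnonzero(labels == group_b))
    weights_a, result_a, _ = _weights_from_stats(
        cov_a, n_a, nodes, restarts, fit_entropy, max_parents
    )
    weights_b, result_b, _ = _weights_from_stats(
        cov_b, n_b, nodes, restarts, fit_entropy, max_parents
    )
    observed = weights_a - weights_b

    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 1]))
    count_ge = np.zeros_like(observed)
    count_le = np.zeros_like(observed)
    for _ in range(n_permutations):
        perm = rng.permutation(len(labels))
        d = both(labels[perm])
        count_ge += d >= observed - 1e-12
        count_le += d <= observed + 1e-12
    b = n_permutations
    p_a_gt_b = (count_ge + 1.0) / (b + 1.0)
    p_b_gt_a = (count_le + 1.0) / (b + 1.0)

    return EdgePermutationSummary(
        nodes=nodes,
        group_a=group_a,
        group_b=group_b,
        weights_a=weights_a,
        weights_b=weights_b,
        p_a_gt_b=p_a_gt_b,
        p_b_gt_a=p_b_gt_a,
        n_permutations=n_permutations,
        seed=int(seed),
        result_a=result_a,
        result_b=result_b,
    )


# ---------------------------------------------------------------------------
# classical layers
# ---------------------------------------------------------------------------


def two_sample_ttest(
    values_a: Sequence[float],
    values_b: Sequence[float],
    equal_var: bool = True,
) -> TTestResult:
    """Two-sided two-sample t-test (pooled variance by default)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ParameterError("each group needs at least 2 values")
    if np.var(a, ddof=1) + np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return TTestResult(statistic=0.0, p_value=1.0, n_a=len(a), n_b=len(b))
        raise DegenerateInputError("zero pooled variance with unequal means")
    t, p = scipy.stats.ttest_ind(a, b, equal_var=equal_var)
    return TTestResult(statistic=float(t), p_value=float(p), n_a=len(a), n_b=len(b))


def _check_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be 1-D and equally long")
    if len(x) < 3:
        raise ParameterError("need at least 3 pairs")
    return x, y


def pearson_correlation(
    x: Sequence[float], y: Sequence[float],
    x_name: str = "x", y_name: str = "y",
) -> AssociationResult:
    """Product-moment correlation with the two-sided t-approximation p."""
    x, y = _check_pair(x, y)
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateInputError("constant input to Pearson correlation")
    r, p = scipy.stats.pearsonr(x, y)
    return AssociationResult(
        x_name=x_name, y_name=y_name, coefficient=float(r), p_value=float(p),
        n=len(x), method="pearson",
    )


def spearman_correlation(
    x: Sequence[float], y: Sequence[float],
    x_name: str = "x", y_name: str = "y",
) -> AssociationResult:
    """Rank correlation: Pearson r of mid-ranks (average ranks on ties)."""
    x, y = _check_pair(x, y)
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateInputError("constant input to Spearman correlation")
    rho, p = scipy.stats.spearmanr(x, y)
    return AssociationResult(
        x_name=x_name, y_name=y_name, coefficient=float(rho), p_value=float(p),
        n=len(x), method="spearman",
    )


# ---------------------------------------------------------------------------
# convenience tables used by the pipeline
# ---------------------------------------------------------------------------


def compare_ci_between_groups(
    fits: Sequence[SubjectFit], group_a: str, group_b: str
) -> pd.DataFrame:
    """Two-sample t-test of subject-level CI per region."""
    regions = fits[0].ci_table.regions
    rows = []
    for ri, region in enumerate(regions):
        va = [f.ci_table.ci[ri] for f in fits if f.group == group_a]
        vb = [f.ci_table.ci[ri] for f in fits if f.group == group_b]
        try:
            res = two_sample_ttest(va, vb)
            t, p = res.statistic, res.p_value
        except DegenerateInputError:
            t, p = np.nan, np.nan
        rows.append(
            {
                "region": region,
                "mean_a": float(np.mean(va)),
                "sd_a": float(np.std(va, ddof=1)),
                "mean_b": float(np.mean(vb)),
                "sd_b": float(np.std(vb, ddof=1)),
                "t": t,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def compare_fc_between_groups(
    fc_z: pd.DataFrame, groups: pd.Series, group_a: str, group_b: str
) -> pd.DataFrame:
    """Two-sample t-test of per-region FC z-scores between groups."""
    rows = []
    ga = groups == group_a
    gb = groups == group_b
    for region in fc_z.columns:
        res = two_sample_ttest(fc_z.loc[ga, region], fc_z.loc[gb, region])
        rows.append(
            {
                "region": region,
                "mean_a": float(fc_z.loc[ga, region].mean()),
                "mean_b": float(fc_z.loc[gb, region].mean()),
                "t": res.statistic,
                "p": res.p_value,
            }
        )
    return pd.DataFrame(rows)
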