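"""BIC search-and-score structure learning.

The learner follows the classic two-stage construction for linear Gaussian
networks: (1) for every node, compute the L1-regularization path of its
penalized regression on all other nodes and keep the variables in the order
they enter the path — the nested unions-so-far are that node's candidate
parent sets; (2) search for the acyclic structure maximizing the BIC score
with each node's parents restricted to its candidate sets, using an
order-based greedy search with seeded random restarts.  An exhaustive
enumerator over all labeled DAGs (practical up to 5 nodes) serves as an
exact oracle.

All scoring goes through sufficient statistics (sample size + ML
covariance), so the same machinery runs on raw matrices and on pooled
per-subject Gram matrices inside permutation loops without touching the
data again.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, ParameterError
from .gbn import DAGStructure, GBNParameters, _aligned_matrix

_LOG_2PI = math.log(2.0 * math.pi)
_TIE_TOL = 1e-9
_PATH_TOL = 1e-10


# ---------------------------------------------------------------------------
# L1-regularization path (LARS homotopy on sufficient statistics)
# ---------------------------------------------------------------------------


def _lasso_events(gram: np.ndarray, corr: np.ndarray) -> list[tuple[float, frozenset[int]]]:
    """Breakpoints of the lasso path from predictor Gram/target correlations.

    ``gram`` is the (p, p) predictor second-moment matrix and ``corr`` the
    (p,) predictor-target vector, both on the 1/N scale of standardized
    data.  Returns ``(penalty, active_set)`` at every active-set change,
    ordered by decreasing penalty and starting from the empty set.

    Implementation is the standard LARS homotopy with the lasso
    modification (variables can leave the active set when a coefficient
    crosses zero); only the breakpoints are retained.
    """
    p = corr.shape[0]
    events: list[tuple[float, frozenset[int]]] = [(math.inf, frozenset())]
    if p == 0:
        return events
    beta = np.zeros(p)
    chat = corr.astype(float).copy()
    active: list[int] = []
    lam = float(np.max(np.abs(chat)))
    if lam <= _PATH_TOL:
        return events
    # first entry
    j0 = int(np.argmax(np.abs(chat)))
    active.append(j0)
    events.append((lam, frozenset(active)))

    max_iter = 8 * p * p + 16
    for _ in range(max_iter):
        if lam <= _PATH_TOL:
            break
        a_idx = np.array(active)
        s = np.sign(chat[a_idx])
        sub = gram[np.ix_(a_idx, a_idx)]
        try:
            d = np.linalg.solve(sub, s)
        except np.linalg.LinAlgError:
            break  # active set collinear; the path cannot proceed
        adir = gram[:, a_idx] @ d

        gamma = lam  # shrink all the way to the unpenalized solution
        kind, who = "end", -1
        active_set = set(active)
        for j in range(p):
            if j in active_set:
                continue
            for num, den in ((lam - chat[j], 1.0 - adir[j]), (lam + chat[j], 1.0 + adir[j])):
                if den > _PATH_TOL:
                    g = num / den
                    if _PATH_TOL < g < gamma - _PATH_TOL:
                        gamma, kind, who = g, "join", j
        for pos, k in enumerate(active):
            if d[pos] != 0.0:
                g = -beta[k] / d[pos]
                if _PATH_TOL < g < gamma - _PATH_TOL:
                    gamma, kind, who = g, "drop", k

        beta[a_idx] += gamma * d
        chat -= gamma * adir
        lam -= gamma
        if kind == "join":
            active.append(who)
            events.append((lam, frozenset(active)))
        elif kind == "drop":
            active.remove(who)
            beta[who] = 0.0
            events.append((lam, frozenset(active)))
        else:
            break
    return events


def _entry_order(events: list[tuple[float, frozenset[int]]]) -> list[tuple[float, int]]:
    """(penalty, variable) at first activation, in entry order."""
    seen: set[int] = set()
    order: list[tuple[float, int]] = []
    for lam, aset in events:
        for j in sorted(aset - seen):
            order.append((lam, j))
            seen.add(j)
    return order


@dataclass(frozen=True)
class ParentCandidatePath:
    """Per-node nested candidate parent sets from the L1 path.

    ``sets[node]`` is a list of ``(penalty, frozenset_of_parent_names)``
    ordered by decreasing penalty, starting with the empty set; each set is
    the union of all variables activated so far (monotone nesting).
    """

    sets: Mapping[str, list[tuple[float, frozenset[str]]]]

    def __post_init__(self) -> None:
        for node, seq in self.sets.items():
            prev: frozenset[str] = frozenset()
            for _, s in seq:
                if node in s:
                    raise ParameterError(f"candidate set for {node!r} contains itself")
                if not prev <= s:
                    raise ParameterError(f"candidate sets for {node!r} are not nested")
                prev = s


def _correlation_from_cov(cov: np.ndarray, nodes: Sequence[str]) -> np.ndarray:
    d = np.diag(cov).copy()
    bad = [nodes[i] for i in range(len(nodes)) if d[i] <= 0]
    if bad:
        raise DegenerateInputError(f"constant columns (zero variance): {bad}")
    s = np.sqrt(d)
    return cov / np.outer(s, s)


def _candidate_paths_from_corr(
    corr: np.ndarray, nodes: Sequence[str]
) -> dict[str, list[tuple[float, frozenset[str]]]]:
    k = len(nodes)
    out: dict[str, list[tuple[float, frozenset[str]]]] = {}
    for i, node in enumerate(nodes):
        others = [j for j in range(k) if j != i]
        gram = corr[np.ix_(others, others)]
        c = corr[others, i]
        events = _lasso_events(gram, c)
        entry = _entry_order(events)
        sets: list[tuple[float, frozenset[str]]] = [(math.inf, frozenset())]
        cum: set[str] = set()
        for lam, j in entry:
            cum.add(nodes[others[j]])
            sets.append((lam, frozenset(cum)))
        out[node] = sets
    return out


def l1_parent_path(
    data: "np.ndarray | pd.DataFrame", node: str, nodes: Sequence[str] | None = None
) -> list[tuple[float, frozenset[str]]]:
    """Candidate parent sets of ``node`` from its lasso path on all others.

    Columns are standardized internally before the path is computed.  The
    result starts with the empty set (infinite penalty) and grows by the
    order in which variables enter the path.
    """
    if isinstance(data, pd.DataFrame):
        nodes = tuple(data.columns)
    elif nodes is None:
        raise ParameterError("node names required when data is a bare array")
    if node not in nodes:
        raise ParameterError(f"unknown node {node!r}")
    x = _aligned_matrix(data, nodes)
    cov = np.cov(x, rowvar=False, bias=True)
    corr = _correlation_from_cov(np.atleast_2d(cov), nodes)
    return _candidate_paths_from_corr(corr, nodes)[node]


def candidate_parent_paths(
    data: "np.ndarray | pd.DataFrame", nodes: Sequence[str] | None = None
) -> ParentCandidatePath:
    """L1 candidate paths for every node (see :func:`l1_parent_path`)."""
    if isinstance(data, pd.DataFrame):
        nodes = tuple(data.columns)
    elif nodes is None:
        raise ParameterError("node names required when data is a bare array")
    x = _aligned_matrix(data, nodes)
    cov = np.cov(x, rowvar=False, bias=True)
    corr = _correlation_from_cov(np.atleast_2d(cov), nodes)
    return ParentCandidatePath(sets=_candidate_paths_from_corr(corr, nodes))


# ---------------------------------------------------------------------------
# decomposable BIC local scores from sufficient statistics
# ---------------------------------------------------------------------------


class LocalScores:
    """Cached per-node BIC local scores from an ML covariance matrix.

    ``local(i, mask)`` returns the contribution of node ``i`` with the
    parent set encoded as a bitmask over node indices:
    ``−(N/2)(ln 2πv̂ + 1) − ((k+2)/2) ln N`` with ``v̂`` the ML residual
    variance of the regression of ``i`` on the masked parents.
    """

    def __init__(self, cov: np.ndarray, n: int):
        self.cov = np.asarray(cov, dtype=float)
        self.n = int(n)
        self._logn = math.log(self.n)
        self._rows: list[list[float]] = self.cov.tolist()
        self._cache: dict[tuple[int, int], float] = {}
        self._members: dict[int, tuple[int, ...]] = {}
        self.evaluations = 0

    def _mask_members(self, mask: int) -> tuple[int, ...]:
        got = self._members.get(mask)
        if got is None:
            got = tuple(i for i in range(self.cov.shape[0]) if mask >> i & 1)
            self._members[mask] = got
        return got

    def residual_variance(self, i: int, mask: int) -> float:
        # hand-rolled Cholesky on plain lists: the matrices are tiny (at
        # most max_parents square) and this sits in the innermost loop of
        # permutation re-fits, where numpy call overhead dominates
        rows = self._rows
        if mask == 0:
            return rows[i][i]
        pi = self._mask_members(mask)
        k = len(pi)
        if k == 1:
            p = pi[0]
            dpp = rows[p][p]
            if dpp <= 0.0:
                return -1.0
            c = rows[p][i]
            return rows[i][i] - c * c / dpp
        a = [[rows[p][q] for q in pi] for p in pi]
        rhs = [rows[p][i] for p in pi]
        low = [[0.0] * k for _ in range(k)]
        for r in range(k):
            lr = low[r]
            ar = a[r]
            for c in range(r):
                s = ar[c]
                lc = low[c]
                for m in range(c):
                    s -= lr[m] * lc[m]
                lr[c] = s / lc[c]
            s = ar[r]
            for m in range(r):
                s -= lr[m] * lr[m]
            if s <= 1e-300:
                return -1.0
            lr[r] = math.sqrt(s)
        y = [0.0] * k
        for r in range(k):
            s = rhs[r]
            lr = low[r]
            for m in range(r):
                s -= lr[m] * y[m]
            y[r] = s / lr[r]
        return rows[i][i] - sum(t * t for t in y)

    def fit(self, i: int, mask: int) -> tuple[np.ndarray, float]:
        """Weights (ordered by parent index) and ML residual variance."""
        cov = self.cov
        if mask == 0:
            return np.zeros(0), float(cov[i, i])
        pi = self._mask_members(mask)
        b = np.linalg.solve(cov[np.ix_(pi, pi)], cov[pi, i])
        v = float(cov[i, i] - cov[i, pi] @ b)
        return b, max(v, 0.0)

    def local(self, i: int, mask: int) -> float:
        key = (i, mask)
        got = self._cache.get(key)
        if got is not None:
            return got
        self.evaluations += 1
        v = self.residual_variance(i, mask)
        if v <= 1e-300 or not math.isfinite(v):
            score = -math.inf  # degenerate/collinear parent set: never selected
        else:
            k = mask.bit_count()
            score = (
                -0.5 * self.n * (_LOG_2PI + math.log(v) + 1.0)
                - 0.5 * (k + 2) * self._logn
            )
        self._cache[key] = score
        return score


def _stats_from_data(
    data: "np.ndarray | pd.DataFrame", nodes: Sequence[str] | None
) -> tuple[np.ndarray, int, tuple[str, ...]]:
    if isinstance(data, pd.DataFrame):
        nodes = tuple(data.columns)
    elif nodes is None:
        raise ParameterError("node names required when data is a bare array")
    else:
        nodes = tuple(nodes)
    x = _aligned_matrix(data, nodes)
    n = x.shape[0]
    if n < 3:
        raise ParameterError("need at least 3 samples")
    xc = x - x.mean(axis=0)
    cov = (xc.T @ xc) / n
    return cov, n, nodes


# ---------------------------------------------------------------------------
# search result container
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SearchResult:
    """Outcome of a structure search."""

    dag: DAGStructure
    score: float
    method: str
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# order-based greedy search over candidate-restricted structures
# ---------------------------------------------------------------------------


def _candidate_masks(
    candidates: ParentCandidatePath,
    nodes: tuple[str, ...],
    max_parents: int,
) -> list[list[int]]:
    idx = {n: i for i, n in enumerate(nodes)}
    masks: list[list[int]] = []
    for node in nodes:
        if node not in candidates.sets:
            raise ParameterError(f"candidates missing for node {node!r}")
        seen: set[int] = set()
        seq: list[int] = []
        for _, s in candidates.sets[node]:
            if len(s) > max_parents:
                continue  # truncation: larger unions along the path are cut
            m = 0
            for p in s:
                m |= 1 << idx[p]
            if m not in seen:
                seen.add(m)
                seq.append(m)
        if 0 not in seen:
            seq.insert(0, 0)
        masks.append(seq)
    return masks


def _edges_of_assignment(
    assign: Sequence[int], nodes: tuple[str, ...]
) -> tuple[tuple[str, str], ...]:
    edges = []
    for c, mask in enumerate(assign):
        m = mask
        while m:
            p = (m & -m).bit_length() - 1
            edges.append((nodes[p], nodes[c]))
            m &= m - 1
    return tuple(sorted(edges))


def _evaluate_order(
    order: Sequence[int],
    cand_masks: list[list[int]],
    scores: LocalScores,
) -> tuple[float, list[int]]:
    preds = 0
    total = 0.0
    assign = [0] * len(order)
    for node in order:
        best_s = -math.inf
        best_m = 0
        seen: set[int] = set()
        for pm in cand_masks[node]:
            m = pm & preds
            if m in seen:
                continue
            seen.add(m)
            s = scores.local(node, m)
            if s > best_s:
                best_s, best_m = s, m
        total += best_s
        assign[node] = best_m
        preds |= 1 << node
    return total, assign


def _bits(mask: int) -> list[int]:
    out = []
    while mask:
        b = mask & -mask
        out.append(b)
        mask &= mask - 1
    return out


def _refine_assignment(
    order: Sequence[int],
    assign: list[int],
    cand_masks: list[list[int]],
    scores: LocalScores,
    max_parents: int,
) -> list[int]:
    """Greedy add/drop of single parents within each node's candidate union.

    The ordering (hence acyclicity) is fixed; per node the parent set is
    improved over subsets of the candidate union restricted to predecessors,
    which covers non-prefix subsets the nested path sets cannot express.
    """
    union = [0] * len(assign)
    for node, seq in enumerate(cand_masks):
        for m in seq:
            union[node] |= m
    preds = 0
    out = list(assign)
    for node in order:
        allowed = union[node] & preds
        cur = out[node]
        cur_s = scores.local(node, cur)
        improved = True
        while improved:
            improved = False
            best_m, best_s = cur, cur_s
            for b in _bits(cur):
                m = cur & ~b
                s = scores.local(node, m)
                if s > best_s + _TIE_TOL:
                    best_m, best_s = m, s
            if cur.bit_count() < max_parents:
                for b in _bits(allowed & ~cur):
                    m = cur | b
                    s = scores.local(node, m)
                    if s > best_s + _TIE_TOL:
                        best_m, best_s = m, s
            if best_m != cur:
                cur, cur_s = best_m, best_s
                improved = True
        out[node] = cur
        preds |= 1 << node
    return out


def _creates_cycle(assign: Sequence[int], parent: int, child: int) -> bool:
    """Would adding parent -> child close a directed cycle?

    Walks ancestors of ``parent`` through the parent masks.
    """
    seen = 1 << parent
    stack = [parent]
    target = 1 << child
    while stack:
        i = stack.pop()
        m = assign[i] & ~seen
        if m & target:
            return True
        seen |= m
        while m:
            stack.append((m & -m).bit_length() - 1)
            m &= m - 1
    return False


def _hill_climb_dag(
    assign: list[int],
    union: list[int],
    scores: LocalScores,
    max_parents: int,
) -> list[int]:
    """Steepest-ascent edge moves: add / delete / reverse within candidates.

    Complements the order-based stage — reversals in particular can escape
    orientation local optima that no sequence of improving ordering swaps
    repairs.
    """
    k = len(assign)
    assign = list(assign)
    local = [scores.local(i, assign[i]) for i in range(k)]

    def greedy_prune(node: int, mask: int) -> tuple[int, float]:
        s = scores.local(node, mask)
        improved = True
        while improved:
            improved = False
            for b in _bits(mask):
                s2 = scores.local(node, mask & ~b)
                if s2 > s + _TIE_TOL:
                    mask, s = mask & ~b, s2
                    improved = True
        return mask, s

    while True:
        best_gain = _TIE_TOL
        best_move = None
        for c in range(k):
            m = assign[c]
            for b in _bits(m):
                p = b.bit_length() - 1
                # delete p -> c
                gain = scores.local(c, m & ~b) - local[c]
                if gain > best_gain:
                    best_gain, best_move = gain, ("del", p, c, 0, 0)
                # reverse p -> c, then greedily prune both endpoints'
                # parents: score-neutral reversals alone cannot escape an
                # equivalence-class member, but reversal-plus-prune can
                if union[p] >> c & 1 and assign[p].bit_count() < max_parents:
                    tmp = assign[c]
                    assign[c] = m & ~b
                    cycle = _creates_cycle(assign, c, p)
                    assign[c] = tmp
                    if not cycle:
                        mc, sc_ = greedy_prune(c, m & ~b)
                        mp, sp_ = greedy_prune(p, assign[p] | (1 << c))
                        if mp >> c & 1:  # keep the reversed edge itself
                            gain = sc_ - local[c] + sp_ - local[p]
                            if gain > best_gain:
                                best_gain, best_move = gain, ("rev", p, c, mc, mp)
            if m.bit_count() < max_parents:
                for b in _bits(union[c] & ~m & ~(1 << c)):
                    p = b.bit_length() - 1
                    if _creates_cycle(assign, p, c):
                        continue
                    gain = scores.local(c, m | b) - local[c]
                    if gain > best_gain:
                        best_gain, best_move = gain, ("add", p, c, 0, 0)
        if best_move is None:
            return assign
        kind, p, c, mc, mp = best_move
        if kind == "del":
            assign[c] &= ~(1 << p)
        elif kind == "add":
            assign[c] |= 1 << p
        else:
            assign[c] = mc
            assign[p] = mp
            local[p] = scores.local(p, assign[p])
        local[c] = scores.local(c, assign[c])


def _search_orderings(
    scores: LocalScores,
    cand_masks: list[list[int]],
    nodes: tuple[str, ...],
    restarts: int,
    rng: np.random.Generator,
    max_parents: int,
) -> tuple[float, list[int], dict]:
    k = len(nodes)
    union = [0] * k
    for i, seq in enumerate(cand_masks):
        for m in seq:
            union[i] |= m
    orderings_scored = 0
    ties = 0

    def better(s_new, e_new, s_old, e_old) -> bool:
        nonlocal ties
        if s_new > s_old + _TIE_TOL:
            return True
        if abs(s_new - s_old) <= _TIE_TOL:
            ties += 1
            return e_new < e_old
        return False

    best_score = -math.inf
    best_assign: list[int] = [0] * k
    best_edges: tuple = ((chr(0x10FFFF), chr(0x10FFFF)),) * (k * k + 1)

    starts: list[list[int]] = [list(range(k))]
    for _ in range(max(restarts - 1, 0)):
        starts.append([int(j) for j in rng.permutation(k)])

    choice_cache: dict[tuple[int, int], tuple[float, int]] = {}

    def choice(node: int, preds: int) -> tuple[float, int]:
        # the best candidate subset depends on the predecessors only
        # through their overlap with the node's candidate union
        key = (node, preds & union[node])
        got = choice_cache.get(key)
        if got is not None:
            return got
        best_s = -math.inf
        best_m = 0
        seen: set[int] = set()
        for pm in cand_masks[node]:
            m = pm & preds
            if m in seen:
                continue
            seen.add(m)
            s = scores.local(node, m)
            if s > best_s:
                best_s, best_m = s, m
        choice_cache[key] = (best_s, best_m)
        return best_s, best_m

    for order in starts:
        # per-node best choice under the current ordering, updated
        # incrementally: an adjacent swap only changes the two swapped nodes
        node_score = [0.0] * k
        assign = [0] * k
        preds = 0
        total = 0.0
        for node in order:
            s, m = choice(node, preds)
            node_score[node], assign[node] = s, m
            total += s
            preds |= 1 << node
        orderings_scored += 1
        improved = True
        while improved:
            improved = False
            preds = 0
            for j in range(k - 1):
                a, b = order[j], order[j + 1]
                sb2, mb2 = choice(b, preds)
                sa2, ma2 = choice(a, preds | (1 << b))
                delta = sa2 + sb2 - node_score[a] - node_score[b]
                orderings_scored += 1
                accept = delta > _TIE_TOL
                if not accept and abs(delta) <= _TIE_TOL:
                    ties += 1
                    trial = assign.copy()
                    trial[a], trial[b] = ma2, mb2
                    if _edges_of_assignment(trial, nodes) < _edges_of_assignment(assign, nodes):
                        accept = True
                if accept:
                    order[j], order[j + 1] = b, a
                    node_score[a], node_score[b] = sa2, sb2
                    assign[a], assign[b] = ma2, mb2
                    total += delta
                    improved = True
                    preds |= 1 << b
                else:
                    preds |= 1 << a
        # polish this restart: ordering-respecting subset refinement, then
        # unconstrained edge moves (add/delete/reverse-and-prune)
        assign = _refine_assignment(order, assign, cand_masks, scores, max_parents)
        assign = _hill_climb_dag(assign, union, scores, max_parents)
        total = sum(scores.local(i, m) for i, m in enumerate(assign))
        edges = _edges_of_assignment(assign, nodes)
        if better(total, edges, best_score, best_edges):
            best_score, best_assign, best_edges = total, assign, edges

    diag = {
        "orderings_scored": orderings_scored,
        "local_scores_evaluated": scores.evaluations,
        "ties_encountered": ties,
        "restarts": restarts,
    }
    return best_score, best_assign, diag


def search_from_stats(
    cov: np.ndarray,
    n: int,
    nodes: Sequence[str],
    candidates: ParentCandidatePath | None = None,
    max_parents: int = 8,
    restarts: int = 50,
    seed: "int | np.random.Generator | Sequence[int]" = 0,
) -> tuple[SearchResult, LocalScores]:
    """Candidate-restricted BIC search from (covariance, N) statistics.

    This is the engine behind :func:`search_bic_optimal` and the group /
    permutation fits: it never touches row-level data, so pooled subject
    Gram matrices can be re-searched cheaply.
    """
    nodes = tuple(nodes)
    cov = np.asarray(cov, dtype=float)
    if candidates is None:
        corr = _correlation_from_cov(cov, nodes)
        candidates = ParentCandidatePath(sets=_candidate_paths_from_corr(corr, nodes))
    scores = LocalScores(cov, n)
    cand_masks = _candidate_masks(candidates, nodes, max_parents)
    rng = np.random.default_rng(seed)
    best_score, assign, diag = _search_orderings(
        scores, cand_masks, nodes, restarts, rng, max_parents
    )
    dag = DAGStructure.from_edges(nodes, _edges_of_assignment(assign, nodes))
    result = SearchResult(
        dag=dag, score=best_score, method="path-restricted", diagnostics=diag
    )
    return result, scores


def parameters_from_scores(
    dag: DAGStructure, scores: LocalScores, means: Sequence[float] | None = None
) -> GBNParameters:
    """ML parameters of ``dag`` read off a :class:`LocalScores` cache."""
    nodes = dag.nodes
    idx = {n: i for i, n in enumerate(nodes)}
    mean = {n: float(means[idx[n]]) if means is not None else 0.0 for n in nodes}
    variance: dict[str, float] = {}
    weights: dict[str, dict[str, float]] = {}
    degenerate: set[str] = set()
    for node in nodes:
        i = idx[node]
        pa = sorted(dag.parents[node])
        mask = 0
        for p in pa:
            mask |= 1 << idx[p]
        b, v = scores.fit(i, mask)
        order = [idx[p] for p in pa]
        b_by_parent = dict(zip(sorted(order), b))
        weights[node] = {nodes[j]: float(bj) for j, bj in b_by_parent.items()}
        if v < 1e-12 * max(scores.cov[i, i], 1.0):
            v = 0.0
            degenerate.add(node)
        variance[node] = v
    return GBNParameters(
        mean=mean, variance=variance, weights=weights, degenerate=frozenset(degenerate)
    )


def search_bic_optimal(
    data: "np.ndarray | pd.DataFrame",
    candidates: ParentCandidatePath | None = None,
    max_parents: int = 8,
    restarts: int = 50,
    seed: int = 0,
    nodes: Sequence[str] | None = None,
) -> SearchResult:
    """Learn the BIC-optimal DAG restricted to L1-path candidate parents.

    Order-based greedy search with seeded restarts: node orderings are
    hill-climbed by adjacent swaps, each node taking its best-scoring
    candidate subset consistent with the ordering.  Score ties (Markov
    equivalent structures) are broken lexicographically on the sorted edge
    list, which makes the result deterministic for fixed data and seed.
    """
    cov, n, nodes = _stats_from_data(data, nodes)
    result, _ = search_from_stats(
        cov, n, nodes, candidates=candidates, max_parents=max_parents,
        restarts=restarts, seed=seed,
    )
    return result


# ---------------------------------------------------------------------------
# exhaustive enumeration oracle (n <= 5)
# ---------------------------------------------------------------------------

_MAX_EXHAUSTIVE = 5


def _is_acyclic_masks(pmasks: Sequence[int], k: int) -> bool:
    remaining = (1 << k) - 1
    while remaining:
        progressed = False
        m = remaining
        while m:
            i = (m & -m).bit_length() - 1
            m &= m - 1
            if pmasks[i] & remaining == 0:
                remaining &= ~(1 << i)
                progressed = True
        if not progressed:
            return False
    return True


def exhaustive_search(
    data: "np.ndarray | pd.DataFrame", nodes: Sequence[str] | None = None
) -> SearchResult:
    """Score every labeled DAG and return the BIC maximum (exact oracle).

    Only feasible for small systems: 25 labeled DAGs on 3 nodes, 543 on 4,
    29,281 on 5; more than 5 nodes is refused — use
    :func:`search_bic_optimal` there.
    """
    cov, n, nodes = _stats_from_data(data, nodes)
    k = len(nodes)
    if k > _MAX_EXHAUSTIVE:
        raise ParameterError(
            f"exhaustive enumeration is limited to {_MAX_EXHAUSTIVE} nodes "
            f"(got {k}); use search_bic_optimal for larger systems"
        )
    scores = LocalScores(cov, n)
    # precompute every local score
    locals_: list[dict[int, float]] = []
    for i in range(k):
        others = [j for j in range(k) if j != i]
        table: dict[int, float] = {}
        for r in range(len(others) + 1):
            for combo in itertools.combinations(others, r):
                m = 0
                for j in combo:
                    m |= 1 << j
                table[m] = scores.local(i, m)
        locals_.append(table)

    best_score = -math.inf
    best_assign: tuple[int, ...] | None = None
    best_edges: tuple = ()
    count = 0
    ties = 0
    mask_lists = [sorted(locals_[i]) for i in range(k)]
    for assign in itertools.product(*mask_lists):
        if not _is_acyclic_masks(assign, k):
            continue
        count += 1
        s = 0.0
        for i in range(k):
            s += locals_[i][assign[i]]
        if s > best_score + _TIE_TOL:
            best_score, best_assign = s, assign
            best_edges = _edges_of_assignment(assign, nodes)
        elif best_assign is not None and abs(s - best_score) <= _TIE_TOL:
            ties += 1
            e = _edges_of_assignment(assign, nodes)
            if e < best_edges:
                best_assign, best_edges = assign, e
                best_score = max(best_score, s)
    assert best_assign is not None
    dag = DAGStructure.from_edges(nodes, best_edges)
    return SearchResult(
        dag=dag,
        score=best_score,
        method="exhaustive",
        diagnostics={
            "structures_scored": count,
            "ties_encountered": ties,
            "local_scores_evaluated": scores.evaluations,
        },
    )
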