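"""Synthetic two-group cohorts with known ground truth.

The study design this generator emulates: two groups (a patient group and
matched controls, 17 subjects each), one resting-state scan per subject
(190 retained volumes at TR = 2 s), and nine default-mode-network regions
— PCC, dorsal/ventral MPFC, bilateral IPL, bilateral LTC and bilateral
hippocampus.  Each group has its own linear Gaussian Bayesian network;
group contrasts are planted by editing individual connection weights.
Optional AR(1) coloring mimics the temporal autocorrelation of fMRI that
the (iid) network model ignores, and per-subject covariates (functional
connectivity z-scores, cognitive scores) are drawn correlated with planted
connectivity metrics so brain–behavior analyses have a known answer.

All randomness descends from one integer seed through
``numpy.random.SeedSequence`` entropy lists, so sub-streams (per group, per
subject, per covariate) are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.signal

from .exceptions import AcyclicityError, DataError, ParameterError
from .gbn import DAGStructure, GBNParameters, sample_from_bn

#: Canonical region labels of the nine-node default mode network.
DMN_REGIONS = (
    "PCC", "dMPFC", "vMPFC", "lIPL", "rIPL", "lLTC", "rLTC", "lHC", "rHC",
)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CovariateLink:
    """How a behavioral covariate tracks a planted connectivity metric.

    ``metric`` names the linked quantity: ``"ci:REGION"`` (the region's
    true in-degree in the subject's group network), ``"weight:P->C"`` (a
    true edge weight) or ``"fc:REGION"`` (the subject's simulated FC
    z-score).  ``strength`` is the target correlation; ``noise_scale``
    multiplies the independent noise component.
    """

    metric: str
    strength: float
    noise_scale: float = 1.0

    def __post_init__(self) -> None:
        if not -1.0 <= self.strength <= 1.0:
            raise ParameterError("correlation strength must lie in [-1, 1]")
        if self.noise_scale < 0:
            raise ParameterError("noise_scale must be nonnegative")


@dataclass(frozen=True)
class SubjectSeries:
    subject_id: str
    group: str
    data: np.ndarray  # timepoints x regions


@dataclass(frozen=True)
class CohortTimeSeries:
    """Per-subject ROI matrices sharing one region ordering."""

    region_names: tuple[str, ...]
    subjects: tuple[SubjectSeries, ...]

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise DataError("duplicate subject identifiers")
        for s in self.subjects:
            if s.data.ndim != 2 or s.data.shape[1] != len(self.region_names):
                raise DataError(
                    f"subject {s.subject_id!r} matrix has shape {s.data.shape}, "
                    f"expected (*, {len(self.region_names)})"
                )
            if not np.all(np.isfinite(s.data)):
                raise DataError(f"subject {s.subject_id!r} has non-finite values")

    def groups(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for s in self.subjects:
            seen.setdefault(s.group, None)
        return tuple(seen)

    def subjects_in(self, group: str) -> tuple[SubjectSeries, ...]:
        return tuple(s for s in self.subjects if s.group == group)


@dataclass(frozen=True)
class CohortConfig:
    """Everything needed to generate a two-group cohort reproducibly."""

    n_group_a: int
    n_group_b: int
    n_timepoints: int
    region_names: tuple[str, ...]
    dag_a: DAGStructure
    params_a: GBNParameters
    dag_b: DAGStructure
    params_b: GBNParameters
    ar1_coefficient: float = 0.0
    covariate_spec: Mapping[str, CovariateLink] = field(default_factory=dict)
    seed: int = 0
    group_a_label: str = "control"
    group_b_label: str = "patient"
    # optional per-group seeds: regenerating one group leaves the other intact
    seed_a: int | None = None
    seed_b: int | None = None
    fc_baseline: float = 1.0
    fc_ci_scale: float = 0.2
    fc_noise_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.n_group_a < 2 or self.n_group_b < 2:
            raise ParameterError("each group needs at least 2 subjects")
        if self.n_timepoints < len(self.region_names) + 2:
            raise ParameterError(
                "n_timepoints must be at least number of regions + 2"
            )
        if not 0.0 <= self.ar1_coefficient < 1.0:
            raise ParameterError("ar1_coefficient must lie in [0, 1)")
        region_names = tuple(self.region_names)
        object.__setattr__(self, "region_names", region_names)
        if self.dag_a.nodes != region_names or self.dag_b.nodes != region_names:
            raise ParameterError("both DAGs must be defined over region_names, in order")
        self.params_a.validate_against(self.dag_a)
        self.params_b.validate_against(self.dag_b)
        if self.group_a_label == self.group_b_label:
            raise ParameterError("group labels must differ")


@dataclass(frozen=True)
class SyntheticCohort:
    """Generated cohort plus the configuration that produced it."""

    timeseries: CohortTimeSeries
    fc_z: pd.DataFrame          # subjects x regions
    covariates: pd.DataFrame    # subjects x covariates (+ group column)
    config: CohortConfig


# ---------------------------------------------------------------------------
# ground-truth construction
# ---------------------------------------------------------------------------


def random_dag(
    n_nodes: int,
    edge_prob: float,
    weight_range: tuple[float, float],
    seed: "int | np.random.Generator | Sequence[int]",
    node_names: Sequence[str] | None = None,
    random_sign: bool = False,
    variance_range: tuple[float, float] = (0.5, 1.5),
) -> tuple[DAGStructure, GBNParameters]:
    """Random DAG + parameters: ground truth for recovery experiments.

    Edges run from lower to higher position in a random topological order
    and are kept with probability ``edge_prob``; weights are uniform on
    ``weight_range`` (optionally with a random sign, for magnitude
    ranges like (0.4, 0.8)); conditional variances uniform on
    ``variance_range``; means zero.
    """
    if n_nodes < 1:
        raise ParameterError("n_nodes must be >= 1")
    if not 0.0 <= edge_prob <= 1.0:
        raise ParameterError("edge_prob must lie in [0, 1]")
    lo, hi = weight_range
    if not lo < hi:
        raise ParameterError("weight_range must be a nonempty interval (lo, hi)")
    if variance_range[0] <= 0:
        raise ParameterError("variances must be positive")
    rng = np.random.default_rng(seed)
    if node_names is None:
        width = len(str(n_nodes))
        node_names = tuple(f"R{i + 1:0{width}d}" for i in range(n_nodes))
    else:
        node_names = tuple(node_names)
        if len(node_names) != n_nodes:
            raise ParameterError("node_names length must equal n_nodes")
    topo = list(rng.permutation(n_nodes))
    edges: list[tuple[str, str]] = []
    weights: dict[str, dict[str, float]] = {n: {} for n in node_names}
    for a in range(n_nodes):
        for b in range(a + 1, n_nodes):
            if rng.random() < edge_prob:
                p, c = node_names[topo[a]], node_names[topo[b]]
                w = float(rng.uniform(lo, hi))
                if random_sign and rng.random() < 0.5:
                    w = -w
                edges.append((p, c))
                weights[c][p] = w
    dag = DAGStructure.from_edges(node_names, edges)
    params = GBNParameters(
        mean={n: 0.0 for n in node_names},
        variance={n: float(rng.uniform(*variance_range)) for n in node_names},
        weights=weights,
    )
    return dag, params


def plant_group_difference(
    dag: DAGStructure,
    params: GBNParameters,
    edits: Sequence[tuple[str, str, float]],
) -> tuple[DAGStructure, GBNParameters]:
    """Return an edited copy of (dag, params); inputs are left untouched.

    Each edit ``(parent, child, new_weight)`` rewrites an existing edge
    weight, adds a new edge (must preserve acyclicity), or — with
    ``new_weight == 0`` — removes the edge.
    """
    params.validate_against(dag)
    parents = {c: set(dag.parents[c]) for c in dag.nodes}
    weights = {c: dict(params.weights.get(c, {})) for c in dag.nodes}
    for parent, child, w in edits:
        if parent not in dag.nodes or child not in dag.nodes:
            raise ParameterError(f"unknown node in edit ({parent!r}, {child!r})")
        if w == 0.0:
            parents[child].discard(parent)
            weights[child].pop(parent, None)
        else:
            parents[child].add(parent)
            weights[child][parent] = float(w)
    try:
        new_dag = DAGStructure(
            dag.nodes, {c: frozenset(p) for c, p in parents.items()}
        )
    except AcyclicityError as err:
        raise AcyclicityError(f"edits induce a directed cycle: {err}") from err
    new_params = GBNParameters(
        mean=dict(params.mean),
        variance=dict(params.variance),
        weights=weights,
        degenerate=params.degenerate,
    )
    return new_dag, new_params


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def _ar1_color(x: np.ndarray, phi: float) -> np.ndarray:
    """AR(1)-filter each column, then restore its original mean/variance."""
    if phi == 0.0:
        return x
    y = scipy.signal.lfilter([1.0], [1.0, -phi], x, axis=0)
    ym = y.mean(axis=0)
    ys = y.std(axis=0)
    xs = x.std(axis=0)
    xm = x.mean(axis=0)
    safe = np.where(ys > 0, ys, 1.0)
    return (y - ym) / safe * xs + xm


def _group_entropy(config: CohortConfig, which: str) -> list[int]:
    if which == "a":
        return [config.seed_a] if config.seed_a is not None else [config.seed, 0]
    return [config.seed_b] if config.seed_b is not None else [config.seed, 1]


def _metric_values(
    cohort: CohortTimeSeries,
    fc_z: pd.DataFrame,
    config: CohortConfig,
    metric: str,
) -> np.ndarray:
    """Per-subject values of a linked ground-truth metric."""
    truth = {
        config.group_a_label: (config.dag_a, config.params_a),
        config.group_b_label: (config.dag_b, config.params_b),
    }
    kind, _, arg = metric.partition(":")
    vals = []
    for s in cohort.subjects:
        dag, params = truth[s.group]
        if kind == "ci":
            if arg not in dag.nodes:
                raise ParameterError(f"unknown region in metric {metric!r}")
            vals.append(float(len(dag.parents[arg])))
        elif kind == "weight":
            p, _, c = arg.partition("->")
            if p not in dag.nodes or c not in dag.nodes:
                raise ParameterError(f"unknown edge in metric {metric!r}")
            vals.append(float(params.weights.get(c, {}).get(p, 0.0)))
        elif kind == "fc":
            if arg not in fc_z.columns:
                raise ParameterError(f"unknown region in metric {metric!r}")
            vals.append(float(fc_z.loc[s.subject_id, arg]))
        else:
            raise ParameterError(
                f"metric {metric!r} must start with 'ci:', 'weight:' or 'fc:'"
            )
    return np.array(vals)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw a full two-group cohort from the configured ground truth.

    Each subject's series is an ancestral sample from their group's
    network, optionally AR(1)-colored per region and re-standardized.  FC
    z-scores are baseline + scale·(true regional CI) + Gaussian noise;
    covariates mix the standardized linked metric with independent noise at
    the configured correlation strength.  Identical configs (including
    seed) give byte-identical output.
    """
    for label, params in (
        (config.group_a_label, config.params_a),
        (config.group_b_label, config.params_b),
    ):
        if any(v <= 0 for v in params.variance.values()):
            raise DataError(
                f"group {label!r} has degenerate (non-positive) conditional variances"
            )

    subjects: list[SubjectSeries] = []
    groups = (
        (config.group_a_label, config.n_group_a, config.dag_a, config.params_a, "a"),
        (config.group_b_label, config.n_group_b, config.dag_b, config.params_b, "b"),
    )
    fc_rows: dict[str, np.ndarray] = {}
    k = len(config.region_names)
    for label, n_subj, dag, params, which in groups:
        ent = _group_entropy(config, which)
        for j in range(n_subj):
            sid = f"{label}{j + 1:02d}"
            rng = np.random.default_rng(np.random.SeedSequence(ent + [j, 0]))
            x = sample_from_bn(dag, params, config.n_timepoints, rng)
            x = _ar1_color(x, config.ar1_coefficient)
            subjects.append(SubjectSeries(subject_id=sid, group=label, data=x))
            fc_rng = np.random.default_rng(np.random.SeedSequence(ent + [j, 1]))
            ci = np.array([len(dag.parents[r]) for r in config.region_names], float)
            fc_rows[sid] = (
                config.fc_baseline
                + config.fc_ci_scale * ci
                + config.fc_noise_sd * fc_rng.standard_normal(k)
            )

    ts = CohortTimeSeries(region_names=config.region_names, subjects=tuple(subjects))
    ids = [s.subject_id for s in ts.subjects]
    fc_z = pd.DataFrame(
        [fc_rows[sid] for sid in ids], index=ids, columns=list(config.region_names)
    )
    fc_z.index.name = "subject_id"

    cov_data: dict[str, np.ndarray] = {}
    for ci_idx, (name, link) in enumerate(sorted(config.covariate_spec.items())):
        m = _metric_values(ts, fc_z, config, link.metric)
        sd = m.std()
        z = (m - m.mean()) / sd if sd > 0 else np.zeros_like(m)
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2, ci_idx]))
        noise = rng.standard_normal(len(ids))
        rho = link.strength
        cov_data[name] = rho * z + link.noise_scale * np.sqrt(1 - rho**2) * noise
    covariates = pd.DataFrame(cov_data, index=ids)
    covariates.insert(0, "group", [s.group for s in ts.subjects])
    covariates.index.name = "subject_id"

    return SyntheticCohort(timeseries=ts, fc_z=fc_z, covariates=covariates, config=config)


# ---------------------------------------------------------------------------
# study-scale defaults
# ---------------------------------------------------------------------------

# Hand-built nine-region ground truth echoing the hub layout reported for
# the default mode network: PCC/MPFC/IPL as high-convergence hubs fed by
# the network, LTC/HC as a peripheral pair-wise subsystem.  The graph is
# kept moderately sparse so that the contrast-carrying edges participate
# in colliders and their orientations are identifiable from data.
_DEFAULT_EDGES_A: dict[tuple[str, str], float] = {
    ("rLTC", "lLTC"): 0.60,
    ("rHC", "lHC"): 0.60,
    ("rLTC", "dMPFC"): 0.45,
    ("lHC", "dMPFC"): 0.45,
    ("dMPFC", "vMPFC"): 0.45,
    ("rLTC", "vMPFC"): 0.35,
    ("vMPFC", "PCC"): 0.40,
    ("rHC", "PCC"): 0.40,
    ("dMPFC", "lIPL"): 0.55,
    ("rHC", "lIPL"): 0.30,
    ("PCC", "rIPL"): 0.40,
    ("lIPL", "rIPL"): 0.30,
    ("rLTC", "rIPL"): 0.40,
}

#: Planted group-B contrasts: a weakened fronto-parietal edge, a removed
#: parieto-parietal edge (so rIPL loses one parent), a weakened
#: temporo-frontal edge and a strengthened temporo-parietal edge.
DEFAULT_GROUP_EDITS: tuple[tuple[str, str, float], ...] = (
    ("dMPFC", "lIPL", 0.15),
    ("PCC", "rIPL", 0.0),
    ("rLTC", "vMPFC", 0.05),
    ("rLTC", "rIPL", 0.65),
)

DEFAULT_COVARIATES: dict[str, CovariateLink] = {
    "mmse": CovariateLink("ci:rIPL", 0.50),
    "moca": CovariateLink("ci:rIPL", 0.50),
    "visuospatial": CovariateLink("ci:vMPFC", 0.55),
    "attention": CovariateLink("fc:rLTC", -0.50),
    "delayed_recall": CovariateLink("ci:dMPFC", 0.55),
    "orientation": CovariateLink("ci:rIPL", 0.55),
}


def unit_variance_parameters(
    dag: DAGStructure, weights: Mapping[str, Mapping[str, float]]
) -> GBNParameters:
    """Conditional variances making every node's marginal variance 1.

    With unit marginal variances the generating weights live on the same
    standardized scale as the weights fitted after per-subject column
    standardization, so a planted weight difference is the difference the
    group statistic actually measures.
    """
    order = dag.topological_order()
    idx = {n: i for i, n in enumerate(order)}
    k = len(order)
    cov = np.zeros((k, k))
    variance: dict[str, float] = {}
    for node in order:
        i = idx[node]
        pa = sorted(dag.parents[node])
        b = np.array([weights[node][p] for p in pa])
        pi = [idx[p] for p in pa]
        if pa:
            pred_var = float(b @ cov[np.ix_(pi, pi)] @ b)
        else:
            pred_var = 0.0
        v = 1.0 - pred_var
        if v <= 0.0:
            raise ParameterError(
                f"weights into {node!r} imply predicted variance {pred_var:.3f} "
                ">= 1; cannot standardize marginals"
            )
        variance[node] = v
        cov[i, i] = 1.0
        for j in range(k):
            if j != i:
                cov[i, j] = cov[j, i] = float(b @ cov[pi, j]) if pa else 0.0
    return GBNParameters(
        mean={n: 0.0 for n in dag.nodes},
        variance=variance,
        weights={n: dict(weights.get(n, {})) for n in dag.nodes},
    )


def default_truth() -> tuple[DAGStructure, GBNParameters]:
    """The default nine-region group-A (control) network.

    Marginal variances are normalized to 1 (see
    :func:`unit_variance_parameters`), so the edge weights are directly the
    standardized-scale connectivity coefficients downstream fits estimate.
    """
    weights: dict[str, dict[str, float]] = {r: {} for r in DMN_REGIONS}
    for (p, c), w in _DEFAULT_EDGES_A.items():
        weights[c][p] = w
    dag = DAGStructure.from_edges(DMN_REGIONS, list(_DEFAULT_EDGES_A))
    return dag, unit_variance_parameters(dag, weights)


def default_cohort_config(
    seed: int = 0,
    edits: Sequence[tuple[str, str, float]] = DEFAULT_GROUP_EDITS,
    ar1_coefficient: float = 0.0,
    n_per_group: int = 17,
    n_timepoints: int = 190,
) -> CohortConfig:
    """Study-scale default: 17+17 subjects, 190 timepoints, 9 DMN regions."""
    dag_a, params_a = default_truth()
    dag_b, params_b = plant_group_difference(dag_a, params_a, list(edits))
    return CohortConfig(
        n_group_a=n_per_group,
        n_group_b=n_per_group,
        n_timepoints=n_timepoints,
        region_names=DMN_REGIONS,
        dag_a=dag_a,
        params_a=params_a,
        dag_b=dag_b,
        params_b=params_b,
        ar1_coefficient=ar1_coefficient,
        covariate_spec=dict(DEFAULT_COVARIATES),
        seed=seed,
    )
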