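"""Shared fixtures: small ground-truth networks and cohort builders."""

from __future__ import annotations

import numpy as np
import pytest

from bnec.gbn import DAGStructure, GBNParameters, sample_from_bn
from bnec.synthetic import CohortTimeSeries, SubjectSeries


@pytest.fixture
def chain_bn():
    """X -> Y -> Z with unit noise."""
    dag = DAGStructure.from_edges(("X", "Y", "Z"), [("X", "Y"), ("Y", "Z")])
    params = GBNParameters(
        mean={"X": 0.0, "Y": 1.0, "Z": -0.5},
        variance={"X": 1.0, "Y": 0.5, "Z": 2.0},
        weights={"X": {}, "Y": {"X": 0.8}, "Z": {"Y": -0.6}},
    )
    return dag, params


@pytest.fixture
def five_node_null_bn():
    """Diamond-plus-tail: all edge orientations compelled by colliders."""
    nodes = ("R1", "R2", "R3", "R4", "R5")
    edges = {
        ("R1", "R2"): 0.6,
        ("R1", "R3"): 0.6,
        ("R2", "R4"): 0.6,
        ("R3", "R4"): -0.5,
        ("R4", "R5"): 0.6,
    }
    w: dict[str, dict[str, float]] = {n: {} for n in nodes}
    for (p, c), v in edges.items():
        w[c][p] = v
    dag = DAGStructure.from_edges(nodes, list(edges))
    params = GBNParameters(
        mean={n: 0.0 for n in nodes},
        variance={n: 1.0 for n in nodes},
        weights=w,
    )
    return dag, params


def build_cohort(groups, n_timepoints, seed):
    """Cohort from {label: (dag, params, n_subjects)} with nested seeding."""
    subjects = []
    region_names = None
    for gi, (label, (dag, params, n_subj)) in enumerate(sorted(groups.items())):
        region_names = dag.nodes
        for s in range(n_subj):
            x = sample_from_bn(
                dag, params, n_timepoints, np.random.SeedSequence([seed, gi, s])
            )
            subjects.append(SubjectSeries(f"{label}{s:02d}", label, x))
    return CohortTimeSeries(region_names=region_names, subjects=tuple(subjects))


@pytest.fixture
def rng():
    return np.random.default_rng(20231206)
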