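"""Regional convergence index (CI) and the high/low dichotomy.

The convergence index of a region is its number of parents in the learned
DAG — the number of ingoing directed connections.  Regions whose CI lies
strictly above the average over all regions are classified ``high``
(network hubs whose activity depends strongly on the rest of the network),
the remainder ``low``; a tie exactly at the mean is assigned ``low``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .gbn import DAGStructure


@dataclass(frozen=True)
class ConvergenceIndexTable:
    """Per-region in-degree counts, optionally with a high/low label.

    ``scope`` records what the table describes: a group label, a subject
    identifier, or any free-form tag.
    """

    regions: tuple[str, ...]
    ci: tuple[int, ...]
    classification: tuple[str, ...] | None = None
    scope: str = "group"

    def __post_init__(self) -> None:
        if len(self.regions) != len(self.ci):
            raise ParameterError("regions and ci must have equal length")
        if self.classification is not None and len(self.classification) != len(self.ci):
            raise ParameterError("classification length mismatch")
        if any(c < 0 for c in self.ci):
            raise ParameterError("convergence indices are nonnegative counts")

    @property
    def total(self) -> int:
        return int(sum(self.ci))

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.regions, self.ci))

    def to_frame(self) -> pd.DataFrame:
        data = {"region": self.regions, "ci": self.ci}
        if self.classification is not None:
            data["classification"] = self.classification
        df = pd.DataFrame(data)
        df["scope"] = self.scope
        return df


def convergence_index(dag: DAGStructure, scope: str = "group") -> ConvergenceIndexTable:
    """CI per region: the size of its parent set. Totals the edge count."""
    ci = tuple(len(dag.parents[r]) for r in dag.nodes)
    return ConvergenceIndexTable(regions=dag.nodes, ci=ci, scope=scope)


def classify_regions(table: ConvergenceIndexTable) -> ConvergenceIndexTable:
    """Label regions ``high`` iff CI is strictly above the mean CI.

    Ties at the mean go to ``low`` — with every region equal, none is a hub.
    """
    if len(table.ci) < 1:
        raise ParameterError("need at least one region")
    mean = float(np.mean(table.ci))
    labels = tuple("high" if c > mean else "low" for c in table.ci)
    return replace(table, classification=labels)
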