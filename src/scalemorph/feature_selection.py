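"""Correlation-based pruning of collinear length variables.

Strongly correlated variables carry redundant shape information; within each
group of mutually correlated variables one representative is kept, chosen by
an ordered preference list that encodes which variable is easiest to measure
(the crown height L6 stands in for the keel L2 and posterior base margin L8;
the scale length L5 stands in for the concealed field L7).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data_io import MeasurementTable
from .errors import DegenerateVariableError, InsufficientDataError

#: preference order: for each correlated cluster the earliest name wins
DEFAULT_PRIORITY = ("L6", "L5", "L1", "L3", "L4", "L2", "L7", "L8")

DEFAULT_THRESHOLD = 0.90


@dataclass
class CorrelationReport:
    variables: tuple[str, ...]
    matrix: np.ndarray  # symmetric Pearson correlations, diag 1
    clusters: list[tuple[str, ...]]  # connected components at the threshold
    kept: tuple[str, ...]
    dropped: dict[str, str]  # dropped variable -> representative that replaced it
    threshold: float = DEFAULT_THRESHOLD

    def as_dict(self) -> dict:
        return {
            "variables": list(self.variables),
            "matrix": self.matrix.tolist(),
            "clusters": [list(c) for c in self.clusters],
            "kept": list(self.kept),
            "dropped": dict(self.dropped),
            "threshold": self.threshold,
        }


def select_variables(
    table: MeasurementTable,
    threshold: float = DEFAULT_THRESHOLD,
    priority: Sequence[str] = DEFAULT_PRIORITY,
) -> CorrelationReport:
    """Prune mutually correlated variables down to preferred representatives.

    Pearson correlations are computed pairwise on complete cases of the raw
    millimetre values (the variables share a dimension, so no
    standardization). Two variables are linked when ``|r| >= threshold``;
    connected components of that graph form clusters, and within each
    cluster the variable earliest in ``priority`` is kept.
    """
    variables = tuple(table.variable_names)
    if len(table) < 3:
        raise InsufficientDataError(
            f"need at least 3 records to estimate correlations, got {len(table)}"
        )
    X = table.matrix(variables)
    sd = X.std(axis=0)
    for name, s in zip(variables, sd):
        if s == 0.0:
            raise DegenerateVariableError(f"variable {name} has zero variance")
    R = np.corrcoef(X, rowvar=False)
    if R.ndim == 0:  # single variable
        R = np.ones((1, 1))

    # union-find over variables linked at the threshold
    parent = list(range(len(variables)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    # tiny slack so an exact linear dependence (r = 1 up to round-off) still
    # links at threshold 1.0
    for i in range(len(variables)):
        for j in range(i + 1, len(variables)):
            if abs(R[i, j]) >= threshold - 1e-12:
                parent[find(i)] = find(j)

    rank = {name: priority.index(name) if name in priority else len(priority) + k
            for k, name in enumerate(variables)}
    components: dict[int, list[str]] = {}
    for i, name in enumerate(variables):
        components.setdefault(find(i), []).append(name)
    clusters = [tuple(sorted(members, key=lambda v: rank[v]))
                for _, members in sorted(components.items())]

    kept: list[str] = []
    dropped: dict[str, str] = {}
    for cluster in clusters:
        representative = cluster[0]
        kept.append(representative)
        for other in cluster[1:]:
            dropped[other] = representative
    kept_ordered = tuple(v for v in variables if v in kept)
    return CorrelationReport(
        variables=variables,
        matrix=R,
        clusters=clusters,
        kept=kept_ordered,
        dropped=dropped,
        threshold=threshold,
    )
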