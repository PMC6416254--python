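"""Agglomerative hierarchical clustering of scales (Q-type cluster analysis).

Specimens are clustered on their raw length variables with the squared
Euclidean distance and between-groups (unweighted average) linkage: the
distance between two clusters is the mean of the squared Euclidean point
distances over all cross pairs. Implemented from scratch with Lance-Williams
incremental updates; a brute-force cross-pair recomputation guards
correctness in the test suite. No standardization is applied — the length
variables share the millimetre dimension.

Average linkage is reducible, so merge heights are monotone non-decreasing;
this is asserted on every run. Ties between candidate merges are broken by
the lexicographically smallest pair of minimal member identifiers, making
the dendrogram deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .data_io import MeasurementTable
from .errors import DataError, IntegrityError
from .metrics import mean_silhouette

_MONOTONE_RTOL = 1e-9


@dataclass
class Dendrogram:
    """Merge tree of an agglomerative run.

    Clusters are numbered like a linkage matrix: leaves are ``0..n-1`` and
    the cluster created by merge ``i`` is ``n + i``. ``merges`` holds
    ``(cluster_a, cluster_b, linkage_height, new_size)`` with
    ``cluster_a < cluster_b``.
    """

    n_leaves: int
    merges: list[tuple[int, int, float, int]]
    leaf_ids: tuple[str, ...]
    method_params: dict = field(default_factory=lambda: {
        "distance": "squared_euclidean", "linkage": "between_groups_average"})

    def __post_init__(self) -> None:
        if len(self.merges) != self.n_leaves - 1:
            raise IntegrityError(
                f"{self.n_leaves} leaves require {self.n_leaves - 1} merges, "
                f"got {len(self.merges)}"
            )
        heights = [m[2] for m in self.merges]
        for h_prev, h_next in zip(heights, heights[1:]):
            if h_next < h_prev * (1 - _MONOTONE_RTOL) - 1e-12:
                raise IntegrityError(
                    f"non-monotone merge heights: {h_prev} then {h_next}"
                )

    def heights(self) -> np.ndarray:
        return np.array([m[2] for m in self.merges])

    def as_dict(self) -> dict:
        return {
            "n_leaves": self.n_leaves,
            "leaf_ids": list(self.leaf_ids),
            "merges": [list(m) for m in self.merges],
            "method_params": dict(self.method_params),
        }


@dataclass
class Partition:
    """A k-group labelling of the scales.

    Labels are integers ``0..k-1`` assigned by descending group size, ties
    by the smallest member identifier, so partitions are canonical.
    """

    labels: np.ndarray
    k: int
    scale_ids: tuple[str, ...]
    method_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if len(np.unique(self.labels)) != self.k:
            raise IntegrityError(
                f"partition declares k={self.k} but has "
                f"{len(np.unique(self.labels))} distinct labels"
            )
        if self.labels.shape[0] != len(self.scale_ids):
            raise IntegrityError("one label required per scale")

    def group_sizes(self) -> list[int]:
        return np.bincount(self.labels, minlength=self.k).tolist()

    def members(self, label: int) -> list[str]:
        return [sid for sid, g in zip(self.scale_ids, self.labels) if g == label]

    def as_dict(self) -> dict:
        return {
            "k": self.k,
            "labels": self.labels.tolist(),
            "scale_ids": list(self.scale_ids),
            "group_sizes": self.group_sizes(),
            "method_params": dict(self.method_params),
        }


def canonical_labels(raw_labels: Sequence[int], scale_ids: Sequence[str]) -> np.ndarray:
    """Renumber arbitrary group ids by descending size, then smallest member id."""
    raw = np.asarray(raw_labels)
    groups: dict[int, list[str]] = {}
    for g, sid in zip(raw, scale_ids):
        groups.setdefault(int(g), []).append(sid)
    order = sorted(groups, key=lambda g: (-len(groups[g]), min(groups[g])))
    remap = {g: new for new, g in enumerate(order)}
    return np.array([remap[int(g)] for g in raw])


def agglomerate(
    table: MeasurementTable, variables: Sequence[str] | None = None
) -> Dendrogram:
    """Cluster the table's scales; returns the full merge tree.

    ``variables`` defaults to the table's full variable set; in the pipeline
    it is the pruned set from variable selection.
    """
    variables = tuple(variables if variables is not None else table.variable_names)
    if len(table) < 2:
        raise DataError("need at least 2 records to cluster")
    X = table.matrix(variables)
    bad = np.argwhere(~np.isfinite(X))
    if bad.size:
        r, c = bad[0]
        raise DataError(
            f"non-finite value for scale {table.scale_ids[r]!r}, "
            f"variable {variables[c]}"
        )
    n = X.shape[0]
    ids = table.scale_ids

    D = squareform(pdist(X, metric="sqeuclidean"))
    np.fill_diagonal(D, np.inf)
    size = np.ones(n, dtype=int)
    active = np.ones(n, dtype=bool)
    # cluster index of each active row and its smallest member id (tie-break key)
    cluster_no = np.arange(n)
    min_id = list(ids)

    merges: list[tuple[int, int, float, int]] = []
    next_cluster = n
    D = D.copy()
    for _ in range(n - 1):
        masked = np.where(active[:, None] & active[None, :], D, np.inf)
        h = masked.min()
        ti, tj = np.nonzero(masked == h)
        # candidate pairs (i<j); tie-break on sorted (min member id) pair
        best = None
        for i, j in zip(ti, tj):
            if i >= j:
                continue
            key = tuple(sorted((min_id[i], min_id[j])))
            if best is None or key < best[0]:
                best = (key, int(i), int(j))
        _, i, j = best
        new_size = size[i] + size[j]
        a, b = sorted((cluster_no[i], cluster_no[j]))
        merges.append((int(a), int(b), float(h), int(new_size)))
        # Lance-Williams update for unweighted average linkage, stored in row i
        others = active.copy()
        others[[i, j]] = False
        D[i, others] = (size[i] * D[i, others] + size[j] * D[j, others]) / new_size
        D[others, i] = D[i, others]
        active[j] = False
        size[i] = new_size
        cluster_no[i] = next_cluster
        min_id[i] = min(min_id[i], min_id[j])
        next_cluster += 1

    return Dendrogram(n_leaves=n, merges=merges, leaf_ids=tuple(ids))


def cut_k(dendrogram: Dendrogram, k: int) -> Partition:
    """Cut the merge tree into ``k`` groups by undoing the last ``k-1`` merges."""
    n = dendrogram.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    parent = list(range(n + len(dendrogram.merges)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for idx, (a, b, _, _) in enumerate(dendrogram.merges[: n - k]):
        new = n + idx
        parent[find(a)] = new
        parent[find(b)] = new
    raw = [find(i) for i in range(n)]
    labels = canonical_labels(raw, dendrogram.leaf_ids)
    return Partition(
        labels=labels,
        k=k,
        scale_ids=dendrogram.leaf_ids,
        method_params=dict(dendrogram.method_params, k=k),
    )


def compare_k(
    table: MeasurementTable,
    variables: Sequence[str] | None = None,
    ks: Sequence[int] = (7, 8, 9),
) -> dict[int, dict]:
    """Diagnostics for candidate group counts; never chooses k automatically.

    For each k: group sizes, within-group dispersion (summed squared
    Euclidean distance to group centroids), mean silhouette, and 2-D
    principal-component scatter coordinates for visual comparison against
    the fossils. Choosing k is the analyst's decision.
    """
    ks = list(ks)
    if not ks:
        raise ValueError("ks must be non-empty")
    variables = tuple(variables if variables is not None else table.variable_names)
    X = table.matrix(variables)
    dendro = agglomerate(table, variables)
    # PCA scatter for plotting (centered, unscaled)
    Xc = X - X.mean(axis=0)
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    scatter = Xc @ Vt[: min(2, Xc.shape[1])].T

    out: dict[int, dict] = {}
    for k in ks:
        part = cut_k(dendro, k)
        within = 0.0
        for g in range(k):
            pts = X[part.labels == g]
            within += float(((pts - pts.mean(axis=0)) ** 2).sum())
        out[k] = {
            "partition": part,
            "group_sizes": part.group_sizes(),
            "within_dispersion": within,
            "mean_silhouette": mean_silhouette(X, part.labels) if k > 1 else float("nan"),
            "scatter_2d": scatter,
        }
    return out
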