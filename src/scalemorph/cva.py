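"""Canonical variate analysis and the reassign-and-refit refinement loop.

CVA validates a clustering: canonical axes maximize between-group relative
to within-group scatter (the generalized eigenproblem of W^-1 B), each
scale is assigned to the group whose mean is nearest in Mahalanobis
distance under the pooled within-group covariance (equal priors, linear
discrimination), and the resubstitution accuracy against the cluster
labels measures how self-consistent the grouping is. Scales the model
disagrees with can then be moved to their predicted group and the model
refit; one such adjustment round is the default.

Single-member groups are allowed: they contribute a mean but no
within-group scatter. A singular pooled scatter raises, with an optional
ridge (W + lambda*diag(W)) as the documented escape hatch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg

from .clustering import Partition, canonical_labels
from .data_io import MeasurementTable
from .errors import SchemaError, SingularityError

_EIG_TOL = 1e-9


@dataclass
class CVAModel:
    group_means: np.ndarray         # (g, p), mm
    pooled_within_cov: np.ndarray   # (p, p), W / (n - g)
    canonical_coefficients: np.ndarray  # (p, r); unit within-group variance per axis
    eigenvalues: np.ndarray         # (r,), descending, positive
    groups: tuple[int, ...]
    variables: tuple[str, ...]
    group_sizes: tuple[int, ...] = ()
    ridge: float = 0.0

    def __post_init__(self) -> None:
        g, p = self.group_means.shape
        assert len(self.eigenvalues) <= min(g - 1, p), (
            "positive eigenvalue count exceeds min(g-1, p)"
        )
        d = np.diag(self.pooled_within_cov)
        assert np.allclose(self.pooled_within_cov, self.pooled_within_cov.T)
        assert np.all(d > 0), "pooled within-covariance needs positive diagonal"

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Canonical scores (coordinates on the discriminant axes)."""
        center = self.group_means.mean(axis=0)
        return (np.asarray(X, dtype=float) - center) @ self.canonical_coefficients

    def as_dict(self) -> dict:
        return {
            "groups": list(self.groups),
            "variables": list(self.variables),
            "group_sizes": list(self.group_sizes),
            "group_means": self.group_means.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "canonical_coefficients": self.canonical_coefficients.tolist(),
            "ridge": self.ridge,
        }


@dataclass
class ClassificationResult:
    predicted: np.ndarray       # per-scale group label
    confusion: np.ndarray       # (g, g) counts, rows = true labels
    accuracy: float
    scores: np.ndarray          # (n, r) canonical coordinates

    def __post_init__(self) -> None:
        if self.confusion.size:
            assert self.confusion.sum() == len(self.predicted)
            n = self.confusion.sum()
            assert abs(self.accuracy - np.trace(self.confusion) / n) < 1e-12

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "confusion": self.confusion.tolist(),
            "predicted": self.predicted.tolist(),
        }


def _scatter_matrices(X: np.ndarray, labels: np.ndarray, groups: Sequence[int]):
    p = X.shape[1]
    grand = X.mean(axis=0)
    B = np.zeros((p, p))
    W = np.zeros((p, p))
    means = []
    sizes = []
    for g in groups:
        pts = X[labels == g]
        if pts.shape[0] == 0:
            raise ValueError(f"group {g} has no members")
        mu = pts.mean(axis=0)
        means.append(mu)
        sizes.append(pts.shape[0])
        dm = (mu - grand)[:, None]
        B += pts.shape[0] * (dm @ dm.T)
        centered = pts - mu
        W += centered.T @ centered
    return np.array(means), np.array(sizes), B, W


def fit_cva(
    table: MeasurementTable,
    labels: Partition | np.ndarray,
    variables: Sequence[str] | None = None,
    ridge: float = 0.0,
) -> CVAModel:
    """Fit canonical axes and the pooled within-group covariance.

    Axes solve the generalized eigenproblem B a = lambda W a, are ordered by
    descending eigenvalue, and are scaled so the pooled within-group variance
    along each axis is 1. ``ridge`` adds ``ridge*diag(W)`` to W for
    near-singular cases (default 0: no regularization).
    """
    lab = labels.labels if isinstance(labels, Partition) else np.asarray(labels)
    variables = tuple(
        variables
        if variables is not None
        else (labels.method_params.get("variables") if isinstance(labels, Partition) else None)
        or table.variable_names
    )
    X = table.matrix(variables)
    groups = tuple(int(g) for g in np.unique(lab))
    means, sizes, B, W = _scatter_matrices(X, lab, groups)
    if ridge > 0:
        W = W + ridge * np.diag(np.diag(W))
    n, p = X.shape
    g = len(groups)
    dof = max(n - g, 1)
    try:
        # symmetric-definite generalized eigenproblem; eigh needs W > 0
        evals, evecs = scipy.linalg.eigh(B, W)
    except scipy.linalg.LinAlgError as exc:
        raise SingularityError(
            "pooled within-group scatter is singular; pass ridge > 0 "
            "(W + ridge*diag(W)) to regularize"
        ) from exc
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    r = min(g - 1, p)
    keep = np.flatnonzero(evals[:r] > _EIG_TOL * max(evals.max(), 1.0))
    evals = np.clip(evals[keep], 0.0, None)
    # eigh normalizes a^T W a = 1; rescale so a^T (W/dof) a = 1
    coeffs = evecs[:, keep] * np.sqrt(dof)
    return CVAModel(
        group_means=means,
        pooled_within_cov=W / dof,
        canonical_coefficients=coeffs,
        eigenvalues=evals,
        groups=groups,
        variables=variables,
        group_sizes=tuple(int(s) for s in sizes),
        ridge=ridge,
    )


def mahalanobis_distances(model: CVAModel, X: np.ndarray) -> np.ndarray:
    """(n, g) squared Mahalanobis distances to each group mean."""
    Sinv = np.linalg.pinv(model.pooled_within_cov)
    diffs = X[:, None, :] - model.group_means[None, :, :]  # (n, g, p)
    return np.einsum("ngp,pq,ngq->ng", diffs, Sinv, diffs)


def classify(
    model: CVAModel,
    table: MeasurementTable,
    true_labels: np.ndarray | Partition | None = None,
) -> ClassificationResult:
    """Assign each scale to the Mahalanobis-nearest group mean (equal priors).

    Ties at exactly equal distance go to the lowest group id. When
    ``true_labels`` is given, the confusion matrix and resubstitution
    accuracy are computed against it.
    """
    missing = set(model.variables) - set(table.variable_names)
    if missing:
        raise SchemaError(f"model variables missing from table: {sorted(missing)}")
    X = table.matrix(model.variables)
    d2 = mahalanobis_distances(model, X)
    predicted = np.array([model.groups[j] for j in d2.argmin(axis=1)])

    g = len(model.groups)
    index = {grp: i for i, grp in enumerate(model.groups)}
    if true_labels is not None:
        truth = true_labels.labels if isinstance(true_labels, Partition) else np.asarray(true_labels)
        confusion = np.zeros((g, g), dtype=int)
        for t, pr in zip(truth, predicted):
            confusion[index[int(t)], index[int(pr)]] += 1
        accuracy = float(np.trace(confusion) / len(predicted))
    else:
        confusion = np.zeros((0, 0), dtype=int)
        accuracy = float("nan")
    return ClassificationResult(
        predicted=predicted,
        confusion=confusion,
        accuracy=accuracy,
        scores=model.transform(X),
    )


def refine_labels(
    table: MeasurementTable,
    labels: Partition,
    variables: Sequence[str] | None = None,
    max_rounds: int = 1,
    ridge: float = 0.0,
) -> tuple[Partition, list[ClassificationResult]]:
    """Adjust scales to the group the discriminant model predicts, then refit.

    Each round fits a CVA on the current labels, classifies all scales, and
    moves every misclassified scale to its predicted group. Stops after
    ``max_rounds`` or at a fixpoint (no scale moves). The history holds one
    classification per fitted model, so ``history[0].accuracy`` is the
    self-consistency of the input labels and the last entry that of the
    refined labels. A reassignment that empties a group retires the group
    (k decrements) with a logged warning.
    """
    import logging

    if max_rounds < 1:
        raise ValueError("max_rounds must be >= 1")
    variables = tuple(variables if variables is not None else table.variable_names)
    current = labels.labels.copy()
    history: list[ClassificationResult] = []
    for _ in range(max_rounds):
        model = fit_cva(table, current, variables, ridge=ridge)
        result = classify(model, table, true_labels=current)
        history.append(result)
        if np.array_equal(result.predicted, current):
            break
        lost = set(np.unique(current)) - set(np.unique(result.predicted))
        if lost:
            logging.getLogger("scalemorph").warning(
                "refinement emptied group(s) %s; k reduced", sorted(lost)
            )
        current = result.predicted.copy()
    else:
        # score the final labelling so the history ends with its accuracy
        model = fit_cva(table, current, variables, ridge=ridge)
        history.append(classify(model, table, true_labels=current))

    final = canonical_labels(current, labels.scale_ids)
    refined = Partition(
        labels=final,
        k=len(np.unique(final)),
        scale_ids=labels.scale_ids,
        method_params=dict(labels.method_params, refined=True, variables=variables),
    )
    return refined, history
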