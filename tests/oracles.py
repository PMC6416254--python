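"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own code paths: the clustering
oracle recomputes every cross-pair mean from the raw points at every step,
and the CVA oracle explicitly inverts W and eigendecomposes W^-1 B with a
generic (non-symmetric) eigensolver.
"""

from __future__ import annotations

import numpy as np


def brute_force_average_linkage(X, ids):
    """O(n^3) between-groups (average) linkage on squared Euclidean distances.

    Returns the merge sequence as (members_a, members_b, height) with the
    member sets given as frozensets of ids, ties broken by the sorted pair
    of minimal member ids.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    D = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=-1)
    clusters = [frozenset([i]) for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                cross = [D[i, j] for i in clusters[a] for j in clusters[b]]
                h = sum(cross) / len(cross)
                key = tuple(sorted((
                    min(ids[i] for i in clusters[a]),
                    min(ids[i] for i in clusters[b]),
                )))
                if best is None or (h, key) < (best[0], best[1]):
                    best = (h, key, a, b)
        h, _, a, b = best
        merges.append((
            frozenset(ids[i] for i in clusters[a]),
            frozenset(ids[i] for i in clusters[b]),
            h,
        ))
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return merges


def dendrogram_member_merges(dendro):
    """Convert a Dendrogram's numbered merges to (members_a, members_b, height)."""
    n = dendro.n_leaves
    members = {i: frozenset([dendro.leaf_ids[i]]) for i in range(n)}
    out = []
    for idx, (a, b, h, _) in enumerate(dendro.merges):
        out.append((members[a], members[b], h))
        members[n + idx] = members[a] | members[b]
    return out


def cva_eigenvalues_oracle(X, labels):
    """Eigenvalues of W^-1 B via explicit inversion and np.linalg.eig."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    grand = X.mean(axis=0)
    p = X.shape[1]
    B = np.zeros((p, p))
    W = np.zeros((p, p))
    groups = np.unique(labels)
    for g in groups:
        pts = X[labels == g]
        mu = pts.mean(axis=0)
        B += len(pts) * np.outer(mu - grand, mu - grand)
        W += (pts - mu).T @ (pts - mu)
    evals = np.linalg.eig(np.linalg.inv(W) @ B)[0]
    evals = np.sort(np.real(evals))[::-1]
    r = min(len(groups) - 1, p)
    return evals[:r][evals[:r] > 1e-9 * max(evals.max(), 1.0)]


def mahalanobis_assign_oracle(X, means, pooled_cov, group_ids):
    """Nearest group mean in Mahalanobis distance, computed point by point."""
    Sinv = np.linalg.inv(pooled_cov)
    out = []
    for x in np.asarray(X, dtype=float):
        d2 = []
        for mu in means:
            diff = x - mu
            d2.append(float(diff @ Sinv @ diff))
        out.append(group_ids[int(np.argmin(d2))])
    return np.array(out)


def geometry_lengths_oracle(points):
    """Hand-written coordinate-geometry recomputation of the length variables."""
    pts = np.asarray(points, dtype=float)

    def d(i, j):  # 1-based
        return float(np.hypot(*(pts[i - 1] - pts[j - 1])))

    p1, p4, p5, p6, p7 = pts[0], pts[3], pts[4], pts[5], pts[6]
    # L1: distance from p1 to the line p4-p5, positive away from the crown
    e = p5 - p4
    nvec = np.array([-e[1], e[0]]) / np.hypot(*e)
    if np.dot(0.5 * (p6 + p7) - p4, nvec) > 0:
        nvec = -nvec
    L1 = max(0.0, float(np.dot(p1 - p4, nvec)))
    u = (p5 - p6) / np.hypot(*(p5 - p6))
    proj = [float(np.dot(pts[i], u)) for i in range(1, 7)]  # landmarks 2..7
    return {
        "L1": L1,
        "L2": d(1, 11),
        "L3": d(2, 4),
        "L4": max(proj) - min(proj),
        "L5": d(5, 6),
        "L6": d(5, 7),
        "L8": d(9, 10),
    }
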