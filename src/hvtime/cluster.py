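"""Hierarchical clustering of HV genes under uncentered correlation.

The similarity between two expression profiles is the uncentered
correlation s = Σ x_i y_i / sqrt(Σ x_i² · Σ y_i²) — a cosine similarity
computed without subtracting profile means — and the clustering distance is
d = 1 - s, in [0, 2]. Genes are mean-centered before clustering (the
metric itself stays uncentered), then agglomerated bottom-up. Linkage is
average by default (complete and single are available); ties in the
minimum pairwise distance are broken deterministically by the smallest
(row-index, row-index) pair in lexicographic order, so the merge sequence
is reproducible.

The agglomerator is implemented in-package (Lance-Williams updates,
O(n³) worst case — HV gene lists are a few hundred rows); its merge
sequence is cross-checked against scipy.cluster.hierarchy in the test
suite.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import ClusterTree
from .errors import InsufficientData, ZeroVector

__all__ = [
    "mean_center",
    "uncentered_correlation",
    "pairwise_uncentered_distance",
    "hierarchical_cluster",
    "HierarchicalClustering",
]


def mean_center(gene_row: Sequence[float]) -> np.ndarray:
    """Subtract the row mean; the output sums to zero."""
    x = np.asarray(gene_row, dtype=float)
    if x.size == 0:
        raise InsufficientData("empty row")
    return x - x.mean()


def uncentered_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Uncentered (cosine-like) correlation in [-1, 1]."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape:
        raise ValueError("vectors must have equal length")
    nx = np.sqrt((xv**2).sum())
    ny = np.sqrt((yv**2).sum())
    if nx == 0 or ny == 0:
        raise ZeroVector("uncentered correlation undefined for an all-zero vector")
    return float(np.clip((xv * yv).sum() / (nx * ny), -1.0, 1.0))


def pairwise_uncentered_distance(matrix: np.ndarray) -> np.ndarray:
    """Full matrix of d = 1 - s over rows; rows must be non-zero."""
    X = np.asarray(matrix, dtype=float)
    norms = np.sqrt((X**2).sum(axis=1))
    if np.any(norms == 0):
        bad = int(np.flatnonzero(norms == 0)[0])
        raise ZeroVector(f"row {bad} is all-zero")
    S = (X @ X.T) / np.outer(norms, norms)
    D = 1.0 - np.clip(S, -1.0, 1.0)
    np.fill_diagonal(D, 0.0)
    return D


_LINKAGES = ("average", "complete", "single")


def hierarchical_cluster(
    centered_matrix,
    linkage: str = "average",
    leaf_ids: Sequence[str] | None = None,
) -> ClusterTree:
    """Agglomerate rows under uncentered-correlation distance.

    Deterministic: among equally close pairs, the one with the smallest
    (node creation order) index pair merges first. Merge heights are
    non-decreasing for average (and complete) linkage.
    """
    if linkage not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}")
    if isinstance(centered_matrix, pd.DataFrame):
        if leaf_ids is None:
            leaf_ids = [str(i) for i in centered_matrix.index]
        X = centered_matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(centered_matrix, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise InsufficientData("clustering needs at least 2 rows")
    if leaf_ids is None:
        leaf_ids = [str(i) for i in range(n)]

    D0 = pairwise_uncentered_distance(X)
    total = 2 * n - 1
    big = np.inf
    D = np.full((total, total), big)
    D[:n, :n] = D0
    np.fill_diagonal(D, big)
    sizes = np.zeros(total, dtype=int)
    sizes[:n] = 1
    active = np.zeros(total, dtype=bool)
    active[:n] = True
    merges: list[tuple[int, int, float, int]] = []
    for step in range(n - 1):
        idx = np.flatnonzero(active)
        sub = D[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        flat = sub[iu]
        k = int(np.argmin(flat))  # first minimum = smallest (i, j) pair
        i, j = int(idx[iu[0][k]]), int(idx[iu[1][k]])
        d = float(flat[k])
        new = n + step
        # Lance-Williams update against every other active node
        others = idx[(idx != i) & (idx != j)]
        if linkage == "average":
            upd = (sizes[i] * D[i, others] + sizes[j] * D[j, others]) / (
                sizes[i] + sizes[j]
            )
        elif linkage == "complete":
            upd = np.maximum(D[i, others], D[j, others])
        else:
            upd = np.minimum(D[i, others], D[j, others])
        D[new, others] = upd
        D[others, new] = upd
        sizes[new] = sizes[i] + sizes[j]
        active[i] = active[j] = False
        active[new] = True
        merges.append((i, j, d, new))
    return ClusterTree(merges=merges, leaf_ids=[str(x) for x in leaf_ids])


class HierarchicalClustering(BaseEstimator):
    """Estimator wrapper: mean-center rows, cluster, expose the tree.

    Parameters
    ----------
    linkage : {"average", "complete", "single"}
    center : bool
        Mean-center each row before computing similarities (the study's
        procedure applies centering even though the metric is uncentered).

    Fitted attributes
    -----------------
    tree_ : ClusterTree
    leaf_order_ : list[str]   display (heat-map) row order
    """

    def __init__(self, linkage: str = "average", center: bool = True):
        self.linkage = linkage
        self.center = center

    def fit(self, X, y=None) -> "HierarchicalClustering":
        if isinstance(X, pd.DataFrame):
            ids = [str(i) for i in X.index]
            mat = X.to_numpy(dtype=float)
        else:
            mat = np.asarray(X, dtype=float)
            ids = [str(i) for i in range(mat.shape[0])]
        if self.center:
            mat = mat - mat.mean(axis=1, keepdims=True)
        self.tree_ = hierarchical_cluster(mat, linkage=self.linkage, leaf_ids=ids)
        self.leaf_order_ = self.tree_.leaf_order()
        return self
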