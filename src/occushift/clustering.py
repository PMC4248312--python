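"""Clustering of the occupancy matrix and cell-type relatedness dendrogram.

Rows (merged segments) are clustered by Euclidean k-means on the
quantile-normalized signal; cell-type relatedness is summarized by
average-linkage hierarchical clustering of the Pearson dissimilarity
(1 − r) computed on the raw (library-normalized, not quantile-normalized)
signal columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

__all__ = [
    "ClusterResult",
    "Dendrogram",
    "clip_quantiles",
    "kmeans_cluster",
    "gmm_cluster",
    "correlation_dendrogram",
]


@dataclass
class ClusterResult:
    labels: np.ndarray  # cluster id per row, 1..k
    k: int
    seed: int
    inertia: float
    row_order: np.ndarray  # display ordering (stable sort by label)

    def __post_init__(self) -> None:
        if self.labels.min(initial=1) < 1 or self.labels.max(initial=self.k) > self.k:
            raise ValueError("labels must lie in [1..k]")


@dataclass
class Dendrogram:
    leaves: list[str]
    merges: list[tuple[int, int, float]]  # (node, node, height)
    newick: str
    linkage: np.ndarray = field(repr=False, default=None)


def clip_quantiles(matrix: pd.DataFrame, lo: float = 0.005, hi: float = 0.995) -> pd.DataFrame:
    """Winsorize each column at its lo/hi quantiles (heatmap saturation).

    Quantiles are taken as actual data values (lower/higher order
    statistics), which makes the operation idempotent.
    """
    if not (0 < lo < hi < 1):
        raise ValueError(f"need 0 < lo < hi < 1, got lo={lo}, hi={hi}")
    values = matrix.to_numpy(dtype=float)
    lower = pd.Series(np.quantile(values, lo, axis=0, method="lower"), index=matrix.columns)
    upper = pd.Series(np.quantile(values, hi, axis=0, method="higher"), index=matrix.columns)
    return matrix.clip(lower=lower, upper=upper, axis=1)


def kmeans_cluster(
    matrix: pd.DataFrame, k: int = 16, seed: int = 0, n_restarts: int = 10
) -> ClusterResult:
    """Euclidean k-means on rows; best of ``n_restarts`` by inertia.

    Deterministic for a given seed (k-means++ initialization with a fixed
    random state).
    """
    n = matrix.shape[0]
    if k < 1 or k > n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(matrix.to_numpy(dtype=float)) + 1
    order = np.argsort(labels, kind="stable")
    return ClusterResult(labels=labels, k=k, seed=seed, inertia=float(km.inertia_), row_order=order)


def gmm_cluster(
    matrix: pd.DataFrame, k: int = 16, seed: int = 0, n_restarts: int = 5
) -> ClusterResult:
    """Model-based (Gaussian-mixture) variant with the same interface."""
    n = matrix.shape[0]
    if k < 1 or k > n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    gm = GaussianMixture(
        n_components=k, covariance_type="diag", n_init=n_restarts, random_state=seed
    )
    x = matrix.to_numpy(dtype=float)
    labels = gm.fit_predict(x) + 1
    order = np.argsort(labels, kind="stable")
    # report within-cluster sum of squares for interface parity
    inertia = 0.0
    for c in range(1, k + 1):
        rows = x[labels == c]
        if len(rows):
            inertia += float(((rows - rows.mean(axis=0)) ** 2).sum())
    return ClusterResult(labels=labels, k=k, seed=seed, inertia=inertia, row_order=order)


def _tree_to_newick(node: hierarchy.ClusterNode, leaves: list[str], parent_height: float) -> str:
    if node.is_leaf():
        return f"{leaves[node.id]}:{parent_height - 0.0:.6g}"
    left = _tree_to_newick(node.get_left(), leaves, node.dist)
    right = _tree_to_newick(node.get_right(), leaves, node.dist)
    return f"({left},{right}):{parent_height - node.dist:.6g}"


def correlation_dendrogram(matrix_raw: pd.DataFrame) -> Dendrogram:
    """Average-linkage dendrogram on Pearson dissimilarity 1 − r.

    Computed on the raw signal columns; a zero-variance column makes the
    correlation undefined and is rejected with the column name.
    """
    if matrix_raw.shape[1] < 2:
        raise ValueError("need ≥2 columns for a dendrogram")
    x = matrix_raw.to_numpy(dtype=float)
    variances = x.var(axis=0)
    for col, v in zip(matrix_raw.columns, variances):
        if v == 0:
            raise ValueError(f"column {col!r} has zero variance; Pearson correlation undefined")
    corr = np.corrcoef(x.T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)  # symmetrize fp noise
    z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    leaves = [str(c) for c in matrix_raw.columns]
    tree = hierarchy.to_tree(z)
    newick = "(" + ",".join(
        _tree_to_newick(child, leaves, tree.dist) for child in (tree.get_left(), tree.get_right())
    ) + ");"
    merges = [(int(a), int(b), float(h)) for a, b, h, _ in z]
    return Dendrogram(leaves=leaves, merges=merges, newick=newick, linkage=z)
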