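"""Downstream profile analytics: k-NN imputation, mean centering,
Pearson-distance complete-linkage clustering, tree cutting, PCA, and
dendrogram/heatmap exports.

Clustering operates on raw percent-positive rows; mean centering is
applied only on the PCA path.  Correlation distance (1 - Pearson r) is
bounded in [0, 2] but is not a metric - the triangle inequality can fail
- which complete linkage tolerates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics.pairwise import nan_euclidean_distances

__all__ = [
    "ClusterTree",
    "PCAResult",
    "knn_impute",
    "mean_center",
    "pearson_distance",
    "hcluster",
    "cut_tree",
    "pca",
    "to_newick",
    "export_dendrogram",
]


def knn_impute(matrix: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Replace each missing cell by the mean of its column over the k nearest rows.

    Row distance is Euclidean over mutually observed columns, scaled by
    the proportion observed (the nan-Euclidean convention); only rows
    with the target column observed can donate, and k is truncated to the
    donors available.  A fully missing column cannot be imputed and is an
    error naming the antigen.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    values = matrix.to_numpy(dtype=float)
    if not np.isnan(values).any():
        return matrix.copy()
    empty = matrix.columns[np.isnan(values).all(axis=0)]
    if len(empty):
        raise ValueError(f"column(s) entirely missing, cannot impute: {list(empty)}")
    if np.isnan(values).all(axis=1).any():
        raise ValueError("a row has no observed values")
    dist = nan_euclidean_distances(values, values)
    out = values.copy()
    n = len(values)
    for i in range(n):
        for j in np.flatnonzero(np.isnan(values[i])):
            donors = np.flatnonzero(~np.isnan(values[:, j]))
            donors = donors[donors != i]
            order = donors[np.argsort(dist[i, donors], kind="stable")]
            nearest = order[:k]
            out[i, j] = values[nearest, j].mean()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def mean_center(matrix: pd.DataFrame) -> pd.DataFrame:
    """Subtract each column's mean (idempotent)."""
    return matrix - matrix.mean(axis=0)


def pearson_distance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise row distance d(i,j) = 1 - Pearson correlation of rows i, j."""
    values = matrix.to_numpy(dtype=float)
    if len(values) < 2:
        raise ValueError("need >= 2 rows")
    sd = values.std(axis=1)
    constant = np.flatnonzero(sd == 0)
    if len(constant):
        names = [str(matrix.index[i]) for i in constant]
        raise ValueError(f"constant row(s), correlation undefined: {names}")
    d = 1.0 - np.corrcoef(values)
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 2.0)
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


@dataclass
class ClusterTree:
    """Agglomeration result: scipy-format linkage plus leaf labels."""

    linkage: np.ndarray  # (n-1, 4): child, child, height, size
    labels: list[str]
    method: str = "complete"

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.linkage.shape != (n - 1, 4):
            raise ValueError("linkage must have n-1 merges for n leaves")

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.linkage)
        return [self.labels[i] for i in order]


def hcluster(distances: pd.DataFrame, method: str = "complete") -> ClusterTree:
    """Agglomerative clustering of a symmetric distance matrix.

    Inter-cluster distance under complete linkage is the maximum pairwise
    member distance; merge heights are therefore non-decreasing.
    """
    d = distances.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    condensed = squareform(d, checks=False)
    linkage = hierarchy.linkage(condensed, method=method)
    return ClusterTree(
        linkage=linkage, labels=[str(x) for x in distances.index], method=method
    )


def cut_tree(tree: ClusterTree, k: int) -> pd.Series:
    """Cluster labels from cutting the k-1 highest merges.

    Labels are integers 0..k-1 ordered by first appearance along the leaf
    index order, so the labelling is deterministic.
    """
    n = len(tree.labels)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range [1, {n}]")
    raw = hierarchy.fcluster(tree.linkage, t=k, criterion="maxclust")
    if len(np.unique(raw)) != k:
        # ties in merge heights can make maxclust undershoot; fall back to
        # an explicit cut between the (k-1)th and kth highest merges
        heights = np.sort(tree.heights)
        thr = (heights[-k] + heights[-(k - 1)]) / 2 if k > 1 else np.inf
        raw = hierarchy.fcluster(tree.linkage, t=thr, criterion="distance")
    relabel: dict[int, int] = {}
    out = np.empty(n, dtype=int)
    for i, r in enumerate(raw):
        if r not in relabel:
            relabel[r] = len(relabel)
        out[i] = relabel[r]
    return pd.Series(out, index=tree.labels, name="cluster")


@dataclass
class PCAResult:
    """Principal components of a profile matrix."""

    loadings: pd.DataFrame       # antigen x component
    scores: pd.DataFrame         # sample x component
    explained_variance_ratio: np.ndarray

    def __post_init__(self) -> None:
        evr = self.explained_variance_ratio
        if np.any(evr < -1e-12) or np.any(np.diff(evr) > 1e-12) or evr.sum() > 1 + 1e-9:
            raise ValueError("explained-variance ratios must be in [0,1], non-increasing")


def pca(matrix: pd.DataFrame, n_components: int | None = None, center: bool = True) -> PCAResult:
    """PCA by SVD of the (column-)mean-centered matrix.

    Sign convention: within each component the largest-magnitude loading
    is made positive.  Requesting more components than the matrix rank
    truncates with a warning.
    """
    import warnings

    x = matrix.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("matrix contains missing values; impute first")
    if center:
        x = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    tol = max(x.shape) * np.finfo(float).eps * (s[0] if s.size else 0)
    rank = int((s > tol).sum())
    if n_components is None:
        n_components = rank
    elif n_components > rank:
        warnings.warn(
            f"requested {n_components} components but rank is {rank}; truncating",
            stacklevel=2,
        )
        n_components = rank
    u, s, vt = u[:, :n_components], s[:n_components], vt[:n_components]
    # sign convention: largest-|loading| positive per component
    for c in range(n_components):
        pivot = np.argmax(np.abs(vt[c]))
        if vt[c, pivot] < 0:
            vt[c] *= -1
            u[:, c] *= -1
    total_var = (x**2).sum()
    evr = (s**2) / total_var if total_var > 0 else np.zeros_like(s)
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return PCAResult(
        loadings=pd.DataFrame(vt.T, index=matrix.columns, columns=comp_names),
        scores=pd.DataFrame(u * s, index=matrix.index, columns=comp_names),
        explained_variance_ratio=evr,
    )


def to_newick(tree: ClusterTree) -> str:
    """Newick serialisation with ultrametric branch lengths.

    Each internal node sits at half its merge height, so the two leaves
    of a 2-leaf tree each get branch length height/2.
    """
    n = len(tree.labels)
    elevation = {i: 0.0 for i in range(n)}
    # merges are ordered bottom-up, so children's elevations always exist
    parts: dict[int, str] = {i: tree.labels[i].replace(" ", "_") for i in range(n)}
    for m, (a, b, h, _) in enumerate(tree.linkage):
        a, b = int(a), int(b)
        elev = h / 2.0
        elevation[n + m] = elev
        parts[n + m] = (
            f"({parts[a]}:{elev - elevation[a]:.10g},{parts[b]}:{elev - elevation[b]:.10g})"
        )
    return parts[n + len(tree.linkage) - 1] + ";"


def export_dendrogram(tree: ClusterTree, path) -> None:
    """Write the tree as Newick plus a CSV of the dendrogram leaf order."""
    from pathlib import Path

    path = Path(path)
    path.write_text(to_newick(tree) + "\n")
    order = tree.leaf_order()
    pd.Series(order, name="leaf").to_csv(path.with_suffix(".order.csv"), index_label="position")
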