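"""Unsupervised structure discovery: PCA and hierarchical clustering.

PCA is computed by singular value decomposition of the (already centered)
data matrix; loadings are the right singular vectors with the sign fixed so
each column's largest-magnitude element is positive, which makes score and
loading plots reproducible across BLAS builds.  Explained variance is
reported in percent.

HCA builds an agglomerative dendrogram from Euclidean distances (average,
complete or Ward linkage); the two-cluster cut at the top merge gives a
simple class-purity summary of whether the spectra fall into two groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = ["PCAResult", "Dendrogram", "pca", "hca", "two_group_separation"]

_CENTER_TOL = 1e-8
_LINKAGES = ("average", "complete", "ward")


@dataclass
class PCAResult:
    """Scores ``(n, k)``, loadings ``(p, k)`` and explained variance (%)."""

    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    k: int


@dataclass
class Dendrogram:
    """Agglomerative merge history in scipy linkage form plus leaf labels."""

    linkage: np.ndarray  # (n-1, 4): cluster i, cluster j, height, size
    leaf_labels: list[str]
    metric: str = "euclidean"
    method: str = "average"

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def cut(self, n_clusters: int) -> np.ndarray:
        """Flat cluster assignment (1-based ids) at ``n_clusters`` clusters."""
        return hierarchy.fcluster(self.linkage, t=n_clusters, criterion="maxclust")

    def to_newick(self) -> str:
        """Newick string with branch lengths = merge-height differences."""
        tree = hierarchy.to_tree(self.linkage)

        def render(node, parent_height: float) -> str:
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                return f"{self.leaf_labels[node.id]}:{parent_height:.6g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return render(tree, tree.dist).rsplit(":", 1)[0] + ";"

    def merge_table(self) -> list[dict]:
        out = []
        for i, j, h, size in self.linkage:
            out.append({"i": int(i), "j": int(j), "height": float(h), "size": int(size)})
        return out


def pca(matrix: np.ndarray, k: int) -> PCAResult:
    """Principal components of a centered matrix via SVD.

    Raises if the matrix is visibly uncentered -- centering is the caller's
    contract (the preprocessing chain ends with mean-centering), and silently
    re-centering here would hide a pipeline wiring bug.
    """
    X = np.asarray(matrix, dtype=float)
    n, p = X.shape
    if np.max(np.abs(X.mean(axis=0))) > _CENTER_TOL * max(1.0, np.max(np.abs(X))):
        raise ValueError("pca expects a column-centered matrix")
    if not 1 <= k <= min(n - 1, p):
        raise ValueError(f"k={k} out of range [1, {min(n - 1, p)}]")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    total = np.sum(s**2)
    loadings = Vt[:k].T.copy()
    # sign convention: largest-|.| element of each loading column positive
    for j in range(k):
        imax = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[imax, j] < 0:
            loadings[:, j] = -loadings[:, j]
    scores = X @ loadings
    evr = 100.0 * (s[:k] ** 2) / total
    return PCAResult(scores=scores, loadings=loadings, explained_variance_ratio=evr, k=k)


def hca(matrix: np.ndarray, metric: str = "euclidean", linkage: str = "average",
        leaf_labels: list[str] | None = None) -> Dendrogram:
    """Agglomerative clustering of rows from the pairwise distance matrix."""
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("hca needs at least 2 rows")
    if metric != "euclidean":
        raise ValueError("only euclidean distance is supported")
    if linkage not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}")
    Z = hierarchy.linkage(pdist(X, metric="euclidean"), method=linkage)
    labels = leaf_labels if leaf_labels is not None else [str(i) for i in range(X.shape[0])]
    if len(labels) != X.shape[0]:
        raise ValueError("leaf_labels length must match row count")
    return Dendrogram(linkage=Z, leaf_labels=list(labels), metric=metric, method=linkage)


def two_group_separation(dendro: Dendrogram, classes) -> float:
    """Purity of the two-cluster cut against the true class labels.

    Cuts the tree at the top merge into 2 clusters; each leaf scores 1 when
    its cluster's majority class equals its own class.  1.0 means the
    dendrogram splits cleanly into the two classes.
    """
    classes = list(classes)
    if dendro.n_leaves < 2:
        raise ValueError("degenerate dendrogram")
    if len(classes) != dendro.n_leaves:
        raise ValueError("classes length must match leaf count")
    assign = dendro.cut(2)
    correct = 0
    for cid in np.unique(assign):
        members = [classes[i] for i in np.flatnonzero(assign == cid)]
        values, counts = np.unique(members, return_counts=True)
        majority = values[np.argmax(counts)]
        correct += sum(1 for c in members if c == majority)
    return correct / dendro.n_leaves
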