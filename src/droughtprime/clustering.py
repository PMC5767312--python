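"""Hierarchical clustering of samples: Euclidean distance, Ward linkage.

Clustering runs on the normalized probe matrix (all probes, post baseline
transformation). With the effect hierarchy planted by the simulator —
organ > condition > genotype — cutting the tree at k = 2 separates the
organs and k = 4 the organ × condition groups, the structure a whole-
transcriptome sample dendrogram shows for this design.

The Ward dialect is the squared-Euclidean criterion with square-root merge
heights (Ward.D2): merge heights are then monotone non-decreasing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform


def distance_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Euclidean distances between sample columns.

    d(i, j) = sqrt(Σ_probes (x_pi − x_pj)²); symmetric with zero diagonal.
    """
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("expression matrix contains missing/non-finite values")
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    d = squareform(pdist(values.T, metric="euclidean"))
    return pd.DataFrame(d, index=matrix.columns, columns=matrix.columns)


def _validate_distances(distances: pd.DataFrame) -> np.ndarray:
    d = distances.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1]:
        raise ValueError("distance table must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance table is not symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ValueError("distance table has a non-zero diagonal")
    if (d < -1e-12).any():
        raise ValueError("negative distances")
    return d


def ward_linkage(distances: pd.DataFrame) -> pd.DataFrame:
    """Agglomerative Ward merging over a Euclidean distance table.

    Returns the merge list as a DataFrame (cluster_a, cluster_b, height,
    size) in scipy linkage convention: leaves are 0..n−1 in the order of
    ``distances``' index, merge i creates cluster n+i. Heights are
    non-decreasing.
    """
    d = _validate_distances(distances)
    Z = hierarchy.linkage(squareform(d, checks=False), method="ward")
    heights = Z[:, 2]
    assert np.all(np.diff(heights) >= -1e-9), "Ward merge heights must be monotone"
    out = pd.DataFrame(Z, columns=["cluster_a", "cluster_b", "height", "size"])
    out.attrs["leaf_labels"] = list(distances.index)
    return out


def cut_tree(tree: pd.DataFrame, k: int) -> pd.Series:
    """Labels for the k-cluster partition obtained by removing the k−1
    highest merges. Deterministic; labels are arbitrary but consistent."""
    labels = tree.attrs.get("leaf_labels")
    n = len(tree) + 1
    if labels is None:
        labels = list(range(n))
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    flat = hierarchy.fcluster(tree[["cluster_a", "cluster_b", "height", "size"]].to_numpy(), k, criterion="maxclust")
    return pd.Series(flat, index=pd.Index(labels, name="sample_id"), name="cluster")


def to_newick(tree: pd.DataFrame) -> str:
    """Serialize the merge list as a Newick string with branch lengths
    derived from merge heights (leaf labels from the distance table)."""
    labels = tree.attrs.get("leaf_labels")
    Z = tree[["cluster_a", "cluster_b", "height", "size"]].to_numpy()
    root = hierarchy.to_tree(Z)
    if labels is None:
        labels = [str(i) for i in range(root.get_count())]

    def render(node, parent_height: float) -> str:
        length = max(parent_height - (0.0 if node.is_leaf() else node.dist), 0.0)
        if node.is_leaf():
            length = parent_height
            return f"{labels[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    left = render(root.left, root.dist)
    right = render(root.right, root.dist)
    return f"({left},{right});"


def cluster_samples(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Distance table + Ward tree for a normalized matrix."""
    d = distance_matrix(matrix)
    return d, ward_linkage(d)
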