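"""PCA and hierarchical clustering with Cluster-3.0 semantics
(uncentered correlation similarity, complete linkage).

The agglomeration is implemented in-package rather than delegated to
scipy because deterministic tie-breaking (merge the lowest-index pair
first) is part of the contract; on tie-free data the merge heights agree
with ``scipy.cluster.hierarchy.linkage(..., 'complete')`` on cosine
distances, which the test suite uses as an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "DendrogramNode",
    "uncentered_correlation_distance",
    "distance_matrix",
    "hcluster",
    "cut_tree",
    "to_newick",
    "pca",
    "impute_missing",
]


@dataclass(frozen=True)
class DendrogramNode:
    """Binary merge node; leaves carry ``label`` and height 0."""

    height: float
    left: "DendrogramNode | None" = None
    right: "DendrogramNode | None" = None
    label: str | None = None

    @property
    def is_leaf(self) -> bool:
        return self.label is not None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        return self.left.leaves() + self.right.leaves()


def uncentered_correlation_distance(x, y) -> float:
    """1 minus the uncentered (no mean subtraction) correlation of x and y.

    The similarity is sum(x*y) / sqrt(sum(x^2) * sum(y^2)); the distance
    lies in [0, 2]. Zero-norm vectors are an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    nx = np.sqrt((x * x).sum())
    ny = np.sqrt((y * y).sum())
    if nx == 0 or ny == 0:
        raise ValueError("zero-norm vector has undefined uncentered correlation")
    return float(1.0 - (x * y).sum() / (nx * ny))


def distance_matrix(vectors: np.ndarray) -> np.ndarray:
    """Pairwise uncentered-correlation distances for rows of ``vectors``."""
    v = np.asarray(vectors, dtype=float)
    norms = np.sqrt((v * v).sum(axis=1))
    if np.any(norms == 0):
        bad = np.nonzero(norms == 0)[0].tolist()
        raise ValueError(f"zero-norm vectors at rows {bad}")
    sim = (v @ v.T) / np.outer(norms, norms)
    d = 1.0 - sim
    np.fill_diagonal(d, 0.0)
    return np.maximum(d, 0.0)


def hcluster(
    matrix: pd.DataFrame, axis: str = "cols"
) -> tuple[DendrogramNode, np.ndarray]:
    """Complete-linkage agglomeration on uncentered-correlation distances.

    ``axis="cols"`` clusters samples (columns), ``axis="rows"`` clusters
    features. Ties are broken by the lowest (i, j) pair index over clusters
    ordered by creation, making the output byte-reproducible. Returns the
    dendrogram root and a scipy-style (n-1, 4) linkage matrix.
    """
    if axis not in ("rows", "cols"):
        raise ValueError(f"axis must be 'rows' or 'cols', got {axis!r}")
    vectors = matrix.to_numpy(dtype=float)
    labels = list(matrix.index.astype(str))
    if axis == "cols":
        vectors = vectors.T
        labels = list(matrix.columns.astype(str))
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 items to cluster")

    d = distance_matrix(vectors)
    # Lance-Williams complete linkage: d(i+j, k) = max(d(i,k), d(j,k)).
    # Cluster ids are 0..n-1 for leaves, then n, n+1, ... in creation order.
    total = 2 * n - 1
    big = np.full((total, total), np.inf)
    big[:n, :n] = d
    np.fill_diagonal(big, np.inf)
    nodes: dict[int, DendrogramNode] = {
        i: DendrogramNode(0.0, label=labels[i]) for i in range(n)
    }
    sizes = {i: 1 for i in range(n)}
    active = list(range(n))
    linkage = np.zeros((n - 1, 4))
    for step in range(n - 1):
        ids = np.array(active)
        sub = big[np.ix_(ids, ids)]
        iu = np.triu_indices(len(ids), 1)
        vals = sub[iu]
        # argmin takes the first minimum in row-major order, i.e. the
        # lowest (i, j) pair among ties — the documented tie-break.
        k = int(np.argmin(vals))
        i, j = int(ids[iu[0][k]]), int(ids[iu[1][k]])
        dist = float(vals[k])
        new_id = n + step
        merged = np.maximum(big[i, ids], big[j, ids])
        big[new_id, ids] = merged
        big[ids, new_id] = merged
        big[new_id, new_id] = np.inf
        big[new_id, [i, j]] = np.inf
        big[[i, j], new_id] = np.inf
        nodes[new_id] = DendrogramNode(
            height=dist, left=nodes[i], right=nodes[j]
        )
        sizes[new_id] = sizes[i] + sizes[j]
        linkage[step] = (i, j, dist, sizes[new_id])
        active = [c for c in active if c not in (i, j)] + [new_id]
        del nodes[i], nodes[j]
    return nodes[2 * n - 2], linkage


def cut_tree(root: DendrogramNode, k: int) -> dict[str, int]:
    """Cut the dendrogram into ``k`` clusters (split highest merges first).

    Returns {leaf label: cluster id}, ids numbered by leaf order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    clusters = [root]
    while len(clusters) < k:
        # split the cluster with the highest merge height
        heights = [c.height if not c.is_leaf else -1.0 for c in clusters]
        i = int(np.argmax(heights))
        if clusters[i].is_leaf:
            break  # fewer leaves than k
        node = clusters.pop(i)
        clusters.extend([node.left, node.right])
    clusters.sort(key=lambda c: c.leaves()[0])
    return {
        leaf: cid for cid, c in enumerate(clusters) for leaf in c.leaves()
    }


def _escape(label: str) -> str:
    if any(ch in label for ch in " (),:;'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(root: DendrogramNode) -> str:
    """Serialize a dendrogram as a Newick string with branch lengths.

    A child's branch length is the height difference to its parent.
    """

    def render(node: DendrogramNode, parent_height: float) -> str:
        length = max(parent_height - node.height, 0.0)
        if node.is_leaf:
            return f"{_escape(node.label)}:{length:.10g}"
        inner = ",".join(
            render(c, node.height) for c in (node.left, node.right)
        )
        return f"({inner}):{length:.10g}"

    if root.is_leaf:
        return f"{_escape(root.label)};"
    inner = ",".join(render(c, root.height) for c in (root.left, root.right))
    return f"({inner});"


def impute_missing(matrix: pd.DataFrame, method: str = "feature_min") -> pd.DataFrame:
    """Impute NaNs per feature (row) before PCA.

    ``feature_min`` uses the row minimum (detection-floor reading);
    ``feature_mean`` uses the row mean. Rows that are entirely missing
    are dropped.
    """
    if method not in ("feature_min", "feature_mean"):
        raise ValueError(f"unknown imputation method {method!r}")
    out = matrix.dropna(how="all")
    fill = out.min(axis=1) if method == "feature_min" else out.mean(axis=1)
    return out.apply(lambda row: row.fillna(fill[row.name]), axis=1)


def pca(
    matrix: pd.DataFrame,
    n_components: int = 2,
    impute: str = "feature_min",
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA of samples (columns) over features (rows).

    Data are centered per feature but not scaled. Returns
    (scores: samples x components, loadings: features x components,
    explained variance fractions). Raises on a constant matrix.
    """
    filled = impute_missing(matrix, impute)
    x = filled.to_numpy(dtype=float).T  # samples x features
    n_components = min(n_components, min(x.shape))
    if np.allclose(x, x[0]):
        raise ValueError("constant matrix has no principal components")
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(x)
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    scores_df = pd.DataFrame(scores, index=filled.columns, columns=comp_names)
    loadings_df = pd.DataFrame(
        model.components_.T, index=filled.index, columns=comp_names
    )
    return scores_df, loadings_df, model.explained_variance_ratio_


def explained_variance_percent(fractions: Sequence[float]) -> list[float]:
    """Fractions as percentages rounded to 2 decimals (reporting style)."""
    return [round(float(f) * 100.0, 2) for f in fractions]
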