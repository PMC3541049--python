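"""Community comparison: Bray-Curtis dissimilarity, UPGMA clustering,
cophenetic validation, dendrogram cutting, and Kruskal-Wallis factor
tests.

BC(x, y) = sum|x_i - y_i| / sum(x_i + y_i) between relative-abundance
vectors; UPGMA (average agglomeration) turns the pairwise dissimilarity
matrix into an ultrametric merge tree whose node heights are cophenetic
dissimilarities; the cophenetic correlation (Pearson, between the input
dissimilarities and the tree's leaf-pair merge heights) validates that
the tree reproduces the pairwise structure; cutting the tree at a
height partitions the samples into community groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from scipy.stats import kruskal, pearsonr
from skbio import DistanceMatrix

__all__ = [
    "Dendrogram",
    "bray_curtis",
    "upgma",
    "cophenetic_correlation",
    "cut_tree",
    "kruskal_wallis",
    "kruskal_by_factor",
    "to_newick",
]


@dataclass
class Dendrogram:
    """UPGMA merge tree: scipy linkage matrix plus leaf ids.  Internal
    node heights are the merge dissimilarities, non-decreasing toward
    the root."""

    linkage: np.ndarray
    ids: tuple

    @property
    def n_leaves(self) -> int:
        return len(self.ids)

    @property
    def root_height(self) -> float:
        return float(self.linkage[-1, 2])

    def cophenetic_matrix(self) -> DistanceMatrix:
        condensed = hierarchy.cophenet(self.linkage)
        return DistanceMatrix(squareform(condensed), ids=self.ids)


def _as_frame(matrix) -> pd.DataFrame:
    if hasattr(matrix, "abundance"):  # CommunityMatrix
        df = matrix.abundance.copy()
        df["unknown"] = matrix.unknown
        return df
    if hasattr(matrix, "table"):  # BinTable (bins x samples)
        return matrix.table.T
    return pd.DataFrame(matrix)


def bray_curtis(matrix) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities between sample rows.

    Accepts a CommunityMatrix (unknown fraction included as a bin), a
    BinTable, or any samples x bins frame/array.  A pair of all-zero
    samples is defined to have dissimilarity 0.
    """
    df = _as_frame(matrix)
    data = df.to_numpy(dtype=float)
    if (data < 0).any():
        raise ValueError("abundances must be non-negative")
    if len(df) < 2:
        raise ValueError("need at least two samples")
    condensed = pdist(data, metric="braycurtis")
    condensed = np.nan_to_num(condensed, nan=0.0)  # all-zero pairs -> 0
    return DistanceMatrix(squareform(condensed), ids=[str(i) for i in df.index])


def upgma(d: DistanceMatrix) -> Dendrogram:
    """Average-agglomeration hierarchical clustering of a dissimilarity
    matrix (inter-cluster distance = unweighted mean of member pairwise
    distances)."""
    if d.shape[0] < 2:
        raise ValueError("UPGMA needs at least two samples")
    linkage = hierarchy.linkage(d.condensed_form(), method="average")
    return Dendrogram(linkage=linkage, ids=tuple(d.ids))


def cophenetic_correlation(d: DistanceMatrix, tree: Dendrogram) -> float:
    """Pearson correlation between the condensed input dissimilarities
    and the tree's cophenetic dissimilarities (leaf-pair merge heights)."""
    if tuple(d.ids) != tree.ids:
        raise ValueError("tree was not built over this matrix's ids")
    if d.shape[0] < 3:
        raise ValueError("cophenetic correlation undefined for fewer than 3 samples")
    cophenetic = hierarchy.cophenet(tree.linkage)
    original = d.condensed_form()
    if np.allclose(original, original[0]) or np.allclose(cophenetic, cophenetic[0]):
        return 1.0 if np.allclose(original, cophenetic) else float("nan")
    return float(pearsonr(original, cophenetic)[0])


def cut_tree(tree: Dendrogram, h: float) -> pd.Series:
    """Cluster labels after removing merges with height > h."""
    if h < 0:
        raise ValueError("cut height must be non-negative")
    labels = hierarchy.fcluster(tree.linkage, t=h, criterion="distance")
    return pd.Series(labels, index=pd.Index(tree.ids, name="sample_id"), name="cluster")


def kruskal_wallis(values, groups):
    """Kruskal-Wallis rank-sum test with midrank ties and the standard
    tie correction; p from the chi-square approximation (k-1 d.f.).

    Returns (H, p).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must align")
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("Kruskal-Wallis needs at least two groups")
    samples = [values[groups == g] for g in levels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group must be non-empty")
    if all(np.allclose(s, values[0]) for s in samples):
        return 0.0, 1.0  # identical data in every group: H = 0 by convention
    res = kruskal(*samples)
    return float(res.statistic), float(res.pvalue)


def kruskal_by_factor(matrix, factor: pd.Series, response="abundance", clusters=None):
    """Factor tests over a community matrix.

    response="abundance": one test per taxon bin (values = per-sample
    relative abundances grouped by the factor); returns a DataFrame of
    (bin, H, p).  response="cluster": a single test on cluster
    membership ranks grouped by the factor (requires `clusters`).
    Both modes are reconstructions of 'groupings differ with respect to
    the factor'.
    """
    df = _as_frame(matrix)
    factor = factor.reindex(df.index)
    if factor.isna().any():
        raise ValueError("factor labels missing for some samples")
    if response == "cluster":
        if clusters is None:
            raise ValueError("cluster response needs cluster labels")
        clusters = clusters.reindex(df.index)
        h, p = kruskal_wallis(clusters.to_numpy(float), factor.to_numpy())
        return pd.DataFrame([{"response": "cluster", "H": h, "p": p}])
    rows = []
    for col in df.columns:
        h, p = kruskal_wallis(df[col].to_numpy(), factor.to_numpy())
        rows.append({"response": col, "H": h, "p": p})
    return pd.DataFrame(rows)


def to_newick(tree: Dendrogram) -> str:
    """Newick export with ultrametric branch lengths (leaf depth = merge
    height / 2, so the path between two leaves equals their cophenetic
    dissimilarity)."""
    root = hierarchy.to_tree(tree.linkage)

    def height(node):
        return 0.0 if node.is_leaf() else float(node.dist)

    def render(node, parent_height):
        length = (parent_height - height(node)) / 2.0
        if node.is_leaf():
            return f"{tree.ids[node.id]}:{length:.6g}"
        left = render(node.left, height(node))
        right = render(node.right, height(node))
        return f"({left},{right}):{length:.6g}"

    h = height(root)
    return f"({render(root.left, h)},{render(root.right, h)});"
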