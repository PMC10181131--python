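"""Genetic-diversity analysis of dosage matrices: pairwise Euclidean
distances, UPGMA dendrograms, and PCA.

Distances use pairwise-complete deletion: each pair is compared on the
loci non-missing in both samples.  PCA imputes missing cells with the
per-marker mean dosage.  UPGMA (average linkage) is implemented directly
so that tie-breaking is deterministic — when several cluster pairs are
equally close the pair whose smallest member label sorts first is merged
— and node heights follow the cophenetic convention (half the merging
distance, so the height above two leaves equals half their cluster
distance and leaf-to-leaf path length equals the distance itself).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances plus per-pair shared-locus counts."""

    names: list[str]
    values: np.ndarray
    shared: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.names)
        if self.values.shape != (n, n) or self.shared.shape != (n, n):
            raise ValueError("distance/shared matrices must be n x n")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.names, columns=self.names)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.names.index(a), self.names.index(b)])

    @property
    def is_complete(self) -> bool:
        return not np.isnan(self.values).any()


@dataclass
class TreeNode:
    """A node of an ultrametric dendrogram; leaves carry labels."""

    height: float
    label: str | None = None
    children: tuple["TreeNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return [leaf for c in self.children for leaf in c.leaves()]


@dataclass
class Dendrogram:
    """Binary UPGMA merge tree over named samples."""

    root: TreeNode

    @property
    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.root.leaves()]

    def cophenetic_distance(self, a: str, b: str) -> float:
        """Distance implied by the tree: twice the height of the lowest
        common ancestor of the two leaves."""
        if a == b:
            return 0.0

        def find(node: TreeNode) -> TreeNode | None:
            has = {leaf.label for leaf in node.leaves()}
            if not {a, b} <= has:
                return None
            for c in node.children:
                deeper = find(c)
                if deeper is not None:
                    return deeper
            return node

        lca = find(self.root)
        if lca is None:
            raise KeyError(f"labels {a!r}, {b!r} not both in tree")
        return 2.0 * lca.height


def euclidean_distances(matrix: pd.DataFrame,
                        scale_by_shared: bool = False) -> DistanceMatrix:
    """Pairwise Euclidean distances over shared non-missing loci.

    ``d(x, y) = sqrt(sum_j (x_j - y_j)^2)`` over loci called in both
    samples.  Pairs sharing zero loci get a missing (NaN) distance.  With
    ``scale_by_shared`` the squared distance is rescaled by
    ``n_loci / n_shared`` so sparsely-compared pairs are not biased low.
    """
    if len(matrix) < 2:
        raise ValueError("need at least 2 samples for pairwise distances")
    X = matrix.to_numpy(dtype=float)
    present = ~np.isnan(X)
    X0 = np.where(present, X, 0.0)
    sq = (X0 ** 2)
    # sum over shared loci of (x - y)^2, computed via masked cross terms
    shared = (present.astype(float) @ present.T.astype(float))
    cross = X0 @ X0.T
    x2 = sq @ present.T.astype(float)
    d2 = x2 + x2.T - 2.0 * cross
    d2 = np.maximum(d2, 0.0)
    if scale_by_shared:
        with np.errstate(divide="ignore", invalid="ignore"):
            d2 = d2 * matrix.shape[1] / shared
    values = np.sqrt(d2)
    values[shared == 0] = np.nan
    np.fill_diagonal(values, 0.0)
    n_incomplete = int(np.isnan(values).sum() // 2)
    if n_incomplete:
        logger.warning("%d sample pairs share no called loci", n_incomplete)
    return DistanceMatrix(names=list(matrix.index), values=values,
                          shared=shared.astype(int))


def upgma(distances: DistanceMatrix) -> Dendrogram:
    """Average-linkage (UPGMA) hierarchical clustering.

    At each step the two closest clusters merge; the distance between
    clusters is the arithmetic mean of all cross-pair distances
    (maintained by size-weighted updates).  Merge-node height is half the
    merging distance, making the tree ultrametric.  Ties are broken by
    the lexicographically smallest member label of the candidate pair.
    """
    if not distances.is_complete:
        raise ValueError("distance matrix has missing entries; impute or "
                         "drop samples sharing no loci before clustering")
    n = len(distances.names)
    if n < 2:
        raise ValueError("need at least 2 samples to cluster")
    D = distances.values.astype(float).copy()
    nodes = {i: TreeNode(0.0, label=distances.names[i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    # sort key per cluster: lexicographically smallest member label
    keys = {i: distances.names[i] for i in range(n)}
    active = list(range(n))
    next_id = n
    big = np.full((2 * n, 2 * n), np.inf)
    big[:n, :n] = D
    np.fill_diagonal(big, np.inf)
    while len(active) > 1:
        idx = np.array(active)
        sub = big[np.ix_(idx, idx)]
        dist = float(sub.min())
        ti, tj = np.where(sub == dist)
        tied = [(idx[i], idx[j]) for i, j in zip(ti, tj) if i < j]
        a, b = min(tied, key=lambda p: tuple(sorted((keys[p[0]], keys[p[1]]))))
        if keys[b] < keys[a]:
            a, b = b, a
        node = TreeNode(height=dist / 2.0,
                        children=(nodes[a], nodes[b]))
        nodes[next_id] = node
        sizes[next_id] = sizes[a] + sizes[b]
        keys[next_id] = min(keys[a], keys[b])
        for c in active:
            if c in (a, b):
                continue
            new_d = (sizes[a] * big[a, c] + sizes[b] * big[b, c]) / sizes[next_id]
            big[next_id, c] = big[c, next_id] = new_d
        active = [c for c in active if c not in (a, b)] + [next_id]
        next_id += 1
    return Dendrogram(root=nodes[active[0]])


def pca_scores(matrix: pd.DataFrame,
               n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal-component scores of a (mean-imputed) dosage matrix.

    Missing cells are replaced by the per-marker mean dosage (logged).
    Sign convention: within each component the largest-magnitude loading
    is made positive.  Returns (scores DataFrame, explained-variance
    fractions).  A matrix with zero variance yields all-zero scores and
    zero explained variance.
    """
    if len(matrix) < n_components:
        raise ValueError("fewer samples than requested components")
    X = matrix.to_numpy(dtype=float)
    n_missing = int(np.isnan(X).sum())
    if n_missing:
        logger.info("PCA: imputing %d missing cells with per-marker means",
                    n_missing)
        col_means = np.nanmean(X, axis=0)
        col_means = np.where(np.isnan(col_means), 0.0, col_means)
        X = np.where(np.isnan(X), col_means[None, :], X)
    centered = X - X.mean(axis=0)
    if np.allclose(centered, 0.0):
        scores = np.zeros((len(matrix), n_components))
        return (pd.DataFrame(scores, index=matrix.index,
                             columns=[f"PC{i + 1}" for i in range(n_components)]),
                np.zeros(n_components))
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(centered)
    for j in range(n_components):
        i_max = np.argmax(np.abs(pca.components_[j]))
        if pca.components_[j, i_max] < 0:
            scores[:, j] *= -1.0
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return (pd.DataFrame(scores, index=matrix.index, columns=cols),
            pca.explained_variance_ratio_.copy())
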