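"""Ward hierarchical clustering of individuals and tree cuts.

The input dissimilarity is the bounded exponential transform of the gene
similarity, not a Euclidean embedding, so the Ward criterion is applied via
the Lance-Williams recurrence directly to the given distances (the classical
"ward.D" convention). A "ward.D2" dialect (distances squared inside the
recurrence) is also available. Merge order under ward.D equals scipy's
squared-input Ward applied to the square roots of the distances, which is
how it is computed here; cluster assignments are obtained by cutting the
tree at a prespecified number of groups, never at a height, so possible
height inversions on non-Euclidean input are harmless.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .similarity import DistanceMatrix

__all__ = ["ClusterTree", "Partition", "ward_tree", "cut_tree", "partition_sweep"]


@dataclass
class Partition:
    """Assignment of n individuals to k nonempty elements labelled 1..k."""

    gene: str
    k: int
    labels: np.ndarray
    sizes: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        uniq = np.unique(labels)
        if not np.array_equal(uniq, np.arange(1, self.k + 1)):
            raise ValueError(
                f"labels must cover 1..{self.k} with no empty element"
            )
        self.labels = labels
        self.sizes = np.bincount(labels, minlength=self.k + 1)[1:]

    @property
    def n(self) -> int:
        return self.labels.shape[0]


@dataclass
class ClusterTree:
    """Agglomeration history of n-1 Ward merges.

    ``linkage`` is a scipy linkage matrix whose heights are on the
    scipy (squared-input) scale; ``heights`` are the merge criteria on the
    dialect's own scale.
    """

    gene: str
    linkage: np.ndarray
    dialect: str
    n: int

    @property
    def heights(self) -> np.ndarray:
        h = self.linkage[:, 2]
        return h * h if self.dialect == "ward.D" else h


def ward_tree(dist: DistanceMatrix, dialect: str = "ward.D") -> ClusterTree:
    """Cluster individuals with Ward's method on a general dissimilarity.

    ``dialect='ward.D'`` feeds the distances as-is to the Lance-Williams
    Ward update; ``'ward.D2'`` squares them first (scipy's native
    convention). Deterministic for identical input.
    """
    v = dist.values
    n = dist.n
    if n < 2:
        raise ValueError("need at least 2 individuals to cluster")
    if not np.allclose(v, v.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(v) != 0):
        raise ValueError("distance matrix must have a zero diagonal")
    condensed = squareform(v, checks=False)
    if dialect == "ward.D":
        condensed = np.sqrt(condensed)
    elif dialect != "ward.D2":
        raise ValueError(f"unknown Ward dialect {dialect!r}")
    Z = hierarchy.linkage(condensed, method="ward")
    return ClusterTree(gene=dist.gene, linkage=Z, dialect=dialect, n=n)


def cut_tree(tree: ClusterTree, k: int) -> Partition:
    """Cut the agglomeration into exactly ``k`` nonempty groups.

    Cuts undo the last k-1 merges (by merge order, not height), so the cut
    at k is always refined by the cut at k+1. Labels are renumbered 1..k in
    order of first appearance for determinism.
    """
    if not (1 <= k <= tree.n):
        raise ValueError(f"k={k} out of range 1..{tree.n}")
    raw = hierarchy.cut_tree(tree.linkage, n_clusters=k).ravel()
    _, first = np.unique(raw, return_index=True)
    order = raw[np.sort(first)]
    remap = {old: new for new, old in enumerate(order, start=1)}
    labels = np.array([remap[x] for x in raw], dtype=int)
    return Partition(gene=tree.gene, k=k, labels=labels)


def partition_sweep(
    dist: DistanceMatrix, ks: Sequence[int], dialect: str = "ward.D"
) -> List[Partition]:
    """One partition per requested size, all cut from the same tree."""
    ks = list(ks)
    if not ks:
        raise ValueError("ks must be nonempty")
    tree = ward_tree(dist, dialect=dialect)
    return [cut_tree(tree, k) for k in ks]
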