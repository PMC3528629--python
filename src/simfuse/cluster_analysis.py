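"""Hierarchical clustering of a fused similarity matrix.

Similarity is converted to a distance by ``d = 1 - s`` and clustered
agglomeratively (average linkage by default).  Trees can be cut into
exactly k classes with canonical labels (1..k in order of first leaf
appearance) and exported as Newick text.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

LINKAGES = ("average", "complete", "single")

__all__ = [
    "ClusteringTree",
    "ClusterAssignment",
    "to_distance",
    "hierarchical_cluster",
    "cut_tree",
    "to_newick",
]


@dataclass
class ClusteringTree:
    """Agglomerative merge sequence in SciPy linkage-matrix form."""

    Z: np.ndarray  # (n-1, 4) linkage matrix
    leaf_ids: list[str]
    linkage: str = "average"

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        n = len(self.leaf_ids)
        if self.Z.shape != (n - 1, 4):
            raise ValueError(f"linkage matrix shape {self.Z.shape} != ({n - 1}, 4)")

    @property
    def n(self) -> int:
        return len(self.leaf_ids)

    @property
    def heights(self) -> np.ndarray:
        return self.Z[:, 2]


@dataclass
class ClusterAssignment:
    """Flat partition: labels 1..k over an ordered compound list."""

    compound_ids: list[str]
    labels: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.compound_ids),):
            raise ValueError("one label per compound required")
        if self.labels.size and (self.labels.min() < 1 or self.labels.max() > self.k):
            raise ValueError(f"labels must lie in 1..{self.k}")


def to_distance(S: np.ndarray) -> np.ndarray:
    """d = 1 - s entrywise, with an exactly zero diagonal."""
    S = np.asarray(S, dtype=float)
    if S.min() < -1e-9 or S.max() > 1 + 1e-9:
        raise ValueError("similarity entries must lie in [0, 1]")
    D = 1.0 - np.clip(S, 0.0, 1.0)
    np.fill_diagonal(D, 0.0)
    return (D + D.T) / 2.0


def hierarchical_cluster(
    D: np.ndarray, compound_ids, linkage: str = "average"
) -> ClusteringTree:
    """Agglomerative clustering of a symmetric zero-diagonal distance matrix."""
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    D = np.asarray(D, dtype=float)
    if np.isnan(D).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(D, D.T, atol=1e-12, rtol=0) or np.abs(np.diag(D)).max() > 1e-12:
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    Z = hierarchy.linkage(squareform(D, checks=False), method=linkage)
    return ClusteringTree(Z=Z, leaf_ids=[str(c) for c in compound_ids], linkage=linkage)


def cut_tree(tree: ClusteringTree, k: int) -> ClusterAssignment:
    """Cut into exactly k classes; labels are canonical (first-appearance)."""
    n = tree.n
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range [1, {n}]")
    raw = hierarchy.cut_tree(tree.Z, n_clusters=k).ravel()
    remap: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, r in enumerate(raw):
        if r not in remap:
            remap[r] = len(remap) + 1
        labels[i] = remap[r]
    return ClusterAssignment(compound_ids=list(tree.leaf_ids), labels=labels, k=k)


def to_newick(tree: ClusteringTree) -> str:
    """Newick export; branch lengths are merge-height differences."""
    n = tree.n
    heights = {i: 0.0 for i in range(n)}
    texts = {i: _escape(tree.leaf_ids[i]) for i in range(n)}
    for m, (a, b, h, _) in enumerate(tree.Z):
        a, b = int(a), int(b)
        la = h - heights[a]
        lb = h - heights[b]
        node = n + m
        texts[node] = f"({texts[a]}:{la:.10g},{texts[b]}:{lb:.10g})"
        heights[node] = h
    return texts[n + len(tree.Z) - 1] + ";"


def _escape(label: str) -> str:
    if any(c in label for c in "(),:;' \t"):
        return "'" + label.replace("'", "''") + "'"
    return label
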