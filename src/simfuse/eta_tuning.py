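"""Stability-based selection of the sparseness parameter eta.

For each candidate eta the whole fusion-and-clustering pipeline is
repeated on every leave-one-out subset of the compounds.  Two summary
statistics score each eta:

* AMD (average mean disagreement): for each class count k the trees of
  all subsets are cut into k classes and every unordered pair of
  subset clusterings is compared on the compounds they share; the
  disagreement of a pair is the minimum, over relabelings of one side,
  of the number of shared compounds assigned to different classes.
  AMD averages this count over pairs and then over k.  Lower is more
  stable.
* ADI (average Dunn's index): Dunn's index — minimum between-cluster
  distance over maximum within-cluster diameter — of each subset's
  partition, averaged over subsets per k; the mean and variance over k
  are reported.  Higher mean, lower variance is better.

The recommended eta minimizes AMD, with maximal ADI mean as the
tiebreak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.optimize import linear_sum_assignment

from .cluster_analysis import ClusterAssignment, ClusteringTree, cut_tree, hierarchical_cluster, to_distance
from .fusion_core import FusionConfig, fuse
from .views import SimilarityView

__all__ = [
    "StabilityReport",
    "loo_subsets",
    "disagreement",
    "amd",
    "dunn_index",
    "tune_eta",
    "DEFAULT_ETA_GRID",
]

# the customary coarse-to-fine grid spanning the sparse and uniform regimes
DEFAULT_ETA_GRID = (
    0.001, 0.01, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9,
    1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 100, 200, 500, 1000,
)


@dataclass
class StabilityReport:
    eta_grid: np.ndarray
    amd: np.ndarray
    adi_mean: np.ndarray
    adi_var: np.ndarray
    k_range: tuple[int, int]
    n_subsets: int
    recommended_eta: float

    def __post_init__(self) -> None:
        self.eta_grid = np.asarray(self.eta_grid, dtype=float)
        if (np.diff(self.eta_grid) <= 0).any():
            raise ValueError("eta grid must be strictly increasing")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "eta": self.eta_grid,
                "amd": self.amd,
                "adi_mean": self.adi_mean,
                "adi_var": self.adi_var,
            }
        )


def loo_subsets(compound_ids) -> list[np.ndarray]:
    """Index subsets each omitting exactly one compound, in id order."""
    n = len(compound_ids)
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 compounds")
    idx = np.arange(n)
    return [np.delete(idx, i) for i in range(n)]


def disagreement(a: ClusterAssignment, b: ClusterAssignment) -> int:
    """Permutation-matched label disagreement on the common compounds.

    The two partitions are restricted to the compounds they share;
    returned is the minimum over relabelings of ``b`` of the count of
    common compounds whose labels differ — the assignment-problem
    optimum on the k x k agreement matrix, identical to exhaustive
    enumeration over label permutations.
    """
    if a.k != b.k:
        raise ValueError(f"class counts differ: {a.k} vs {b.k}")
    pos_b = {c: i for i, c in enumerate(b.compound_ids)}
    common = [(i, pos_b[c]) for i, c in enumerate(a.compound_ids) if c in pos_b]
    if not common:
        return 0
    k = a.k
    agree = np.zeros((k, k), dtype=int)
    for ia, ib in common:
        agree[a.labels[ia] - 1, b.labels[ib] - 1] += 1
    row, col = linear_sum_assignment(-agree)
    return len(common) - int(agree[row, col].sum())


def amd(trees: list[ClusteringTree], k_range: tuple[int, int]) -> float:
    """Average mean disagreement of subset clusterings over k_range.

    Mean over unordered subset pairs at each k, then unweighted mean
    over k in the inclusive interval ``k_range``.
    """
    if len(trees) < 2:
        raise ValueError("need at least 2 subset clusterings")
    k_lo, k_hi = k_range
    smallest = min(t.n for t in trees)
    if not 2 <= k_lo <= k_hi <= smallest:
        raise ValueError(f"k_range {k_range} exceeds smallest subset size {smallest}")
    per_k = []
    for k in range(k_lo, k_hi + 1):
        cuts = [cut_tree(t, k) for t in trees]
        pair_vals = [disagreement(x, y) for x, y in combinations(cuts, 2)]
        per_k.append(float(np.mean(pair_vals)))
    return float(np.mean(per_k))


def dunn_index(distance: np.ndarray, labels: ClusterAssignment | np.ndarray) -> float:
    """Min between-cluster distance / max within-cluster diameter.

    Singleton clusters contribute diameter 0.  If every cluster is a
    singleton (or all diameters are 0) the index is unbounded and
    ``inf`` is returned with a warning; callers exclude it from
    averages.
    """
    y = labels.labels if isinstance(labels, ClusterAssignment) else np.asarray(labels, dtype=int)
    D = np.asarray(distance, dtype=float)
    n = y.size
    if D.shape != (n, n):
        raise ValueError("distance matrix and labels disagree on n")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("Dunn's index needs at least 2 classes")
    min_between = np.inf
    max_within = 0.0
    for ci in classes:
        mi = y == ci
        pts = np.flatnonzero(mi)
        if pts.size > 1:
            max_within = max(max_within, float(D[np.ix_(pts, pts)].max()))
        for cj in classes:
            if cj <= ci:
                continue
            mj = y == cj
            min_between = min(min_between, float(D[np.ix_(pts, np.flatnonzero(mj))].min()))
    if max_within == 0.0:
        warnings.warn("all cluster diameters are 0; Dunn's index unbounded", stacklevel=2)
        return float("inf")
    return min_between / max_within


def tune_eta(
    views: list[SimilarityView],
    eta_grid=DEFAULT_ETA_GRID,
    k_range: tuple[int, int] = (2, 15),
    config: FusionConfig | None = None,
    linkage: str = "average",
) -> StabilityReport:
    """Score every eta on the grid by leave-one-out stability.

    For each eta, each leave-one-out subset is fused (subset r with
    seed ``config.seed + r`` so replicates are independent yet
    reproducible), clustered on d = 1 - fused_S, and the forest scored
    by AMD and ADI.  Dunn values of all-singleton partitions are
    dropped from the ADI averages.
    """
    if config is None:
        config = FusionConfig()
    eta_grid = sorted(float(e) for e in eta_grid)
    if not eta_grid:
        raise ValueError("eta grid must be nonempty")
    ids = views[0].compound_ids
    subsets = loo_subsets(ids)
    k_lo, k_hi = k_range
    if k_hi > len(ids) - 1:
        raise ValueError(f"k_range {k_range} exceeds subset size {len(ids) - 1}")

    amd_vals, adi_means, adi_vars = [], [], []
    for eta in eta_grid:
        trees, dists = [], []
        for r, subset in enumerate(subsets):
            sub_views = [v.restrict(subset) for v in views]
            cfg = FusionConfig(
                eta=eta,
                k=config.k,
                max_outer=config.max_outer,
                max_em=config.max_em,
                tol_objective=config.tol_objective,
                tol_alpha=config.tol_alpha,
                seed=config.seed + r,
                n_restarts=config.n_restarts,
            )
            res = fuse(sub_views, cfg)
            D = to_distance(res.fused_S)
            trees.append(hierarchical_cluster(D, res.compound_ids, linkage=linkage))
            dists.append(D)
        amd_vals.append(amd(trees, k_range))
        per_k = []
        for k in range(k_lo, k_hi + 1):
            vals = []
            for tree, D in zip(trees, dists):
                v = dunn_index(D, cut_tree(tree, k))
                if np.isfinite(v):
                    vals.append(v)
            per_k.append(float(np.mean(vals)) if vals else np.nan)
        per_k = np.asarray(per_k)
        finite = per_k[np.isfinite(per_k)]
        adi_means.append(float(finite.mean()) if finite.size else np.nan)
        adi_vars.append(float(finite.var()) if finite.size else np.nan)

    amd_arr = np.asarray(amd_vals)
    adi_arr = np.asarray(adi_means)
    best_amd = np.nanmin(amd_arr)
    cand = np.flatnonzero(amd_arr <= best_amd + 1e-12)
    if cand.size > 1 and np.isfinite(adi_arr[cand]).any():
        rec = cand[int(np.nanargmax(adi_arr[cand]))]
    else:
        rec = int(cand[0])
    return StabilityReport(
        eta_grid=np.asarray(eta_grid),
        amd=amd_arr,
        adi_mean=adi_arr,
        adi_var=np.asarray(adi_vars),
        k_range=(k_lo, k_hi),
        n_subsets=len(subsets),
        recommended_eta=float(eta_grid[rec]),
    )
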