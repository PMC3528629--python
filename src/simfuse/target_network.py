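"""Compound-target network validation of a clustering.

The premise: compounds with similar features tend to share protein
targets, so the number of common targets inside a cluster measures the
quality of the similarity the clustering used.  The bipartite
compound-target graph is projected onto compounds (an edge links two
compounds sharing at least one target) and each cluster is scored by
the average within-cluster degree D = (1/n) sum_j D_j of its induced
subgraph.  Cutting a clustering tree over a range of class counts k and
averaging the score over classes yields a curve that can be compared
across similarity sources (fused vs single-view).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import pandas as pd

from .cluster_analysis import ClusteringTree, cut_tree
from .io_formats import BipartiteNetwork

__all__ = [
    "ProjectionGraph",
    "project_common_target",
    "average_degree",
    "common_target_curve",
    "compare_curves",
]


@dataclass
class ProjectionGraph:
    """Compound-compound graph; edge weight = number of shared targets."""

    compound_ids: list[str]
    graph: nx.Graph

    def shared_targets(self, a: str, b: str) -> int:
        if self.graph.has_edge(a, b):
            return self.graph.edges[a, b]["shared_targets"]
        return 0


def project_common_target(net: BipartiteNetwork) -> ProjectionGraph:
    """One-mode projection: drop target nodes, link co-binding compounds.

    Compounds with no shared target stay in the graph as isolated nodes.
    """
    g = nx.Graph()
    g.add_nodes_from(net.compound_ids)
    by_target: dict[str, list[str]] = {}
    for c, t in sorted(net.edges):
        by_target.setdefault(t, []).append(c)
    for members in by_target.values():
        for a, b in combinations(sorted(members), 2):
            if g.has_edge(a, b):
                g.edges[a, b]["shared_targets"] += 1
            else:
                g.add_edge(a, b, shared_targets=1)
    return ProjectionGraph(compound_ids=list(net.compound_ids), graph=g)


def average_degree(g: ProjectionGraph, members) -> float:
    """Mean degree over a compound subset, counting within-subset edges only.

    Over the full compound set this reduces to 2|E|/|V| (handshake
    identity); for a singleton it is 0.
    """
    members = [str(m) for m in members]
    if not members:
        raise ValueError("members must be nonempty")
    unknown = [m for m in members if m not in g.graph]
    if unknown:
        raise ValueError(f"unknown compound ids: {unknown}")
    sub = g.graph.subgraph(members)
    return sum(d for _, d in sub.degree()) / len(members)


def common_target_curve(
    tree: ClusteringTree, g: ProjectionGraph, k_range: range | list[int]
) -> pd.DataFrame:
    """Average-degree validity curve over class counts.

    For each k the tree is cut into k classes, each class scored by
    :func:`average_degree`, and the unweighted mean over classes
    reported.  Columns: ``k``, ``mean_average_degree``.
    """
    missing = [c for c in tree.leaf_ids if c not in g.graph]
    if missing:
        raise ValueError(f"tree leaves absent from projection graph: {missing}")
    rows = []
    for k in k_range:
        assign = cut_tree(tree, k)
        scores = []
        for label in range(1, k + 1):
            members = [c for c, y in zip(assign.compound_ids, assign.labels) if y == label]
            scores.append(average_degree(g, members))
        rows.append({"k": k, "mean_average_degree": sum(scores) / len(scores)})
    return pd.DataFrame(rows)


def compare_curves(
    trees: dict[str, ClusteringTree], g: ProjectionGraph, k_range: range | list[int]
) -> pd.DataFrame:
    """Side-by-side validity curves for several similarity sources.

    Returns a wide table with one ``k`` column and one column per tree
    (e.g. fused / bioactivity / structure), suitable for plotting the
    source-comparison figure.
    """
    out: pd.DataFrame | None = None
    for name, tree in trees.items():
        cur = common_target_curve(tree, g, k_range).rename(
            columns={"mean_average_degree": name}
        )
        out = cur if out is None else out.merge(cur, on="k")
    if out is None:
        raise ValueError("trees must be nonempty")
    return out
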