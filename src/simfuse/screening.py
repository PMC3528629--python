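"""Ligand-based virtual screening over a (fused) similarity matrix.

A query compound's neighbours are ranked by descending similarity; the
fused ranking can be juxtaposed with each single-view ranking and, when
a compound-target edge list is available, annotated with whether each
hit shares a target with the query.  Fused scores are the learned
convex combination of per-view similarities, so degenerate weights
(alpha = (1, 0)) reproduce the corresponding single-view ranking
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import BipartiteNetwork

SIMILARITY_FLAG_THRESHOLD = 0.5

__all__ = ["RankedList", "similarity_search", "compare_rankings"]


@dataclass
class RankedList:
    """Similarity-search result for one query under one source."""

    query: str
    source: str
    entries: pd.DataFrame  # columns: compound, similarity, rank

    def __post_init__(self) -> None:
        e = self.entries
        if list(e.columns) != ["compound", "similarity", "rank"]:
            raise ValueError("entries must have columns [compound, similarity, rank]")
        if (np.diff(e["similarity"].to_numpy()) > 1e-12).any():
            raise ValueError("similarities must be non-increasing")
        if list(e["rank"]) != list(range(1, len(e) + 1)):
            raise ValueError("ranks must be 1..m contiguous")
        if self.query in set(e["compound"]):
            raise ValueError("query must not appear among its own hits")

    def rank_of(self, compound: str) -> int:
        row = self.entries[self.entries["compound"] == compound]
        if row.empty:
            raise KeyError(compound)
        return int(row["rank"].iloc[0])


def similarity_search(S: pd.DataFrame, query: str, top: int | None = None,
                      source: str = "fused") -> RankedList:
    """Rank all other compounds by similarity to ``query``, descending.

    Ties are broken by lexicographic compound id (stable and
    documented); ranks are 1-based.  ``top`` truncates the list after
    ranking.
    """
    if query not in S.index:
        raise KeyError(f"query {query!r} not among compounds")
    sims = S.loc[query].drop(index=query)
    order = sorted(sims.index, key=lambda c: (-sims[c], str(c)))
    entries = pd.DataFrame(
        {
            "compound": order,
            "similarity": [float(sims[c]) for c in order],
            "rank": range(1, len(order) + 1),
        }
    )
    if top is not None:
        entries = entries.head(top)
    return RankedList(query=query, source=source, entries=entries)


def compare_rankings(
    fused: RankedList,
    views: dict[str, RankedList],
    annotations: BipartiteNetwork | None = None,
    threshold: float = SIMILARITY_FLAG_THRESHOLD,
) -> pd.DataFrame:
    """Per-compound rank/similarity table across sources.

    One row per compound with ``rank_fused``/``sim_fused`` plus a rank
    and similarity column per view, a flag for fused similarity above
    ``threshold`` (a reporting aid, not a filter), and — when a
    compound-target network is supplied — whether the compound shares a
    target with the query.
    """
    universe = list(fused.entries["compound"])
    for name, rl in views.items():
        if rl.query != fused.query:
            raise ValueError(f"view {name!r} ranks a different query")
        if set(rl.entries["compound"]) != set(universe):
            raise ValueError(f"view {name!r} covers a different compound universe")

    table = fused.entries.rename(columns={"rank": "rank_fused", "similarity": "sim_fused"})
    for name, rl in views.items():
        cols = rl.entries.rename(
            columns={"rank": f"rank_{name}", "similarity": f"sim_{name}"}
        )
        table = table.merge(cols, on="compound")
    table[f"above_{threshold:g}"] = table["sim_fused"] > threshold
    if annotations is not None:
        q_targets = annotations.targets_of(fused.query)
        table["shares_target_with_query"] = [
            bool(annotations.targets_of(c) & q_targets) for c in table["compound"]
        ]
    return table
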