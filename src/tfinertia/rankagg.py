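"""Rank-product aggregation of ranked lists and top-K consensus.

The rank product of an item over k lists is the geometric mean of its
ranks (1 = best); items are re-ranked by ascending rank product.  A small
rank product marks an item consistently near the top of every list.  The
consensus step reports items found in the top K of at least a minimum
number of per-comparison combined rankings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .exceptions import DataError


@dataclass
class RankProductResult:
    """Per-list ranks, rank products and the combined ordering."""

    item_ids: list[str]
    ranks: np.ndarray  # (n_items, k), average-rank convention for ties
    rank_products: np.ndarray  # geometric mean of ranks per item
    combined_order: list[str]  # ascending rank product, ties lexicographic

    def combined_rank(self, item_id: str) -> int:
        return self.combined_order.index(item_id) + 1

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.ranks,
            index=self.item_ids,
            columns=[f"rank_list{i + 1}" for i in range(self.ranks.shape[1])],
        )
        frame["rank_product"] = self.rank_products
        frame["combined_rank"] = [
            self.combined_order.index(i) + 1 for i in self.item_ids
        ]
        return frame.sort_values("combined_rank")


def _ranks_from_list(lst, items: list[str]) -> np.ndarray:
    """Extract ranks for one input list over a fixed item universe.

    Accepts either an ordered sequence of item ids (best first, no ties)
    or a mapping item -> score ranked descending (ties share their
    average rank).
    """
    if isinstance(lst, Mapping):
        if set(lst) != set(items):
            diff = set(lst) ^ set(items)
            raise DataError(f"item sets differ; symmetric difference {sorted(diff)}")
        scores = np.array([float(lst[i]) for i in items])
        return rankdata(-scores, method="average")
    seq = list(lst)
    if set(seq) != set(items) or len(seq) != len(items):
        diff = set(seq) ^ set(items)
        raise DataError(f"item sets differ; symmetric difference {sorted(diff)}")
    pos = {item: r for r, item in enumerate(seq, start=1)}
    return np.array([float(pos[i]) for i in items])


def rank_products(lists: Sequence) -> RankProductResult:
    """Combine k rankings of one item set by their rank product.

    Each element of ``lists`` is either an ordered sequence of item ids
    (best first) or a mapping from item id to score (higher = better).
    All lists must cover the identical item set.
    """
    if len(lists) < 1:
        raise DataError("rank_products requires at least one list")
    first = lists[0]
    items = sorted(first) if isinstance(first, Mapping) else sorted(first)
    ranks = np.column_stack([_ranks_from_list(lst, items) for lst in lists])
    k = ranks.shape[1]
    rp = np.exp(np.log(ranks).mean(axis=1))
    order = sorted(range(len(items)), key=lambda i: (rp[i], items[i]))
    return RankProductResult(
        item_ids=items,
        ranks=ranks,
        rank_products=rp,
        combined_order=[items[i] for i in order],
    )


def consensus_top(
    rankings: Mapping[str, Sequence[str]],
    top_k: int = 10,
    min_support: int | None = None,
) -> pd.DataFrame:
    """Items in the top ``top_k`` of at least ``min_support`` rankings.

    ``rankings`` maps a comparison name to its combined ordering (best
    first).  ``min_support`` defaults to the number of rankings (strict
    unanimity).  Returns a frame (item_id, support, mean_rank) ordered by
    support descending then mean rank ascending; the mean rank is taken
    over all rankings.
    """
    if top_k < 1:
        raise DataError("top_k must be >= 1")
    n_lists = len(rankings)
    if min_support is None:
        min_support = n_lists
    if not 1 <= min_support <= n_lists:
        raise DataError("min_support must be between 1 and the number of rankings")
    support: dict[str, int] = {}
    rank_sums: dict[str, float] = {}
    for order in rankings.values():
        order = list(order)
        for r, item in enumerate(order, start=1):
            rank_sums[item] = rank_sums.get(item, 0.0) + r
            if r <= top_k:
                support[item] = support.get(item, 0) + 1
    rows = [
        {
            "motif_id": item,
            "support": cnt,
            "mean_rank": rank_sums[item] / n_lists,
        }
        for item, cnt in support.items()
        if cnt >= min_support
    ]
    frame = pd.DataFrame(rows, columns=["motif_id", "support", "mean_rank"])
    return frame.sort_values(
        ["support", "mean_rank", "motif_id"], ascending=[False, True, True]
    ).reset_index(drop=True)
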