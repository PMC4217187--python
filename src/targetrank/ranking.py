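"""Fractional-rank normalization and hybrid rank-of-product aggregation.

Scores from heterogeneous evidence channels (genomic distance in bp, HiC
contact log-ratios, literature t-scores) are made comparable by converting
each list to fractional ranks: the item at sorted position ``i`` of an
``n``-item list receives rank ``i / (n + 1)``, so every rank lies strictly
inside (0, 1) regardless of list length. Tied scores share the mean of their
positions; items with no evidence (undefined scores) occupy a shared tie
block at the bottom of the list.

The hybrid rank of an item is the fractional rank of the product of its
per-channel fractional ranks (smaller product = better). Because ranks are
invariant under strictly increasing transforms, ranking by the product is
identical to ranking by the geometric mean of the channel ranks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Hashable, Mapping, Optional, Sequence

import numpy as np
from scipy.stats import rankdata

ASCENDING = "ascending_better"
DESCENDING = "descending_better"


def _is_undefined(score) -> bool:
    return score is None or (isinstance(score, float) and math.isnan(score))


@dataclass(frozen=True)
class RankedList:
    """Items with raw scores and their fractional ranks in (0, 1)."""

    items: tuple
    scores: tuple
    fractional_ranks: tuple
    direction: str

    def __post_init__(self) -> None:
        if not all(0.0 < r < 1.0 for r in self.fractional_ranks):
            raise ValueError("fractional ranks must lie strictly inside (0, 1)")

    def as_dict(self) -> dict:
        return dict(zip(self.items, self.fractional_ranks))

    def rank_of(self, item) -> float:
        return self.as_dict()[item]

    def __len__(self) -> int:
        return len(self.items)


def fractional_rank(
    scores: Sequence[float] | Mapping[Hashable, Optional[float]],
    direction: str = ASCENDING,
    items: Optional[Sequence[Hashable]] = None,
) -> RankedList:
    """Convert scores to fractional ranks ``i / (n + 1)``.

    ``direction`` states which end of the score scale is rank 1:
    ``ascending_better`` for distances (small is good), ``descending_better``
    for contact strengths and association scores. Undefined scores (``None``
    or NaN) are placed after every defined score and tied together; ties
    share the mean of their positions.
    """
    if isinstance(scores, Mapping):
        if items is not None:
            raise ValueError("pass items either as a mapping or separately, not both")
        items = list(scores.keys())
        scores = [scores[k] for k in items]
    else:
        scores = list(scores)
        items = list(items) if items is not None else list(range(len(scores)))
    if len(items) != len(scores):
        raise ValueError("items and scores differ in length")
    n = len(scores)
    if n == 0:
        raise ValueError("cannot rank an empty list")
    if direction not in (ASCENDING, DESCENDING):
        raise ValueError("unknown direction %r" % direction)

    defined = np.array([not _is_undefined(s) for s in scores], dtype=bool)
    vals = np.array([float(s) if d else 0.0 for s, d in zip(scores, defined)])
    if direction == DESCENDING:
        vals = -vals

    positions = np.empty(n, dtype=float)
    n_def = int(defined.sum())
    if n_def:
        positions[defined] = rankdata(vals[defined], method="average")
    if n_def < n:
        # undefined block occupies positions n_def+1 .. n, tie-averaged
        positions[~defined] = (n_def + 1 + n) / 2.0
    ranks = positions / (n + 1)
    return RankedList(tuple(items), tuple(scores), tuple(ranks), direction)


def hybrid_rank(rank_lists: Sequence[RankedList]) -> RankedList:
    """Aggregate 2 or 3 channel rankings over one item universe.

    Per item, the fractional ranks are multiplied and the products re-ranked
    ascending (a small product means the item is good in every channel).
    The result is order-invariant in the input lists and identical to
    ranking by the geometric mean of the channel ranks.
    """
    if len(rank_lists) < 2:
        raise ValueError("hybrid aggregation needs at least two rank lists")
    universe = set(rank_lists[0].items)
    for rl in rank_lists[1:]:
        if set(rl.items) != universe:
            raise ValueError("rank lists cover different item universes")
    items = list(rank_lists[0].items)
    maps = [rl.as_dict() for rl in rank_lists]
    products = [math.prod(m[it] for m in maps) for it in items]
    return fractional_rank(products, direction=ASCENDING, items=items)
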