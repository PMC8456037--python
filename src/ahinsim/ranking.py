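"""Ranking quality metrics for top-k retrieval: nDCG and half-life utility.

DCG discounts the relevance of the item at 1-based position i by
1/log2(i+1); nDCG divides by the DCG of the ideally (descending) ordered
list, so it lies in [0, 1] and equals 1 exactly when the list is already
sorted by true relevance.  Half-life utility models an exponentially
decaying probability that a user inspects position l::

    HL_u = sum_a max(r_ua - d, 0) / 2^((l_ua - 1) / (h - 1))

where r_ua is the true relevance of candidate a for query u, d a default
score subtracted before discounting (here the mean relevance of the
evaluated candidate pool, unless fixed), and h > 1 the half-life — the rank
at which inspection probability has halved.  Defaults k = 10, h = 3.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

from .search import RankedList

__all__ = [
    "HLParams",
    "dcg",
    "ndcg",
    "half_life_utility",
    "evaluate_topk",
    "EvalReport",
]


@dataclass(frozen=True)
class HLParams:
    """Half-life utility parameters: default score policy and half-life."""

    h: float = 3.0
    d: float | None = None  # None -> per-query mean of the candidate pool

    def __post_init__(self) -> None:
        if self.h <= 1:
            raise ValueError(f"half-life h must be > 1, got {self.h}")


def dcg(rel: Sequence[float]) -> float:
    """Discounted cumulative gain of an ordered relevance list."""
    if len(rel) == 0:
        warnings.warn("DCG of an empty list is 0", stacklevel=2)
        return 0.0
    if any(r < 0 for r in rel):
        raise ValueError("relevance values must be non-negative")
    return sum(r / math.log2(i + 1) for i, r in enumerate(rel, start=1))


def ndcg(rel: Sequence[float]) -> float:
    """Normalized DCG in [0, 1]; an all-zero list scores 0 (0/0 guarded)."""
    ideal = dcg(sorted(rel, reverse=True)) if len(rel) else 0.0
    if ideal == 0:
        return 0.0
    return dcg(rel) / ideal


def half_life_utility(
    items: Sequence[tuple[float, int]],
    params: HLParams = HLParams(),
) -> float:
    """Half-life utility of one query's ranked candidates.

    ``items`` are (true relevance r, 1-based rank l) pairs.  With
    ``params.d`` unset the default score is the mean relevance of the items
    in scope.
    """
    if any(l < 1 for _, l in items):
        raise ValueError("ranks are 1-based")
    if not items:
        return 0.0
    d = params.d if params.d is not None else sum(r for r, _ in items) / len(items)
    return sum(
        max(r - d, 0.0) / 2.0 ** ((l - 1) / (params.h - 1)) for r, l in items
    )


@dataclass(frozen=True)
class EvalReport:
    per_query: tuple[tuple[str, float, float], ...]  # (query, ndcg, hl)
    mean_ndcg: float
    mean_hl: float


def _relevance_fn(truth) -> Callable[[str, str], float]:
    if callable(getattr(truth, "relevance", None)):
        return truth.relevance
    if isinstance(truth, Mapping):
        return lambda q, c: float(truth.get((q, c), 0.0))
    raise TypeError("truth must be a mapping (q, c) -> r or expose .relevance")


def evaluate_topk(
    results: Mapping[str, RankedList],
    truth,
    params: HLParams = HLParams(),
) -> EvalReport:
    """Per-query and mean nDCG / HL for a batch of ranked lists.

    ``truth`` supplies the ground-truth relevance r(q, c); candidates
    missing from it count as relevance 0.  An empty result set yields zero
    metrics with a warning.
    """
    if not results:
        warnings.warn("empty result set; metrics are 0", stacklevel=2)
        return EvalReport(per_query=(), mean_ndcg=0.0, mean_hl=0.0)
    rel_of = _relevance_fn(truth)
    rows = []
    for query in sorted(results):
        ranked = results[query]
        rels = [rel_of(query, cand) for cand, _ in ranked.entries]
        nd = ndcg(rels) if rels else 0.0
        hl = half_life_utility(
            [(r, pos) for pos, r in enumerate(rels, start=1)], params
        )
        rows.append((query, nd, hl))
    mean_ndcg = sum(r[1] for r in rows) / len(rows)
    mean_hl = sum(r[2] for r in rows) / len(rows)
    return EvalReport(per_query=tuple(rows), mean_ndcg=mean_ndcg, mean_hl=mean_hl)
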