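"""Overlap of top-k gene sets from two rankings + hypergeometric test.

Two ranking methods run on the same gene universe each nominate a top-k
set; the question is whether their intersection is larger than chance.
Significance is the over-enrichment upper tail P(X >= k) of
Hypergeometric(N, K, n) — drawing ``n`` genes without replacement from a
universe of ``N`` of which ``K`` are in the other set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .mrmr import RankedFeatureList

__all__ = ["OverlapReport", "hypergeom_tail", "overlap_report"]


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail p-value P(X >= k), X ~ Hypergeometric(N, K, n)."""
    N, K, n, k = int(N), int(K), int(n), int(k)
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"set sizes K={K}, n={n} must lie within N={N}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"overlap k={k} must lie in [0, min(K={K}, n={n})]")
    return float(hypergeom.sf(k - 1, N, K, n))


@dataclass
class OverlapReport:
    size_a: int
    size_b: int
    universe: int
    intersection: list[str]
    p_value: float

    @property
    def overlap(self) -> int:
        return len(self.intersection)

    def to_dict(self) -> dict:
        return {
            "size_a": self.size_a,
            "size_b": self.size_b,
            "universe": self.universe,
            "overlap": self.overlap,
            "p_value": self.p_value,
            "intersection": self.intersection,
        }


def overlap_report(list_a: RankedFeatureList, top_a: int,
                   list_b: RankedFeatureList, top_b: int,
                   universe: int) -> OverlapReport:
    """Intersect the two top prefixes and score the overlap.

    Both lists must rank the same gene universe; the intersection is
    reported in ``list_a`` order.
    """
    if top_a > len(list_a) or top_b > len(list_b):
        raise ValueError("top-k exceeds ranked list length")
    if set(list_a.gene_ids) != set(list_b.gene_ids):
        raise ValueError("the two rankings cover different gene universes")
    set_b = set(list_b.gene_ids[:top_b])
    inter = [g for g in list_a.gene_ids[:top_a] if g in set_b]
    p = hypergeom_tail(universe, top_a, top_b, len(inter))
    return OverlapReport(size_a=top_a, size_b=top_b, universe=universe,
                         intersection=inter, p_value=p)
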