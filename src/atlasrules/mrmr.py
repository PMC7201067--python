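"""Greedy minimum-redundancy-maximum-relevance (mRMR) feature ranking.

The difference (MID) form: the first gene maximises MI to the tissue
label; each subsequent step appends the candidate maximising

    MI(candidate, labels) - mean_{s in selected} MI(candidate, s)

All MI values follow the :mod:`atlasrules.mi_filter` conventions
(equal-frequency discretisation of both variables, plug-in estimate,
log base 2).  Ties go to the lower original column index, so the
ranking is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import ExpressionDataset
from .mi_filter import _mi_bits, discretize

__all__ = ["RankedFeatureList", "rank_mrmr"]


@dataclass
class RankedFeatureList:
    """Ordered gene columns with their selection-time scores."""

    indices: np.ndarray      # dataset column indices, best first
    gene_ids: list[str]
    scores: np.ndarray       # score at selection time (method-specific)
    method: str              # 'mRMR' or 'MCFS'

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.intp)
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if len(np.unique(self.indices)) != self.indices.size:
            raise ValueError("ranked indices must be unique")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("ranked scores must be finite")

    def __len__(self) -> int:
        return int(self.indices.size)

    def top(self, k: int) -> np.ndarray:
        return self.indices[:k]

    def top_gene_ids(self, k: int) -> list[str]:
        return self.gene_ids[:k]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self) + 1),
                "gene_id": self.gene_ids,
                "score": self.scores,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, ds: ExpressionDataset,
                   method: str) -> "RankedFeatureList":
        pos = {g: i for i, g in enumerate(ds.gene_ids)}
        idx = np.array([pos[g] for g in df["gene_id"]], dtype=np.intp)
        return cls(idx, list(df["gene_id"]), df["score"].to_numpy(), method)


def rank_mrmr(ds: ExpressionDataset, features=None,
              bins: int = 5) -> RankedFeatureList:
    """Rank candidate columns by the greedy MID criterion."""
    if len(set(ds.labels)) < 2:
        raise ValueError("need at least 2 classes")
    if features is None:
        features = np.arange(ds.n_genes)
    features = np.asarray(features, dtype=np.intp)
    d = features.size
    if d < 1:
        raise ValueError("empty candidate set")

    y = ds.y
    codes = [discretize(ds.matrix[:, f], bins) for f in features]
    relevance = np.array([_mi_bits(c, y) for c in codes])

    selected: list[int] = []           # positions within `features`
    sel_scores: list[float] = []
    remaining = np.arange(d)
    red_sum = np.zeros(d)              # sum of MI(candidate, selected)

    while remaining.size:
        if not selected:
            score = relevance[remaining]
        else:
            score = relevance[remaining] - red_sum[remaining] / len(selected)
        best = np.flatnonzero(score == score.max())
        # tie-break: lowest original column index
        pick_pos = remaining[best[np.argmin(features[remaining[best]])]]
        selected.append(int(pick_pos))
        sel_scores.append(float(score[np.searchsorted(remaining, pick_pos)]))
        remaining = remaining[remaining != pick_pos]
        if remaining.size:
            picked_codes = codes[pick_pos]
            for r in remaining:
                red_sum[r] += _mi_bits(codes[r], picked_codes)

    order = np.asarray(selected, dtype=np.intp)
    return RankedFeatureList(
        indices=features[order],
        gene_ids=[ds.gene_ids[f] for f in features[order]],
        scores=np.asarray(sel_scores),
        method="mRMR",
    )
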