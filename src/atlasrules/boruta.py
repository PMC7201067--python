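"""Boruta all-relevant feature selection by shadow-feature comparison.

Each iteration appends a shadow copy of every candidate gene (its values
independently permuted over cells, destroying the association with the
label while preserving the marginal), fits a random-forest importance on
the combined real+shadow block, and credits a "hit" to every real gene
whose mean-impurity-decrease importance exceeds the maximum shadow
importance.  All genes and their shadows stay in the design matrix for
the whole run, so the shadow-max bar a gene must clear never drops as
other genes get rejected.  Undecided genes are resolved by binomial tests of their hit
count against Binomial(iterations, 1/2) at level ``alpha``: the upper
tail confirms, the lower tail rejects.  Because the test is re-run at
every iteration over many genes, p-values are corrected the way the
method's reference implementation does by default: Benjamini-Hochberg
across the currently undecided genes combined with a Bonferroni
``alpha / iteration`` bound over the sequential looks.  The loop stops
when nothing is tentative or ``max_iter`` is reached; leftovers stay
tentative and are conservatively treated as not selected downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom
from sklearn.ensemble import RandomForestClassifier

from .data_model import ExpressionDataset

__all__ = ["BorutaResult", "zscore", "run_boruta"]


def zscore(importances) -> float:
    """Mean importance divided by its standard error, ``mean/(sd/sqrt(n))``.

    Degenerate spread (sd = 0) maps to +inf, 0 or -inf by the sign of the
    mean.
    """
    imp = np.asarray(importances, dtype=np.float64)
    if imp.size < 2:
        raise ValueError("need at least 2 importance scores")
    mean = imp.mean()
    sd = imp.std(ddof=1)
    if sd == 0.0:
        return float(np.inf) if mean > 0 else (float(-np.inf) if mean < 0 else 0.0)
    return float(mean / (sd / np.sqrt(imp.size)))


def _bh_significant(pvals: np.ndarray, mask: np.ndarray,
                    alpha: float) -> np.ndarray:
    """Benjamini-Hochberg rejections among ``mask`` entries, as a mask."""
    idx = np.flatnonzero(mask)
    p = pvals[idx]
    m = p.size
    order = np.argsort(p)
    thresh = alpha * (np.arange(1, m + 1) / m)
    passed = p[order] <= thresh
    out = np.zeros_like(mask)
    if passed.any():
        k = int(np.max(np.flatnonzero(passed)))
        out[idx[order[: k + 1]]] = True
    return out


@dataclass
class BorutaResult:
    """Per-feature Boruta verdicts over the candidate set."""

    feature_indices: np.ndarray     # candidate columns, in input order
    status: np.ndarray              # 'confirmed' | 'rejected' | 'tentative'
    hits: np.ndarray
    n_iter: int
    shadow_max_trace: np.ndarray    # per-iteration max shadow importance

    @property
    def confirmed(self) -> np.ndarray:
        return self.feature_indices[self.status == "confirmed"]

    @property
    def rejected(self) -> np.ndarray:
        return self.feature_indices[self.status == "rejected"]

    @property
    def tentative(self) -> np.ndarray:
        return self.feature_indices[self.status == "tentative"]

    def to_frame(self, gene_ids) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [gene_ids[i] for i in self.feature_indices],
                "status": self.status,
                "hits": self.hits,
                "iterations": self.n_iter,
            }
        )


def run_boruta(ds: ExpressionDataset, features=None, max_iter: int = 100,
               alpha: float = 0.05, seed: int = 0,
               n_estimators: int = 100,
               class_weight: str | None = "balanced") -> BorutaResult:
    """Run the shadow-comparison loop on the given candidate columns.

    ``features`` defaults to all genes.  The internal forest is
    class-balanced by default: with tissue sizes spanning an order of
    magnitude, unweighted impurity decreases are dominated by the large
    classes and markers of small tissues cannot accumulate enough
    importance to clear the shadow bar.  Fully reproducible from
    ``seed`` (per-iteration permutations and forest seeds flow from one
    generator).
    """
    if max_iter < 5:
        raise ValueError("max_iter < 5: the binomial test has no resolution")
    if len(set(ds.labels)) < 2:
        raise ValueError("need at least 2 classes")
    if features is None:
        features = np.arange(ds.n_genes)
    features = np.asarray(features, dtype=np.intp)
    if features.size < 1:
        raise ValueError("need at least 1 candidate feature")

    X = ds.matrix[:, features]
    y = ds.y
    n, d = X.shape
    rng = np.random.default_rng(seed)

    hits = np.zeros(d, dtype=np.intp)
    status = np.full(d, "tentative", dtype=object)
    active = np.ones(d, dtype=bool)
    trace: list[float] = []
    it = 0
    for it in range(1, max_iter + 1):
        # independent permutation of every column; all features keep their
        # shadows for the whole run so the shadow-max bar never drops
        order = np.argsort(rng.random(X.shape), axis=0)
        shadow = np.take_along_axis(X, order, axis=0)
        rf = RandomForestClassifier(
            n_estimators=n_estimators,
            class_weight=class_weight,
            random_state=int(rng.integers(2**31)),
        )
        rf.fit(np.hstack([X, shadow]), y)
        imp = rf.feature_importances_
        shadow_max = float(imp[d:].max())
        trace.append(shadow_max)
        hits += imp[:d] > shadow_max

        if it >= 5 and active.any():
            p_hi = binom.sf(hits - 1, it, 0.5)   # P[X >= hits]
            p_lo = binom.cdf(hits, it, 0.5)      # P[X <= hits]
            confirm = active & _bh_significant(p_hi, active, alpha) \
                & (p_hi <= alpha / it)
            reject = active & _bh_significant(p_lo, active, alpha) \
                & (p_lo <= alpha / it)
            status[confirm] = "confirmed"
            status[reject & ~confirm] = "rejected"
            active &= ~(confirm | reject)
        if not active.any():
            break

    return BorutaResult(
        feature_indices=features,
        status=np.asarray(status, dtype=object),
        hits=hits,
        n_iter=it,
        shadow_max_trace=np.asarray(trace),
    )
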