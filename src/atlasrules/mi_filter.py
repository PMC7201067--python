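"""Mutual-information screening of genes against the tissue label.

Each gene's expression is discretised into at most ``bins``
equal-frequency intervals (rank-based, so the score is invariant under
any strictly monotone transform of the values) and the plug-in MI
estimate with log base 2 is computed from the joint empirical frequency
table, with the usual 0*log0 = 0 convention.  Genes whose MI to the
label strictly exceeds a threshold (0.02 bits by default) survive the
screen; gene order is never changed, only filtered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import mutual_info_score

from .data_model import ExpressionDataset

__all__ = ["MIResult", "discretize", "estimate_mi", "mi_screen"]

_LN2 = float(np.log(2.0))


def discretize(values, bins: int) -> np.ndarray:
    """Equal-frequency bin codes for a 1-D array (<= ``bins`` bins).

    Quantile edges depend only on ranks; tied values always fall in the
    same bin.  A constant vector maps to a single bin.
    """
    values = np.asarray(values, dtype=np.float64)
    if bins < 1:
        raise ValueError("bins must be >= 1")
    if values.size == 0 or np.all(values == values[0]) or bins == 1:
        return np.zeros(values.shape, dtype=np.intp)
    codes = pd.qcut(values, bins, labels=False, duplicates="drop")
    return np.asarray(codes, dtype=np.intp)


def _mi_bits(a: np.ndarray, b: np.ndarray) -> float:
    return float(mutual_info_score(a, b)) / _LN2


def estimate_mi(values, labels, bins: int = 5) -> float:
    """Plug-in MI (bits) between one gene's expression and the labels."""
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels)
    if values.shape[0] != labels.shape[0]:
        raise ValueError(
            f"values ({values.shape[0]}) and labels ({labels.shape[0]}) "
            "differ in length"
        )
    if values.shape[0] < 2:
        raise ValueError("need at least 2 cells")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    return _mi_bits(discretize(values, bins), labels)


@dataclass
class MIResult:
    """Per-gene MI scores and the surviving gene set of a screen."""

    scores: np.ndarray          # MI in bits, one per gene of the dataset
    bins: int
    threshold: float
    surviving: np.ndarray       # column indices with score > threshold
    warning: str | None = None

    def to_frame(self, gene_ids) -> pd.DataFrame:
        passed = np.zeros(len(self.scores), dtype=bool)
        passed[self.surviving] = True
        return pd.DataFrame(
            {"gene_id": gene_ids, "mi_bits": self.scores, "passed": passed}
        )


def mi_screen(ds: ExpressionDataset, threshold: float = 0.02,
              bins: int = 5) -> MIResult:
    """Score every gene with :func:`estimate_mi` and keep MI > threshold.

    An empty survivor set is reported with a warning, not an error.
    """
    y = ds.y
    scores = np.empty(ds.n_genes)
    for j in range(ds.n_genes):
        scores[j] = _mi_bits(discretize(ds.matrix[:, j], bins), y)
    surviving = np.flatnonzero(scores > threshold)
    warning = None
    if surviving.size == 0:
        warning = (
            f"no gene exceeded the MI threshold {threshold}; "
            "downstream selection has nothing to rank"
        )
    return MIResult(scores=scores, bins=bins, threshold=threshold,
                    surviving=surviving, warning=warning)
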