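"""Incremental feature selection with cross-validated multiclass MCC.

Given a ranked gene list, classifiers are evaluated on growing top-k
prefixes (k = step, 2*step, ...) with stratified k-fold cross-validation;
the optimum is the smallest k attaining the maximal Matthews correlation
coefficient.  The multiclass MCC is the correlation form

    (N * sum_k C_kk - sum_k t_k p_k)
    / sqrt((N^2 - sum_k p_k^2) (N^2 - sum_k t_k^2))

with t_k / p_k the true / predicted class totals of the pooled
out-of-fold confusion matrix; it reduces to the classic binary formula
at two classes and is defined as 0 when either variance term vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .data_model import ExpressionDataset, FeatureSubsetView, subset_features
from .mrmr import RankedFeatureList

__all__ = [
    "ConfusionMatrix",
    "ClassifierSpec",
    "CVResult",
    "IFSCurve",
    "multiclass_mcc",
    "cross_validate",
    "run_ifs",
]


@dataclass
class ConfusionMatrix:
    """C x C counts; rows = true class, columns = predicted class.

    Class order is the dataset's ``class_names`` order.
    """

    counts: np.ndarray
    class_names: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def overall_accuracy(self) -> float:
        return float(np.trace(self.counts) / self.n)

    @property
    def per_class_accuracy(self) -> np.ndarray:
        """Recall per class; NaN for classes with no true instances."""
        totals = self.counts.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(totals > 0, np.diag(self.counts) / totals, np.nan)


def multiclass_mcc(cm) -> float:
    """Correlation-form multiclass MCC of a confusion matrix, in [-1, 1]."""
    C = cm.counts if isinstance(cm, ConfusionMatrix) else np.asarray(cm)
    C = C.astype(np.float64)
    N = C.sum()
    if N == 0:
        raise ValueError("empty confusion matrix")
    t = C.sum(axis=1)        # true totals
    p = C.sum(axis=0)        # predicted totals
    cov = N * np.trace(C) - t @ p
    var_t = N * N - (t @ t)
    var_p = N * N - (p @ p)
    if var_t <= 0 or var_p <= 0:
        return 0.0
    return float(cov / np.sqrt(var_t * var_p))


@dataclass
class ClassifierSpec:
    """Which supervised classifier IFS evaluates, and with what knobs.

    ``kind='random_forest'`` uses 100 trees and sqrt(d) features per
    split (library defaults); ``kind='part'`` plugs in the PART rule
    learner.
    """

    kind: str = "random_forest"
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("random_forest", "part"):
            raise ValueError(f"unsupported classifier kind {self.kind!r}")

    def build(self):
        if self.kind == "random_forest":
            kwargs = {"n_estimators": 100, "random_state": self.seed}
            kwargs.update(self.params)
            return RandomForestClassifier(**kwargs)
        from .part_rules import PartClassifier

        return PartClassifier(**self.params)


@dataclass
class CVResult:
    confusion: ConfusionMatrix
    per_class_accuracy: np.ndarray
    overall_accuracy: float
    mcc: float


def cross_validate(ds_view, spec: ClassifierSpec, folds: int = 10,
                   seed: int = 0) -> CVResult:
    """Stratified k-fold CV; every cell predicted once while held out.

    Metrics come from the pooled out-of-fold confusion matrix.
    """
    X = np.asarray(ds_view.matrix, dtype=np.float64)
    y = ds_view.y
    class_names = list(ds_view.class_names)
    C = len(class_names)
    counts = np.bincount(y, minlength=C)
    present = counts > 0
    if present.sum() < 2:
        raise ValueError("need at least 2 classes for cross-validation")
    small = np.flatnonzero(present & (counts < folds))
    if small.size:
        raise ValueError(
            f"class {class_names[small[0]]!r} has only {counts[small[0]]} "
            f"cells (< {folds} folds); reduce the fold count"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    cm = np.zeros((C, C), dtype=np.int64)
    for train_idx, test_idx in skf.split(X, y):
        clf = spec.build()
        clf.fit(X[train_idx], y[train_idx])
        pred = np.asarray(clf.predict(X[test_idx]), dtype=np.intp)
        np.add.at(cm, (y[test_idx], pred), 1)
    confusion = ConfusionMatrix(cm, class_names)
    return CVResult(
        confusion=confusion,
        per_class_accuracy=confusion.per_class_accuracy,
        overall_accuracy=confusion.overall_accuracy,
        mcc=multiclass_mcc(confusion),
    )


@dataclass
class IFSCurve:
    """One row per evaluated prefix size k, plus the optimum."""

    ks: np.ndarray
    mccs: np.ndarray
    overall_accs: np.ndarray
    per_class_accs: np.ndarray       # len(ks) x C
    class_names: list[str]
    method: str                      # ranking method tag
    classifier: str

    @property
    def optimum_index(self) -> int:
        return pick_optimum(self.mccs)

    @property
    def optimum_k(self) -> int:
        return int(self.ks[self.optimum_index])

    @property
    def optimum_mcc(self) -> float:
        return float(self.mccs[self.optimum_index])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"k": self.ks, "mcc": self.mccs,
                           "overall_acc": self.overall_accs})
        for i, c in enumerate(self.class_names):
            df[f"acc_{c}"] = self.per_class_accs[:, i]
        return df


def pick_optimum(mccs) -> int:
    """Index of the maximal MCC; ties resolved to the smallest k."""
    mccs = np.asarray(mccs)
    return int(np.argmax(mccs))       # argmax returns the first maximum


def run_ifs(ds: ExpressionDataset, ranked: RankedFeatureList,
            spec: ClassifierSpec, step: int = 5, max_k: int | None = None,
            folds: int = 10, seed: int = 0) -> IFSCurve:
    """Evaluate k = step, 2*step, ... <= max_k on top-k prefixes."""
    if step < 1:
        raise ValueError("step must be >= 1")
    if max_k is None:
        max_k = len(ranked)
    if max_k > len(ranked):
        raise ValueError(f"max_k={max_k} exceeds ranked list length {len(ranked)}")
    ks = np.arange(step, max_k + 1, step, dtype=int)
    if ks.size == 0:
        raise ValueError("no prefix sizes to evaluate (max_k < step)")
    mccs, accs, per_class = [], [], []
    for k in ks:
        view = subset_features(ds, ranked.top(int(k)))
        res = cross_validate(view, spec, folds=folds, seed=seed)
        mccs.append(res.mcc)
        accs.append(res.overall_accuracy)
        per_class.append(res.per_class_accuracy)
    return IFSCurve(
        ks=ks,
        mccs=np.asarray(mccs),
        overall_accs=np.asarray(accs),
        per_class_accs=np.asarray(per_class),
        class_names=list(ds.class_names),
        method=ranked.method,
        classifier=spec.kind,
    )
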