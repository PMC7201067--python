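"""Monte Carlo feature selection (MCFS) via many small decision trees.

``m`` stratified bootstrap resamples of the cells and ``t`` uniform
random ``s``-gene subsets are drawn; one entropy decision tree is grown
per (bootstrap, subset) pair, ``m*t`` trees in total.  Each tree
contributes to the relative importance of every gene it splits on:

    RI_f = sum over trees tau, nodes n splitting on f of
           wAcc(tau)^u * IG(n) * (samples at n / samples in tau)^v

where ``wAcc`` is the tree's weighted (balanced) accuracy on its
out-of-bag cells and ``IG`` the information gain of the node.  Genes are
ranked by decreasing RI, ties broken by column index.  ``u = v = 1`` by
default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .data_model import ExpressionDataset
from .mrmr import RankedFeatureList

__all__ = ["MCFSParams", "TreeAccount", "ri_contribution", "run_mcfs"]


@dataclass
class MCFSParams:
    """Knobs of the Monte-Carlo tree ensemble.

    ``s`` defaults to ``ceil(sqrt(d))`` at run time when left as None.
    ``wacc`` is 'balanced' (mean per-class recall, robust to the atlas's
    class imbalance) or 'plain'.
    """

    m: int = 30
    t: int = 50
    s: int | None = None
    u: float = 1.0
    v: float = 1.0
    seed: int = 0
    wacc: str = "balanced"
    min_leaf: int = 2

    def __post_init__(self) -> None:
        if self.m < 1 or self.t < 1:
            raise ValueError("m and t must be >= 1")
        if self.s is not None and self.s < 1:
            raise ValueError("s must be >= 1")
        if self.wacc not in ("balanced", "plain"):
            raise ValueError("wacc must be 'balanced' or 'plain'")


@dataclass
class TreeAccount:
    """What one tree contributes to RI: its wAcc and per-node records."""

    wacc: float
    nodes: list[tuple[int, float, int]]   # (feature column, IG, samples at node)
    n_tree: int                           # samples the tree was grown on

    def __post_init__(self) -> None:
        if not 0.0 <= self.wacc <= 1.0:
            raise ValueError("wacc must lie in [0, 1]")
        for f, ig, n_node in self.nodes:
            if ig < 0:
                raise ValueError("information gain must be >= 0")
            if n_node > self.n_tree:
                raise ValueError("node sample count exceeds tree sample count")


def ri_contribution(account: TreeAccount, feature: int,
                    params: MCFSParams) -> float:
    """One tree's term of RI_f; 0 if the feature splits no node."""
    total = 0.0
    for f, ig, n_node in account.nodes:
        if f == feature:
            total += (account.wacc ** params.u) * ig * (
                (n_node / account.n_tree) ** params.v
            )
    return total


def _balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean per-class recall over the classes present in y_true."""
    recalls = []
    for c in np.unique(y_true):
        mask = y_true == c
        recalls.append(float(np.mean(y_pred[mask] == c)))
    return float(np.mean(recalls)) if recalls else 0.0


def _tree_account(clf: DecisionTreeClassifier, subset: np.ndarray,
                  n_tree: int, wacc: float) -> TreeAccount:
    t = clf.tree_
    nodes: list[tuple[int, float, int]] = []
    for node in range(t.node_count):
        left, right = t.children_left[node], t.children_right[node]
        if left == -1:
            continue
        n = t.n_node_samples[node]
        ig = t.impurity[node] - (
            t.n_node_samples[left] * t.impurity[left]
            + t.n_node_samples[right] * t.impurity[right]
        ) / n
        nodes.append((int(subset[t.feature[node]]), max(float(ig), 0.0), int(n)))
    return TreeAccount(wacc=wacc, nodes=nodes, n_tree=n_tree)


def run_mcfs(ds: ExpressionDataset, features=None,
             params: MCFSParams | None = None,
             return_accounts: bool = False):
    """Grow the ``m*t`` trees and rank candidate genes by RI.

    Bootstraps are drawn with replacement stratified by class so every
    tree sees all classes; wAcc is evaluated on the bootstrap's
    out-of-bag cells.  Returns a :class:`RankedFeatureList` (method tag
    'MCFS'), plus the list of :class:`TreeAccount` when
    ``return_accounts`` is set.
    """
    params = params or MCFSParams()
    if len(set(ds.labels)) < 2:
        raise ValueError("need at least 2 classes")
    if features is None:
        features = np.arange(ds.n_genes)
    features = np.asarray(features, dtype=np.intp)
    d = features.size
    s = params.s if params.s is not None else max(1, math.ceil(math.sqrt(d)))
    if s > d:
        raise ValueError(f"s={s} exceeds the {d} candidate features")

    rng = np.random.default_rng(params.seed)
    X = ds.matrix
    y = ds.y
    n = X.shape[0]
    class_rows = [np.flatnonzero(y == c) for c in range(len(ds.class_names))]

    bootstraps = []
    for _ in range(params.m):
        rows = np.concatenate(
            [rng.choice(rows_c, size=rows_c.size, replace=True)
             for rows_c in class_rows]
        )
        bootstraps.append(rows)
    subsets = [rng.choice(features, size=s, replace=False)
               for _ in range(params.t)]

    ri = np.zeros(ds.n_genes)
    accounts: list[TreeAccount] = []
    for rows in bootstraps:
        oob = np.setdiff1d(np.arange(n), rows)
        for subset in subsets:
            clf = DecisionTreeClassifier(
                criterion="entropy",
                min_samples_leaf=params.min_leaf,
                random_state=int(rng.integers(2**31)),
            )
            clf.fit(X[np.ix_(rows, subset)], y[rows])
            if oob.size:
                pred = clf.predict(X[np.ix_(oob, subset)])
                if params.wacc == "balanced":
                    wacc = _balanced_accuracy(y[oob], pred)
                else:
                    wacc = float(np.mean(pred == y[oob]))
            else:
                wacc = 0.0
            account = _tree_account(clf, subset, rows.size,
                                    min(max(wacc, 0.0), 1.0))
            if return_accounts:
                accounts.append(account)
            w = account.wacc ** params.u
            for f, ig, n_node in account.nodes:
                ri[f] += w * ig * ((n_node / account.n_tree) ** params.v)

    cand_ri = ri[features]
    order = np.lexsort((features, -cand_ri))
    ranked = RankedFeatureList(
        indices=features[order],
        gene_ids=[ds.gene_ids[f] for f in features[order]],
        scores=cand_ri[order],
        method="MCFS",
    )
    if return_accounts:
        return ranked, accounts
    return ranked
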