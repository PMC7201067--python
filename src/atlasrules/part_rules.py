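"""PART rule induction: partial C4.5 trees + separate-and-conquer.

A rule set is learned by repeatedly growing a *partial* decision tree on
the not-yet-covered training cells, extracting the single best rule
(the path from the root to the leaf covering the most residual cells)
and removing the cells that rule matches, until every cell is covered.
A condition-free default rule predicting the global majority class is
appended last, so the rule set is total.

Partial trees follow C4.5 conventions: binary splits on numeric genes at
midpoints between adjacent sorted values, chosen by gain ratio; at every
node the lower-entropy child subset is expanded first; when all children
of a node are leaves the node is replaced by a leaf if the pessimistic
error estimate (binomial upper confidence limit at confidence
``prune_cf``) does not worsen, and tree growth stops entirely at the
first failed prune — hence "partial".  The learner is deterministic
given the data.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import betaincinv

__all__ = [
    "Condition",
    "Rule",
    "RuleSet",
    "RuleCapError",
    "build_partial_tree",
    "train_part",
    "predict_ruleset",
    "export_rules",
    "import_rules",
    "PartClassifier",
]


class RuleCapError(RuntimeError):
    """Raised when rule induction exceeds the configured rule cap."""


@dataclass(frozen=True)
class Condition:
    """One conjunct: ``gene <= threshold`` or ``gene > threshold``."""

    gene: str
    op: str          # '<=' or '>'
    threshold: float

    def __post_init__(self) -> None:
        if self.op not in ("<=", ">"):
            raise ValueError(f"unsupported operator {self.op!r}")

    def __str__(self) -> str:
        return f"{self.gene} {self.op} {self.threshold:g}"


@dataclass
class Rule:
    """Conjunction of gene-threshold conditions -> predicted tissue."""

    conditions: tuple[Condition, ...]
    klass: str
    coverage: int = 0
    correct: int = 0

    def matches(self, vector: dict[str, float]) -> bool:
        for c in self.conditions:
            try:
                v = vector[c.gene]
            except KeyError:
                raise KeyError(f"missing expression value for gene {c.gene!r}")
            if c.op == "<=" and not v <= c.threshold:
                return False
            if c.op == ">" and not v > c.threshold:
                return False
        return True

    def __str__(self) -> str:
        cond = " AND ".join(str(c) for c in self.conditions) or "TRUE"
        return f"IF {cond} THEN {self.klass} ({self.coverage}/{self.correct})"


@dataclass
class RuleSet:
    """Ordered rules ending in a condition-free default rule."""

    rules: list[Rule]            # last rule has no conditions (default)
    gene_ids: list[str]          # genes of the training view, in order

    def __post_init__(self) -> None:
        if not self.rules or self.rules[-1].conditions:
            raise ValueError("a RuleSet must end with a condition-free default rule")

    @property
    def default_class(self) -> str:
        return self.rules[-1].klass

    def __len__(self) -> int:
        return len(self.rules)


# ----------------------------------------------------------------------
# partial C4.5 tree
# ----------------------------------------------------------------------

def _entropy_bits(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def _pessimistic_errors(n: int, e: int, cf: float) -> float:
    """C4.5-style pessimistic error count: n times the binomial upper
    confidence limit of e errors in n trials at confidence cf."""
    if n == 0:
        return 0.0
    if e >= n:
        return float(n)
    # solve P(X <= e | p) = cf for p
    p = 1.0 - float(betaincinv(n - e, e + 1, cf))
    return n * p


def _best_split(X: np.ndarray, y: np.ndarray, n_classes: int, min_leaf: int):
    """Gain-ratio-optimal (feature, midpoint threshold) over all columns.

    Returns None when no split with positive gain leaves >= min_leaf
    samples on each side.  Ties prefer the lower feature index, then the
    lower threshold.
    """
    n, d = X.shape
    if n < 2 * min_leaf:
        return None
    from scipy.special import xlogy

    order = np.argsort(X, axis=0, kind="stable")
    Xs = np.take_along_axis(X, order, axis=0)             # n x d sorted values
    ys = y[order]                                         # n x d class codes

    # Entropies in count form (natural log; the gain/split-info ratio is
    # base-independent): size*H = size*ln(size) - sum_c c*ln(c).  The
    # left-side sum_c c*ln(c) changes by F[k] = k ln k - (k-1) ln (k-1)
    # when the k-th element of a class crosses the split, so it is a
    # cumulative sum of table lookups — no class dimension needed.
    ks = np.arange(n + 1, dtype=np.float64)
    xk = xlogy(ks, ks)
    F = np.empty(n + 1)
    F[0] = 0.0
    F[1:] = xk[1:] - xk[:-1]

    # occurrence index of each element within its class, per column
    order2 = np.argsort(ys, axis=0, kind="stable")        # groups classes
    pos = np.arange(n)[:, None]
    ys2 = np.take_along_axis(ys, order2, axis=0)
    newgrp = np.empty((n, d), dtype=bool)
    newgrp[0] = True
    newgrp[1:] = ys2[1:] != ys2[:-1]
    starts = np.maximum.accumulate(np.where(newgrp, pos, 0), axis=0)
    occ = np.empty((n, d), dtype=np.intp)
    np.put_along_axis(occ, order2, pos - starts + 1, axis=0)

    class_totals = np.bincount(y, minlength=n_classes)
    rev_occ = class_totals[ys] - occ + 1                  # occurrence from right

    xl_l = np.cumsum(F[occ], axis=0)[:-1]                 # left = first i rows
    xl_r = np.cumsum(F[rev_occ][::-1], axis=0)[::-1][1:]  # right = rest

    sizes_l = np.arange(1, n, dtype=np.float64)
    sizes_r = n - sizes_l
    nHp = n * np.log(n) - xk[class_totals].sum()          # n * parent entropy
    slogl = xk[1:n, None]                                 # i*ln(i)
    slogr = xk[n - 1:0:-1, None]
    gain = (nHp - (slogl - xl_l) - (slogr - xl_r)) / n
    split_info = np.log(n) - (slogl + slogr) / n

    valid = (Xs[1:] > Xs[:-1]) \
        & (sizes_l[:, None] >= min_leaf) & (sizes_r[:, None] >= min_leaf) \
        & (gain > 1e-9)
    if not valid.any():
        return None
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(valid, gain / split_info, -np.inf)
    # column-major flatten: scan feature 0 thresholds ascending, then 1, ...
    flat = np.argmax(ratio.T)           # first occurrence of the max
    j, i = divmod(int(flat), n - 1)
    thr = float((Xs[i, j] + Xs[i + 1, j]) / 2.0)
    return j, thr


@dataclass(eq=False)
class _Leaf:
    seq: int
    idx: np.ndarray                  # residual-set positions at this leaf
    conditions: tuple
    klass: int
    n: int
    errors: int
    is_leaf: bool = True


@dataclass
class _Internal:
    is_leaf: bool = False


class _PartialTree:
    """Grows one partial tree and remembers its leaves in creation order."""

    def __init__(self, X, y, n_classes, prune_cf, min_leaf):
        self.X, self.y = X, y
        self.n_classes = n_classes
        self.prune_cf = prune_cf
        self.min_leaf = min_leaf
        self.leaves: list[_Leaf] = []
        self.stop = False
        self._seq = 0

    def _make_leaf(self, idx, conditions) -> _Leaf:
        counts = np.bincount(self.y[idx], minlength=self.n_classes)
        klass = int(np.argmax(counts))        # tie -> smallest class code
        leaf = _Leaf(self._seq, idx, conditions, klass,
                     int(idx.size), int(idx.size - counts[klass]))
        self._seq += 1
        self.leaves.append(leaf)
        return leaf

    def expand(self, idx: np.ndarray, conditions: tuple):
        y_sub = self.y[idx]
        counts = np.bincount(y_sub, minlength=self.n_classes)
        if (counts > 0).sum() <= 1 or idx.size < 2 * self.min_leaf:
            return self._make_leaf(idx, conditions)
        split = _best_split(self.X[idx], y_sub, self.n_classes, self.min_leaf)
        if split is None:
            return self._make_leaf(idx, conditions)
        j, thr = split
        le_mask = self.X[idx, j] <= thr
        children = [
            (idx[le_mask], conditions + ((j, "<=", thr),)),
            (idx[~le_mask], conditions + ((j, ">", thr),)),
        ]
        # expand the lower-entropy subset first
        ent = [_entropy_bits(np.bincount(self.y[c_idx], minlength=self.n_classes))
               for c_idx, _ in children]
        order = [0, 1] if ent[0] <= ent[1] else [1, 0]
        results: dict[int, object] = {}
        for side in order:
            if self.stop:
                results[side] = _Internal()   # left unexpanded
            else:
                results[side] = self.expand(*children[side])
        if all(isinstance(r, _Leaf) for r in results.values()):
            # backtracking: try to replace this node by a leaf
            e_children = sum(
                _pessimistic_errors(r.n, r.errors, self.prune_cf)
                for r in results.values()
            )
            maj = int(np.argmax(counts))
            e_leaf = _pessimistic_errors(idx.size, int(idx.size - counts[maj]),
                                         self.prune_cf)
            if e_leaf <= e_children:
                for r in results.values():
                    self.leaves.remove(r)
                return self._make_leaf(idx, conditions)
            self.stop = True
        return _Internal()


def build_partial_tree(X, y, prune_cf: float = 0.25, min_leaf: int = 2,
                       class_names=None, gene_ids=None):
    """Grow one partial tree and extract its best single rule.

    Returns ``(rule, matched_indices)`` where ``matched_indices`` are the
    row positions (into ``X``) the rule matches — exactly the rows at the
    chosen leaf.  The chosen leaf is the one covering the most rows, ties
    resolved by expansion order.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.intp)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("need a non-empty 2-D instance matrix")
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y differ in length")
    n_classes = int(y.max()) + 1 if y.size else 1
    if class_names is None:
        class_names = [str(c) for c in range(n_classes)]
    n_classes = max(n_classes, len(class_names))
    if gene_ids is None:
        gene_ids = [f"f{j}" for j in range(X.shape[1])]

    tree = _PartialTree(X, y, n_classes, prune_cf, min_leaf)
    tree.expand(np.arange(X.shape[0]), ())
    best = max(tree.leaves, key=lambda l: (l.n, -l.seq))
    conds = tuple(
        Condition(gene_ids[j], op, thr) for j, op, thr in best.conditions
    )
    rule = Rule(conditions=conds, klass=str(class_names[best.klass]),
                coverage=best.n, correct=best.n - best.errors)
    return rule, best.idx


# ----------------------------------------------------------------------
# separate-and-conquer training and prediction
# ----------------------------------------------------------------------

def _as_arrays(ds_view):
    """Accept a FeatureSubsetView/ExpressionDataset or an (X, y) pair."""
    X = np.asarray(ds_view.matrix, dtype=np.float64)
    y = ds_view.y
    return X, y, list(ds_view.class_names), list(ds_view.gene_ids)


def _rule_mask(rule: Rule, X: np.ndarray, gene_pos: dict[str, int]) -> np.ndarray:
    mask = np.ones(X.shape[0], dtype=bool)
    for c in rule.conditions:
        if c.gene not in gene_pos:
            raise KeyError(f"missing expression value for gene {c.gene!r}")
        col = X[:, gene_pos[c.gene]]
        mask &= (col <= c.threshold) if c.op == "<=" else (col > c.threshold)
    return mask


def train_part(ds_view, prune_cf: float = 0.25, min_leaf: int = 2,
               seed: int = 0, max_rules: int = 20000) -> RuleSet:
    """Learn an ordered rule set by separate-and-conquer.

    ``seed`` is accepted for interface uniformity only: PART is
    deterministic given the data.  Per-rule coverage/correct counts are
    recorded by a first-match replay over the *full* training view.
    """
    X, y, class_names, gene_ids = _as_arrays(ds_view)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes in the training view")
    n = X.shape[0]
    residual = np.arange(n)
    rules: list[Rule] = []
    while residual.size:
        rule, matched = build_partial_tree(
            X[residual], y[residual], prune_cf=prune_cf, min_leaf=min_leaf,
            class_names=class_names, gene_ids=gene_ids,
        )
        rules.append(rule)
        if len(rules) > max_rules:
            raise RuleCapError(
                f"rule induction exceeded the cap of {max_rules} rules"
            )
        keep = np.ones(residual.size, dtype=bool)
        keep[matched] = False
        residual = residual[keep]
    counts = np.bincount(y, minlength=len(class_names))
    default = Rule(conditions=(), klass=class_names[int(np.argmax(counts))])
    rules.append(default)
    rs = RuleSet(rules=rules, gene_ids=gene_ids)
    _replay_counts(rs, X, y, class_names)
    return rs


def _replay_counts(rs: RuleSet, X: np.ndarray, y: np.ndarray,
                   class_names: list[str]) -> None:
    """First-match replay on the training set to fill coverage/correct."""
    gene_pos = {g: i for i, g in enumerate(rs.gene_ids)}
    code = {c: i for i, c in enumerate(class_names)}
    remaining = np.ones(X.shape[0], dtype=bool)
    for rule in rs.rules:
        m = _rule_mask(rule, X, gene_pos) & remaining
        rule.coverage = int(m.sum())
        rule.correct = int((y[m] == code[rule.klass]).sum())
        remaining &= ~m


def predict_ruleset(rs: RuleSet, cell) -> str:
    """Predict one cell: the first satisfied rule wins (default is total).

    ``cell`` is either a mapping gene id -> value or a vector over the
    rule set's ``gene_ids``.
    """
    if isinstance(cell, dict):
        vector = cell
    else:
        cell = np.asarray(cell, dtype=np.float64)
        if cell.shape[0] != len(rs.gene_ids):
            raise ValueError(
                f"vector covers {cell.shape[0]} genes; rule set expects "
                f"{len(rs.gene_ids)}"
            )
        vector = dict(zip(rs.gene_ids, cell))
    for rule in rs.rules:
        if rule.matches(vector):
            return rule.klass
    raise AssertionError("unreachable: default rule is total")


def predict_matrix(rs: RuleSet, X: np.ndarray) -> np.ndarray:
    """Vectorised first-match prediction for a matrix over rs.gene_ids."""
    X = np.asarray(X, dtype=np.float64)
    gene_pos = {g: i for i, g in enumerate(rs.gene_ids)}
    out = np.empty(X.shape[0], dtype=object)
    remaining = np.ones(X.shape[0], dtype=bool)
    for rule in rs.rules:
        if not remaining.any():
            break
        m = _rule_mask(rule, X, gene_pos) & remaining
        out[m] = rule.klass
        remaining &= ~m
    return out


# ----------------------------------------------------------------------
# serialisation
# ----------------------------------------------------------------------

def export_rules(rs: RuleSet, path) -> str:
    """Write human-readable rules plus a machine-readable JSON twin.

    The text file has one ``IF ... THEN tissue (coverage/correct)`` line
    per rule; the JSON twin (``<path>.json``) round-trips exactly via
    :func:`import_rules`.
    """
    path = str(path)
    d = os.path.dirname(path)
    if d:
        os.makedirs(d, exist_ok=True)
    with open(path, "w") as fh:
        for rule in rs.rules:
            fh.write(str(rule) + "\n")
    payload = {
        "gene_ids": rs.gene_ids,
        "rules": [
            {
                "conditions": [
                    {"gene": c.gene, "op": c.op, "thr": c.threshold}
                    for c in r.conditions
                ],
                "class": r.klass,
                "coverage": r.coverage,
                "correct": r.correct,
            }
            for r in rs.rules
        ],
    }
    with open(path + ".json", "w") as fh:
        json.dump(payload, fh, indent=1)
    return path


def import_rules(json_path) -> RuleSet:
    with open(json_path) as fh:
        payload = json.load(fh)
    rules = [
        Rule(
            conditions=tuple(
                Condition(c["gene"], c["op"], float(c["thr"]))
                for c in r["conditions"]
            ),
            klass=r["class"],
            coverage=int(r["coverage"]),
            correct=int(r["correct"]),
        )
        for r in payload["rules"]
    ]
    return RuleSet(rules=rules, gene_ids=list(payload["gene_ids"]))


# ----------------------------------------------------------------------
# sklearn-style wrapper so PART plugs into the IFS evaluator
# ----------------------------------------------------------------------

class PartClassifier:
    """Minimal fit/predict wrapper around :func:`train_part`."""

    def __init__(self, prune_cf: float = 0.25, min_leaf: int = 2,
                 max_rules: int = 20000, random_state: int | None = None):
        self.prune_cf = prune_cf
        self.min_leaf = min_leaf
        self.max_rules = max_rules
        self.random_state = random_state   # accepted, unused: PART is deterministic

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        self.classes_, y_codes = np.unique(y, return_inverse=True)

        class _View:
            matrix = X
            gene_ids = [f"f{j}" for j in range(X.shape[1])]

        view = _View()
        view.y = y_codes
        view.class_names = [str(c) for c in self.classes_]
        self.ruleset_ = train_part(view, prune_cf=self.prune_cf,
                                   min_leaf=self.min_leaf,
                                   max_rules=self.max_rules)
        self._code = {str(c): c for c in self.classes_}
        return self

    def predict(self, X):
        labels = predict_matrix(self.ruleset_, np.asarray(X, dtype=np.float64))
        return np.asarray([self._code[l] for l in labels])
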