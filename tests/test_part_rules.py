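import numpy as np
import pytest

import atlasrules as ar
from atlasrules.part_rules import (
    Condition,
    PartClassifier,
    Rule,
    RuleCapError,
    RuleSet,
    build_partial_tree,
    export_rules,
    import_rules,
    predict_matrix,
    predict_ruleset,
    train_part,
)


class _View:
    """Minimal stand-in for a FeatureSubsetView over plain arrays."""

    def __init__(self, X, y, class_names, gene_ids=None):
        self.matrix = np.asarray(X, dtype=float)
        self.y = np.asarray(y)
        self.class_names = class_names
        self.gene_ids = gene_ids or [f"g{j}" for j in range(self.matrix.shape[1])]


class TestBuildPartialTree:
    def test_pure_instances_give_default_style_rule(self):
        rule, matched = build_partial_tree(
            np.array([[1.0], [2.0]]), np.array([0, 0]), class_names=["A", "B"])
        assert rule.conditions == ()
        assert rule.klass == "A"
        assert list(matched) == [0, 1]

    def test_four_point_split_at_midpoint(self):
        rule, matched = build_partial_tree(
            np.array([[1.0], [2.0], [8.0], [9.0]]), np.array([0, 0, 1, 1]),
            class_names=["A", "B"], gene_ids=["gene"])
        assert len(rule.conditions) == 1
        cond = rule.conditions[0]
        assert cond.threshold == pytest.approx(5.0)
        assert rule.coverage == 2
        assert {("<=", "A"), (">", "B")} >= {(cond.op, rule.klass)}

    def test_min_leaf_forces_majority_leaf(self):
        rule, matched = build_partial_tree(
            np.array([[1.0], [9.0], [2.0]]), np.array([0, 1, 0]),
            min_leaf=5, class_names=["A", "B"])
        assert rule.conditions == ()
        assert rule.klass == "A"
        assert len(matched) == 3

    def test_empty_instances_rejected(self):
        with pytest.raises(ValueError):
            build_partial_tree(np.zeros((0, 2)), np.array([], dtype=int))


def _separable_3class():
    X = np.concatenate([np.linspace(0, 1, 20), np.linspace(4, 5, 20),
                        np.linspace(8, 9, 20)])[:, None]
    y = np.repeat([0, 1, 2], 20)
    return _View(X, y, ["A", "B", "C"], ["gene"])


class TestTrainPart:
    def test_separable_classes_few_rules_full_accuracy(self):
        rs = train_part(_separable_3class())
        non_default = [r for r in rs.rules[:-1]]
        assert len(non_default) <= 3
        correct = sum(r.correct for r in rs.rules)
        assert correct == 60

    def test_coverage_conservation(self):
        """First-match coverages over all rules sum to the training size."""
        rng = np.random.default_rng(0)
        X = rng.random((80, 4))
        y = rng.integers(0, 3, 80)
        rs = train_part(_View(X, y, ["A", "B", "C"]))
        assert sum(r.coverage for r in rs.rules) == 80

    def test_replay_reproduces_stored_counts(self):
        rng = np.random.default_rng(1)
        X = rng.random((60, 3))
        y = rng.integers(0, 2, 60)
        view = _View(X, y, ["A", "B"])
        rs = train_part(view)
        # independent first-match replay
        code = {"A": 0, "B": 1}
        remaining = np.ones(60, dtype=bool)
        for rule in rs.rules:
            m = np.array([
                remaining[i] and rule.matches(dict(zip(view.gene_ids, X[i])))
                for i in range(60)
            ])
            assert int(m.sum()) == rule.coverage
            assert int((y[m] == code[rule.klass]).sum()) == rule.correct
            remaining &= ~m

    def test_termination_covers_everything(self):
        rng = np.random.default_rng(2)
        X = rng.random((50, 2))
        y = rng.integers(0, 3, 50)
        rs = train_part(_View(X, y, ["A", "B", "C"]))
        assert len(rs.rules) <= 51
        preds = predict_matrix(rs, X)
        assert not any(p is None for p in preds)

    def test_single_class_view_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            train_part(_View(np.random.rand(10, 2), np.zeros(10, int), ["A"]))

    def test_rule_cap_enforced(self):
        rng = np.random.default_rng(3)
        X = rng.random((40, 2))
        y = rng.integers(0, 2, 40)
        with pytest.raises(RuleCapError):
            train_part(_View(X, y, ["A", "B"]), max_rules=1)


class TestPredict:
    def test_default_only_ruleset_predicts_default(self):
        rs = RuleSet([Rule((), "A")], gene_ids=["g"])
        assert predict_ruleset(rs, {"g": 99.0}) == "A"

    def test_first_match_semantics(self):
        rs = RuleSet([
            Rule((Condition("g1", ">", 2.0),), "B"),
            Rule((), "A"),
        ], gene_ids=["g1"])
        assert predict_ruleset(rs, {"g1": 3.0}) == "B"
        assert predict_ruleset(rs, {"g1": 1.0}) == "A"
        assert predict_ruleset(rs, np.array([3.0])) == "B"

    def test_missing_gene_named_in_error(self):
        rs = RuleSet([
            Rule((Condition("Lgals7", ">", 2.5),), "Skin"),
            Rule((), "Fat"),
        ], gene_ids=["Lgals7"])
        with pytest.raises(KeyError, match="Lgals7"):
            predict_ruleset(rs, {"other": 1.0})

    def test_training_predictions_match_rule_counts(self):
        view = _separable_3class()
        rs = train_part(view)
        preds = predict_matrix(rs, view.matrix)
        total_correct = sum(r.correct for r in rs.rules)
        code = {c: i for i, c in enumerate(view.class_names)}
        assert sum(code[p] == t for p, t in zip(preds, view.y)) == total_correct


class TestExportImport:
    def test_round_trip_identity(self, tmp_path):
        rng = np.random.default_rng(4)
        X = rng.random((50, 3)) * 4
        y = rng.integers(0, 2, 50)
        rs = train_part(_View(X, y, ["Liver", "Lung"]))
        path = export_rules(rs, tmp_path / "rules.txt")
        back = import_rules(str(path) + ".json")
        assert back.gene_ids == rs.gene_ids
        assert len(back.rules) == len(rs.rules)
        for a, b in zip(rs.rules, back.rules):
            assert a.conditions == b.conditions
            assert (a.klass, a.coverage, a.correct) == \
                (b.klass, b.coverage, b.correct)

    def test_default_only_ruleset_is_single_line(self, tmp_path):
        rs = RuleSet([Rule((), "A", 5, 5)], gene_ids=[])
        path = export_rules(rs, tmp_path / "r.txt")
        assert open(path).read().count("\n") == 1

    def test_rule_text_format(self, tmp_path):
        rs = RuleSet([
            Rule((Condition("Lgals7", ">", 2.5),), "Skin", 10, 9),
            Rule((), "Fat", 2, 1),
        ], gene_ids=["Lgals7"])
        path = export_rules(rs, tmp_path / "r.txt")
        text = open(path).read()
        assert "Lgals7 > 2.5" in text
        assert "THEN Skin (10/9)" in text


class TestPartClassifier:
    def test_fit_predict_on_separable_data(self):
        view = _separable_3class()
        clf = PartClassifier().fit(view.matrix, view.y)
        assert np.array_equal(clf.predict(view.matrix), view.y)

    def test_works_inside_cross_validation(self, small_synth):
        ds, _ = small_synth
        view = ar.subset_features(ds, np.arange(10))
        res = ar.cross_validate(view, ar.ClassifierSpec(kind="part"),
                                folds=5, seed=0)
        assert -1.0 <= res.mcc <= 1.0
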