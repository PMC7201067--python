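import numpy as np
import pytest
from hypothesis import given, strategies as st
from sklearn.metrics import matthews_corrcoef

import atlasrules as ar
from atlasrules.ifs_eval import (
    ClassifierSpec,
    ConfusionMatrix,
    cross_validate,
    multiclass_mcc,
    pick_optimum,
    run_ifs,
)


def _cm_to_labels(cm):
    """Expand a confusion matrix into (y_true, y_pred) label vectors."""
    yt, yp = [], []
    for i in range(cm.shape[0]):
        for j in range(cm.shape[1]):
            yt.extend([i] * cm[i, j])
            yp.extend([j] * cm[i, j])
    return np.array(yt), np.array(yp)


class TestMulticlassMcc:
    def test_perfect_prediction(self):
        assert multiclass_mcc(np.diag([7, 3, 11])) == pytest.approx(1.0)

    def test_single_column_prediction_is_zero(self):
        assert multiclass_mcc(np.array([[5, 0], [3, 0]])) == 0.0

    def test_binary_case_equals_classic_formula(self):
        cm = np.array([[50, 10], [5, 35]])
        tp, fn, fp, tn = 50, 10, 5, 35
        classic = (tp * tn - fp * fn) / np.sqrt(
            (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        assert multiclass_mcc(cm) == pytest.approx(classic)

    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50),
           st.integers(0, 50))
    def test_random_binary_matrices_match_classic_formula(self, tp, fn, fp, tn):
        cm = np.array([[tp, fn], [fp, tn]])
        if cm.sum() == 0:
            return
        denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        classic = 0.0 if denom == 0 else \
            (tp * tn - fp * fn) / np.sqrt(denom)
        assert multiclass_mcc(cm) == pytest.approx(classic, abs=1e-12)

    @given(st.integers(0, 8))
    def test_agrees_with_library_rk_statistic(self, seed):
        rng = np.random.default_rng(seed)
        C = rng.integers(2, 6)
        cm = rng.integers(0, 20, size=(C, C))
        yt, yp = _cm_to_labels(cm)
        if len(np.unique(yt)) < 2:
            return
        assert multiclass_mcc(cm) == pytest.approx(
            matthews_corrcoef(yt, yp), abs=1e-12)

    @given(st.integers(0, 10))
    def test_invariant_under_class_permutation(self, seed):
        rng = np.random.default_rng(seed)
        C = rng.integers(2, 7)
        cm = rng.integers(0, 30, size=(C, C))
        if cm.sum() == 0:
            return
        perm = rng.permutation(C)
        assert multiclass_mcc(cm[np.ix_(perm, perm)]) == pytest.approx(
            multiclass_mcc(cm), abs=1e-12)

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            multiclass_mcc(np.zeros((3, 3)))


class TestConfusionMatrix:
    def test_accuracy_identities(self):
        cm = ConfusionMatrix(np.array([[8, 2], [1, 9]]), ["A", "B"])
        assert cm.overall_accuracy == pytest.approx(17 / 20)
        per = cm.per_class_accuracy
        sizes = cm.counts.sum(axis=1)
        assert np.dot(per, sizes) / sizes.sum() == pytest.approx(
            cm.overall_accuracy)


def _label_copy_dataset(seed=0, n=150, n_classes=3):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, n_classes, n)
    X = np.column_stack([y.astype(float), rng.normal(size=(n, 3))]) + 5
    return ar.ExpressionDataset(X, [f"g{j}" for j in range(4)],
                                [f"c{i}" for i in range(n)],
                                [str(v) for v in y])


class TestCrossValidate:
    def test_separable_by_one_feature(self):
        ds = _label_copy_dataset()
        res = cross_validate(ar.subset_features(ds, [0, 1, 2, 3]),
                             ClassifierSpec(seed=0), folds=10, seed=4)
        assert res.mcc == pytest.approx(1.0)
        assert np.all(res.per_class_accuracy == 1.0)

    def test_deterministic_given_seed(self):
        ds = _label_copy_dataset(seed=1)
        view = ar.subset_features(ds, [1, 2, 3])
        r1 = cross_validate(view, ClassifierSpec(seed=0), folds=5, seed=4)
        r2 = cross_validate(view, ClassifierSpec(seed=0), folds=5, seed=4)
        assert np.array_equal(r1.confusion.counts, r2.confusion.counts)

    def test_null_labels_mcc_near_zero(self):
        """Shuffled labels: mean CV MCC within 0.1 of 0 across seeds."""
        rng = np.random.default_rng(7)
        n = 200
        X = np.abs(rng.normal(size=(n, 10)))
        y = rng.permutation(np.repeat(["A", "B"], n // 2))
        ds = ar.ExpressionDataset(X, [f"g{j}" for j in range(10)],
                                  [f"c{i}" for i in range(n)], list(y))
        view = ar.subset_features(ds, np.arange(10))
        mccs = [cross_validate(view, ClassifierSpec(seed=s, params={
            "n_estimators": 50}), folds=5, seed=s).mcc for s in range(5)]
        assert abs(np.mean(mccs)) < 0.1

    def test_small_class_error_names_fold_reduction(self):
        ds = _label_copy_dataset(n=25)
        with pytest.raises(ValueError, match="fold"):
            cross_validate(ar.subset_features(ds, [0]), ClassifierSpec(),
                           folds=20, seed=0)

    def test_confusion_total_counts_every_cell_once(self):
        ds = _label_copy_dataset(seed=2)
        res = cross_validate(ar.subset_features(ds, [0, 1]),
                             ClassifierSpec(seed=0), folds=5, seed=1)
        assert res.confusion.n == ds.n_cells


class TestRunIfs:
    def test_grid_arithmetic(self):
        ds = _label_copy_dataset(seed=3)
        ranked = ar.rank_mrmr(ds)
        curve = run_ifs(ds, ranked, ClassifierSpec(seed=0), step=1, max_k=4,
                        folds=5, seed=0)
        assert list(curve.ks) == [1, 2, 3, 4]

    def test_tie_break_prefers_smallest_k(self):
        assert pick_optimum([0.5, 0.9, 0.9, 0.7]) == 1

    def test_optimum_at_saturation_is_first_saturating_k(self):
        ds = _label_copy_dataset(seed=4)
        ranked = ar.rank_mrmr(ds)          # label copy ranks first
        curve = run_ifs(ds, ranked, ClassifierSpec(seed=0), step=1, max_k=4,
                        folds=5, seed=0)
        assert curve.optimum_k == 1
        assert curve.optimum_mcc == pytest.approx(1.0)

    def test_endpoint_equals_direct_cross_validation(self):
        ds = _label_copy_dataset(seed=5)
        ranked = ar.rank_mrmr(ds)
        curve = run_ifs(ds, ranked, ClassifierSpec(seed=2), step=4, max_k=4,
                        folds=5, seed=3)
        direct = cross_validate(ar.subset_features(ds, ranked.top(4)),
                                ClassifierSpec(seed=2), folds=5, seed=3)
        assert curve.mccs[-1] == pytest.approx(direct.mcc)

    def test_bad_step_rejected(self):
        ds = _label_copy_dataset()
        ranked = ar.rank_mrmr(ds)
        with pytest.raises(ValueError, match="step"):
            run_ifs(ds, ranked, ClassifierSpec(), step=0, max_k=4)
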