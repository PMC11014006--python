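"""Partitioning, cross-validation structure, model bank, metric identities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hfwave as hw
from hfwave.classify import (ConfusionMatrix, confusion_from_predictions,
                             rank_auc, stratified_fold_assignment)
from hfwave.errors import InvalidParameterError
from hfwave.features import ALL_FEATURES, FeatureMatrix


def labeled_matrix(n_hf, n_control, p=3, seed=0, separation=0.0):
    rng = np.random.default_rng(seed)
    n = n_hf + n_control
    y = np.array(["HF"] * n_hf + ["control"] * n_control)
    X = rng.uniform(0, 1, size=(n, p))
    if separation > 0:
        X[y == "HF", 0] += separation
        X = np.clip(X, 0, 1 + separation) / (1 + separation)
    ids = [f"s{i:04d}" for i in range(n)]
    names = ALL_FEATURES[:p]
    return FeatureMatrix(pd.DataFrame(X, index=ids, columns=names),
                         pd.Series(y, index=ids), "minmax",
                         {c: (0.0, 1.0) for c in names})


class TestPartition:
    def test_study_sized_split(self):
        m = labeled_matrix(682, 954)
        train, test = hw.partition(m, 0.75, seed=0, stratified=True)
        assert (train.n_subjects, test.n_subjects) == (1227, 409)

    def test_tiny_split(self):
        m = labeled_matrix(2, 2)
        train, test = hw.partition(m, 0.75, seed=0, stratified=False)
        assert (train.n_subjects, test.n_subjects) == (3, 1)

    def test_disjoint_and_exhaustive(self):
        m = labeled_matrix(30, 40)
        train, test = hw.partition(m, 0.75, seed=5)
        train_ids = set(train.data.index)
        test_ids = set(test.data.index)
        assert train_ids | test_ids == set(m.data.index)
        assert train_ids & test_ids == set()

    def test_stratification_preserves_proportions(self):
        m = labeled_matrix(200, 300)
        train, _ = hw.partition(m, 0.75, seed=1, stratified=True)
        frac_hf = (train.labels == "HF").mean()
        assert frac_hf == pytest.approx(0.4, abs=0.01)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(InvalidParameterError):
            hw.partition(labeled_matrix(5, 5), 1.5, seed=0)


class TestCrossvalidate:
    def test_fold_sizes_for_study_training_set(self):
        y = pd.Series(["HF"] * 512 + ["control"] * 715)
        assignment = stratified_fold_assignment(y, 10, seed=0)
        sizes = sorted(np.bincount(assignment, minlength=10))
        assert sizes == [122, 122, 122, 123, 123, 123, 123, 123, 123, 123]
        assert sum(sizes) == 1227

    def test_leave_one_out_degenerate(self):
        y = pd.Series(["HF"] * 4 + ["control"] * 4)
        assignment = stratified_fold_assignment(y, 8, seed=0)
        assert sorted(np.bincount(assignment, minlength=8)) == [1] * 8

    def test_same_seed_same_assignment(self):
        y = pd.Series(["HF"] * 50 + ["control"] * 70)
        a = stratified_fold_assignment(y, 10, seed=3)
        b = stratified_fold_assignment(y, 10, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_class_smaller_than_folds_rejected(self):
        m = labeled_matrix(5, 50)
        with pytest.raises(InvalidParameterError):
            hw.crossvalidate(m, "Decision Tree", folds=10, seed=0)

    def test_folds_cover_training_data(self):
        m = labeled_matrix(30, 40, separation=0.5)
        reports = hw.crossvalidate(m, "Decision Tree", folds=5, seed=0)
        assert len(reports) == 5
        assert sum(r["n_val"] for r in reports) == 70


class TestFitPredict:
    @pytest.mark.parametrize("model", sorted(hw.MODEL_FAMILIES))
    def test_separable_data_perfectly_classified(self, model):
        m = labeled_matrix(40, 40, p=1, separation=2.0)
        train, test = hw.partition(m, 0.75, seed=0)
        pred, scores = hw.fit_predict(train, test, model, seed=0)
        y = (test.labels == "HF").astype(int).to_numpy()
        assert np.array_equal(pred, y)
        assert scores.shape == pred.shape

    def test_label_permutation_gives_chance_accuracy(self):
        m = labeled_matrix(200, 200, p=3, separation=1.0, seed=4)
        rng = np.random.default_rng(9)
        shuffled = pd.Series(rng.permutation(m.labels.to_numpy()),
                             index=m.labels.index)
        m_null = FeatureMatrix(m.data, shuffled, "minmax", m.column_ranges)
        train, test = hw.partition(m_null, 0.75, seed=0)
        pred, _ = hw.fit_predict(train, test, "Decision Tree", seed=0)
        y = (test.labels == "HF").astype(int).to_numpy()
        acc = np.mean(pred == y)
        assert 0.4 <= acc <= 0.6  # 99% binomial band around chance at n=100

    def test_deterministic_given_seed(self):
        m = labeled_matrix(50, 50, separation=0.3, seed=2)
        train, test = hw.partition(m, 0.75, seed=1)
        for model in ("Random Forest", "MLP", "BayesNet"):
            p1, s1 = hw.fit_predict(train, test, model, seed=11)
            p2, s2 = hw.fit_predict(train, test, model, seed=11)
            np.testing.assert_array_equal(p1, p2)
            np.testing.assert_array_equal(s1, s2)

    def test_unknown_model_lists_supported(self):
        m = labeled_matrix(10, 10)
        train, test = hw.partition(m, 0.75, seed=0)
        with pytest.raises(InvalidParameterError, match="SVM"):
            hw.fit_predict(train, test, "Perceptron2000", seed=0)


class TestComputeMetrics:
    def test_perfect_confusion(self):
        metrics = hw.compute_metrics(ConfusionMatrix(tp=1, tn=1, fp=0, fn=0))
        assert metrics["accuracy"] == 1.0

    def test_sensitivity_from_counts(self):
        metrics = hw.compute_metrics(ConfusionMatrix(tp=90, tn=0, fp=0, fn=10))
        assert metrics["sensitivity"] == pytest.approx(0.9)

    def test_f1_equals_p_when_precision_equals_recall(self):
        metrics = hw.compute_metrics(ConfusionMatrix(tp=30, tn=50, fp=10, fn=10))
        assert metrics["precision"] == metrics["sensitivity"] == pytest.approx(0.75)
        assert metrics["f1"] == pytest.approx(0.75)

    def test_undefined_ratio_is_missing_not_zero(self):
        metrics = hw.compute_metrics(ConfusionMatrix(tp=0, tn=5, fp=0, fn=0))
        assert np.isnan(metrics["sensitivity"])
        assert np.isnan(metrics["precision"])

    def test_negative_counts_rejected(self):
        with pytest.raises(InvalidParameterError):
            ConfusionMatrix(tp=-1, tn=1, fp=0, fn=0)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.tuples(st.integers(1, 300), st.integers(1, 300),
                     st.integers(0, 300), st.integers(0, 300)))
    def test_accuracy_identity_on_random_confusions(self, counts):
        tp, tn, fp, fn = counts
        c = ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn)
        m = hw.compute_metrics(c)
        pos, neg = tp + fn, tn + fp
        expected = (m["sensitivity"] * pos + m["specificity"] * neg) / (pos + neg)
        assert m["accuracy"] == pytest.approx(expected)
        if not np.isnan(m["f1"]):
            p, r = m["precision"], m["sensitivity"]
            assert m["f1"] == pytest.approx(2 * p * r / (p + r), abs=1e-12)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_auc_matches_pair_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 60))
        y = rng.integers(0, 2, size=n)
        if y.sum() in (0, n):
            y[0], y[-1] = 0, 1
        scores = np.round(rng.normal(size=n) + y, 1)  # rounding creates ties
        auc = rank_auc(scores, y)
        pos = scores[y == 1]
        neg = scores[y == 0]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)


class TestEvaluateModels:
    def test_reports_cover_requested_models(self):
        m = labeled_matrix(40, 60, separation=0.8, seed=6)
        train, test = hw.partition(m, 0.75, seed=0)
        reports = hw.evaluate_models(train, test, "integrated",
                                     ["SVM", "NaiveBayes"], folds=5, seed=0)
        assert [r.model_name for r in reports] == ["SVM", "NaiveBayes"]
        for r in reports:
            assert len(r.cv_fold_metrics) == 5
            assert r.confusion.total == test.n_subjects
            assert 0.0 <= r.accuracy <= 1.0

    def test_confusion_consistent_with_predictions(self):
        y_true = np.array([1, 1, 0, 0, 1])
        y_pred = np.array([1, 0, 0, 1, 1])
        c = confusion_from_predictions(y_true, y_pred)
        assert (c.tp, c.tn, c.fp, c.fn) == (2, 1, 1, 1)
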