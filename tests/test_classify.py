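"""Grouped CV, sparse logistic fits, metrics, calibration, thresholds."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

import charmark as cm
from charmark.classify import ClassifyError, threshold_metrics


def metadata_matrix(participants, labels, rng=None):
    """FeatureMatrix with random simplex rows and given row metadata."""
    rng = rng or np.random.default_rng(0)
    n = len(participants)
    values = rng.dirichlet(np.ones(27), size=n)
    return cm.FeatureMatrix(values, [f"t{i}" for i in range(n)], list(labels),
                            list(participants), cm.ALPHABET.display_names())


class TestMakeFolds:
    def test_balanced_toy_case(self):
        fm = metadata_matrix([f"p{i}" for i in range(10)],
                             ["case"] * 5 + ["control"] * 5)
        plan = cm.make_folds(fm, n_folds=5, seed=0)
        for _, test in plan.splits():
            labels = np.asarray(fm.row_groups)[test]
            assert sorted(labels) == ["case", "control"]

    def test_participant_transcripts_share_fold(self):
        parts = ["p0", "p0", "p0", "p1", "p2", "p3", "p4", "p5", "p6",
                 "p7", "p8", "p9", "p9"]
        labels = ["case"] * 6 + ["control"] * 7
        plan = cm.make_folds(metadata_matrix(parts, labels), n_folds=3, seed=1)
        folds_p0 = set(plan.assignment[np.asarray(parts) == "p0"])
        assert len(folds_p0) == 1

    def test_stratification_within_ten_points(self):
        rng = np.random.default_rng(5)
        parts, labels = [], []
        for i in range(100):
            lab = "case" if i < 55 else "control"
            for _ in range(int(rng.integers(1, 6))):
                parts.append(f"p{i}")
                labels.append(lab)
        fm = metadata_matrix(parts, labels, rng)
        plan = cm.make_folds(fm, n_folds=5, seed=2)
        y = np.asarray(labels) == "case"
        global_prop = y.mean()
        for _, test in plan.splits():
            assert abs(y[test].mean() - global_prop) <= 0.10

    def test_no_participant_spans_folds(self, space_effect_corpus):
        corpus, _, _ = space_effect_corpus
        plan = cm.make_folds(corpus, n_folds=5, seed=3)
        for train, test in plan.splits():
            train_parts = {corpus[i].participant_id for i in np.flatnonzero(train)}
            test_parts = {corpus[i].participant_id for i in np.flatnonzero(test)}
            assert not train_parts & test_parts

    def test_deterministic_given_seed(self, null_corpus):
        corpus, _, _ = null_corpus
        a = cm.make_folds(corpus, 5, seed=9)
        b = cm.make_folds(corpus, 5, seed=9)
        assert np.array_equal(a.assignment, b.assignment)

    def test_too_few_participants_raises(self):
        fm = metadata_matrix(["p0", "p1", "p2", "p3"],
                             ["case", "case", "control", "control"])
        with pytest.raises(ClassifyError):
            cm.make_folds(fm, n_folds=5, seed=0)


class TestFitPredictLasso:
    def test_separable_feature(self):
        rng = np.random.default_rng(0)
        X = np.zeros((60, 2))
        y = np.array([0, 1] * 30)
        X[:, 0] = y + rng.normal(scale=0.01, size=60)
        probs, coefs = cm.fit_predict_lasso(X, y, X)
        from sklearn.metrics import roc_auc_score
        assert roc_auc_score(y, probs) == 1.0
        assert coefs[0] != 0

    def test_single_class_raises(self):
        X = np.zeros((4, 2))
        with pytest.raises(ClassifyError):
            cm.fit_predict_lasso(X, np.zeros(4), X)

    def test_planted_feature_selected_across_folds(self):
        rng = np.random.default_rng(1)
        n = 300
        y = rng.integers(0, 2, size=n)
        X = rng.dirichlet(np.ones(27), size=n)
        X[:, 5] += 0.15 * y  # planted signal in one of 27 columns
        fm = cm.FeatureMatrix(X, [f"t{i}" for i in range(n)],
                              ["case" if v else "control" for v in y],
                              [f"p{i}" for i in range(n)],
                              cm.ALPHABET.display_names())
        plan = cm.make_folds(fm, 5, seed=0)
        rep = cm.evaluate_feature_matrix(fm, plan, seed=0)
        planted = cm.ALPHABET.display_names()[5]
        hits = sum(planted in names for names in rep.selected_features)
        assert hits >= 4


class TestCalibrationMetrics:
    def test_perfect_predictions(self):
        brier, ece, _ = cm.calibration_metrics([0.0, 1.0, 1.0, 0.0],
                                               [0, 1, 1, 0])
        assert brier == 0.0 and ece == 0.0

    def test_constant_half_on_balanced(self):
        brier, ece, bins = cm.calibration_metrics([0.5] * 10, [0, 1] * 5)
        assert brier == pytest.approx(0.25)
        assert ece == pytest.approx(0.0)

    def test_overconfident_single_bin(self):
        brier, ece, bins = cm.calibration_metrics([0.8] * 10, [0, 1] * 5)
        assert ece == pytest.approx(0.3)
        assert len(bins) == 1 and bins.iloc[0]["count"] == 10

    def test_length_mismatch(self):
        with pytest.raises(ClassifyError):
            cm.calibration_metrics([0.5], [0, 1])


class TestOptimizeThreshold:
    def test_perfect_separation(self):
        t, m = cm.optimize_threshold([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1],
                                     "youden_j")
        assert 0.2 < t < 0.8
        assert m["youden_j"] == pytest.approx(1.0)

    def test_uninformative_probs(self):
        t, m = cm.optimize_threshold([0.5] * 6, [0, 1] * 3, "youden_j")
        assert m["youden_j"] == pytest.approx(0.0)

    def test_enumerated_example(self):
        t, m = cm.optimize_threshold([0.1, 0.4, 0.6, 0.9], [0, 0, 1, 1],
                                     "f1_max")
        assert 0.4 < t < 0.6
        assert m["f1"] == pytest.approx(1.0)

    def test_single_class_raises(self):
        with pytest.raises(ClassifyError):
            cm.optimize_threshold([0.2, 0.8], [1, 1], "youden_j")


class TestConfusionMatrix:
    def test_all_correct(self):
        counts, props = cm.confusion_matrix([0.1, 0.9], [0, 1], 0.5)
        assert counts[0, 1] == 0 and counts[1, 0] == 0

    def test_all_wrong(self):
        counts, _ = cm.confusion_matrix([0.9, 0.1], [0, 1], 0.5)
        (tn, fp), (fn, tp) = counts
        assert (tn, fp, fn, tp) == (0, 1, 1, 0)

    def test_hand_enumerated_four_rows(self):
        probs = [0.2, 0.6, 0.7, 0.4]
        labels = [0, 0, 1, 1]
        counts, props = cm.confusion_matrix(probs, labels, 0.5)
        (tn, fp), (fn, tp) = counts
        assert (tn, fp, fn, tp) == (1, 1, 1, 1)
        assert np.allclose(props, 0.5)

    def test_metric_identities(self):
        rng = np.random.default_rng(2)
        probs = rng.random(50)
        labels = rng.integers(0, 2, size=50)
        m = threshold_metrics(probs, labels, 0.5)
        (tn, fp), (fn, tp) = cm.confusion_matrix(probs, labels, 0.5)[0]
        assert m["accuracy"] == pytest.approx((tp + tn) / 50)
        if m["precision"] + m["recall_sensitivity"] > 0:
            assert m["f1"] == pytest.approx(
                2 * m["precision"] * m["recall_sensitivity"]
                / (m["precision"] + m["recall_sensitivity"])
            )


class TestEvaluateCV:
    def test_auc_equals_mann_whitney(self, space_effect_corpus):
        corpus, _, _ = space_effect_corpus
        plan = cm.make_folds(corpus, 5, seed=0)
        rep = cm.evaluate_cv(corpus, plan, "charmark", seed=0)
        y, probs = rep.oof_labels, rep.oof_probs
        n1, n0 = int(y.sum()), int((1 - y).sum())
        u = mannwhitneyu(probs[y == 1], probs[y == 0]).statistic
        assert rep.pooled["auc"] == pytest.approx(u / (n1 * n0))

    def test_oof_predictions_cover_all_rows(self, space_effect_corpus):
        corpus, _, _ = space_effect_corpus
        plan = cm.make_folds(corpus, 5, seed=1)
        rep = cm.evaluate_cv(corpus, plan, "space_only", seed=1)
        assert rep.oof_probs.shape[0] == len(corpus)
        assert not np.isnan(rep.oof_probs).any()

    def test_unknown_variant(self, null_corpus):
        corpus, _, _ = null_corpus
        plan = cm.make_folds(corpus, 5, seed=0)
        with pytest.raises(ClassifyError):
            cm.evaluate_cv(corpus, plan, "tfidf")

    def test_report_shapes(self, space_effect_corpus):
        corpus, _, _ = space_effect_corpus
        plan = cm.make_folds(corpus, 5, seed=0)
        rep = cm.evaluate_cv(corpus, plan, "charmark", seed=0)
        assert len(rep.per_fold) == 5
        for key in ("auc", "f1", "precision", "recall_sensitivity",
                    "specificity", "accuracy", "brier", "ece"):
            assert 0 <= rep.mean[key] <= 1
            assert rep.sd[key] >= 0
        assert set(rep.thresholds) == {"default_0.5", "youden_j", "f1_max"}
        row = rep.summary_row()
        assert "±" in row["auc"]

    def test_alpha_sensitivity_single_value(self, null_corpus):
        corpus, _, _ = null_corpus
        plan = cm.make_folds(corpus, 5, seed=0)
        reports, spread = cm.alpha_sensitivity(corpus, plan, [0.01], seed=0)
        assert spread["auc_spread"] == 0.0
        table = cm.sensitivity_table(reports)
        assert list(table["alpha"]) == ["0.01"]

    def test_huge_alpha_uninformative(self, space_effect_corpus):
        corpus, _, _ = space_effect_corpus
        sub = corpus[:150] + corpus[-150:]
        plan = cm.make_folds(sub, 5, seed=0)
        rep = cm.evaluate_cv(sub, plan, "charmark", alpha=100.0, seed=0)
        # features collapse toward uniform; discrimination collapses with them
        assert abs(rep.mean["auc"] - 0.5) <= 0.1
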