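"""LDA vs the Mahalanobis oracle, LOO-CV, and exact figures of merit."""

import numpy as np
import pytest

import chemodisc as cd
from chemodisc.discriminant import ConfusionCounts, UndefinedMetricError, _confusion


def mahalanobis_predict(model, X):
    """Oracle: assign each row to the Mahalanobis-closest class mean."""
    Sinv = np.linalg.inv(model.pooled_covariance)
    out = []
    for x in np.atleast_2d(X):
        d = {
            cls: float((x - mu) @ Sinv @ (x - mu))
            for cls, mu in model.class_means.items()
        }
        dp, dn = d[model.positive_class], d[model.negative_class]
        out.append(model.positive_class if dp < dn else model.negative_class)
    return np.array(out)


class TestFitLDA:
    def test_symmetric_1d_case(self):
        X = np.array([[-2.0], [0.0], [0.0], [2.0]])
        y = ["A", "A", "B", "B"]
        # means -1 and +1, pooled variance ((2)+(2))/2 = 2 -> weight (−1−1)/2 = −1
        model = cd.fit_lda(X, y)
        assert model.positive_class == "A"
        assert model.weight_vector[0] == pytest.approx(-1.0)
        assert model.bias == pytest.approx(0.0)
        assert model.regularization == 0.0

    def test_unit_variance_weight_two(self):
        # construct exact sample means −1/+1 and pooled variance 1
        a = np.array([-2.0, -1.0, 0.0]) + (-1 - np.mean([-2.0, -1.0, 0.0]))
        b = a + 2.0
        X = np.concatenate([a, b]).reshape(-1, 1)
        y = ["A"] * 3 + ["B"] * 3
        model = cd.fit_lda(X, y, positive_class="B")
        pooled = model.pooled_covariance[0, 0]
        assert model.weight_vector[0] == pytest.approx(2.0 / pooled)

    def test_equal_means_degenerate_to_negative_class(self):
        X = np.array([[0.0, 1.0], [0.0, -1.0], [0.0, 1.0], [0.0, -1.0]])
        X[:, 0] += np.array([1e-9, -1e-9, 1e-9, -1e-9])  # avoid exact zero variance
        y = ["A", "A", "B", "B"]
        model = cd.fit_lda(X, y)
        s = cd.score(model, X)
        np.testing.assert_allclose(s, 0, atol=1e-6)
        assert all(p == model.negative_class for p in cd.predict(model, X))

    def test_predictions_match_mahalanobis_oracle(self, separable_2class):
        X, y = separable_2class
        model = cd.fit_lda(X, y)
        grid = np.random.default_rng(31).normal(1.5, 2.0, size=(50, 2))
        np.testing.assert_array_equal(
            cd.predict(model, grid), mahalanobis_predict(model, grid)
        )

    def test_matches_sklearn_lda_predictions(self, separable_2class):
        sklearn_da = pytest.importorskip("sklearn.discriminant_analysis")
        X, y = separable_2class
        model = cd.fit_lda(X, y)
        ref = sklearn_da.LinearDiscriminantAnalysis(
            solver="lsqr", priors=[0.5, 0.5]
        ).fit(X, y)
        grid = np.random.default_rng(32).normal(1.5, 2.0, size=(60, 2))
        np.testing.assert_array_equal(cd.predict(model, grid), ref.predict(grid))

    def test_class_means_classified_correctly(self, separable_2class):
        X, y = separable_2class
        model = cd.fit_lda(X, y)
        for cls, mu in model.class_means.items():
            assert cd.predict(model, mu.reshape(1, -1))[0] == cls

    def test_singular_covariance_regularized_and_recorded(self):
        rng = np.random.default_rng(33)
        base = rng.normal(size=(10, 1))
        X = np.hstack([base, base])  # perfectly collinear columns
        X[:5] += 3.0
        y = ["A"] * 5 + ["B"] * 5
        model = cd.fit_lda(X, y)
        assert model.regularization > 0


class TestScore:
    def test_midpoint_scores_zero(self, separable_2class):
        X, y = separable_2class
        model = cd.fit_lda(X, y)
        mid = (model.class_means["A"] + model.class_means["B"]) / 2
        assert cd.score(model, mid.reshape(1, -1))[0] == pytest.approx(0.0, abs=1e-10)

    def test_positive_mean_scores_positive(self, separable_2class):
        X, y = separable_2class
        model = cd.fit_lda(X, y)
        mu = model.class_means[model.positive_class]
        assert cd.score(model, mu.reshape(1, -1))[0] > 0

    def test_dimension_mismatch_rejected(self, separable_2class):
        X, y = separable_2class
        model = cd.fit_lda(X, y)
        with pytest.raises(ValueError, match="columns"):
            cd.score(model, np.ones((2, 5)))


class TestLooCV:
    def test_perfectly_separated_data_all_100(self, separable_2class):
        X, y = separable_2class
        counts, fom = cd.loo_cv(X, y)
        assert (fom.sensitivity, fom.specificity, fom.accuracy) == (100.0, 100.0, 100.0)
        assert counts.total == len(y)

    def test_counts_always_conserved(self, separable_2class):
        X, y = separable_2class
        rng = np.random.default_rng(34)
        y_shuffled = rng.permutation(y)
        counts, _ = cd.loo_cv(X, y_shuffled)
        assert counts.total == len(y)

    def test_row_permutation_invariance(self, separable_2class):
        X, y = separable_2class
        perm = np.random.default_rng(35).permutation(len(y))
        c1, f1 = cd.loo_cv(X, y)
        c2, f2 = cd.loo_cv(X[perm], np.asarray(y)[perm])
        assert c1.to_dict() == c2.to_dict()

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(36)
        accs = []
        for s in range(20):
            r = np.random.default_rng(s)
            X = r.normal(size=(33, 3))
            y = np.array(["A"] * 15 + ["B"] * 18)
            _, fom = cd.loo_cv(X, r.permutation(y))
            accs.append(fom.accuracy)
        # null data: accuracy hovers at or below chance (LOO is slightly
        # pessimistic on label-balanced noise)
        assert 30 <= np.mean(accs) <= 60


class TestFiguresOfMerit:
    def test_all_correct_gives_100s(self):
        fom = cd.figures_of_merit(ConfusionCounts(TP=5, FN=0, TN=6, FP=0))
        assert (fom.sensitivity, fom.specificity, fom.accuracy) == (100.0, 100.0, 100.0)

    def test_hand_arithmetic_case(self):
        fom = cd.figures_of_merit(ConfusionCounts(TP=3, FN=1, TN=4, FP=2))
        assert fom.sensitivity == pytest.approx(75.0)
        assert fom.specificity == pytest.approx(100 * 4 / 6)
        assert round(fom.specificity, 3) == 66.667
        assert fom.accuracy == pytest.approx(70.0)

    def test_zero_denominator_raises(self):
        with pytest.raises(UndefinedMetricError, match="sensitivity"):
            cd.figures_of_merit(ConfusionCounts(TP=0, FN=0, TN=3, FP=1))
        with pytest.raises(UndefinedMetricError, match="specificity"):
            cd.figures_of_merit(ConfusionCounts(TP=2, FN=1, TN=0, FP=0))

    @pytest.mark.parametrize("tp,fn,tn,fp", [(3, 1, 4, 2), (5, 0, 6, 0), (1, 7, 2, 3)])
    def test_accuracy_is_prevalence_weighted_combination(self, tp, fn, tn, fp):
        c = ConfusionCounts(TP=tp, FN=fn, TN=tn, FP=fp)
        fom = cd.figures_of_merit(c)
        expected = (fom.sensitivity * (tp + fn) + fom.specificity * (tn + fp)) / c.total
        assert fom.accuracy == pytest.approx(expected, abs=1e-12)


class TestEvaluateSplit:
    def test_internal_consistency_of_report(self, separable_2class):
        X, y = separable_2class
        tr = list(range(0, 8)) + list(range(12, 20))
        te = list(range(8, 12)) + list(range(20, 24))
        rep = cd.evaluate_split(X[tr], np.asarray(y)[tr], X[te], np.asarray(y)[te], [0, 1])
        for block in (rep["cv"], rep["test"]):
            recomputed = cd.figures_of_merit(block["counts"])
            assert recomputed.to_dict() == block["fom"].to_dict()
        assert len(rep["scores"]) == len(tr) + len(te)

    def test_empty_test_partition_flagged(self, separable_2class):
        X, y = separable_2class
        rep = cd.evaluate_split(X, y, None, [], [0, 1])
        assert rep["test_absent"] and rep["test"] is None

    def test_confusion_orientation(self):
        y_true = np.array(["A", "A", "B", "B"])
        y_pred = np.array(["A", "B", "B", "A"])
        c = _confusion(y_true, y_pred, "A")
        assert c.to_dict() == {"TP": 1, "TN": 1, "FP": 1, "FN": 1}
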