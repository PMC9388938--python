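"""LOOCV linear-SVM search, F-score ranking, permutation inference."""

import itertools

import numpy as np
import pytest

import falffmvpa as fm
from falffmvpa import classify


class TestFScore:
    def test_hand_computed_example(self):
        assert fm.f_score([1, 2, 3, 4, 5, 6], [1, 1, 1, 0, 0, 0]) == pytest.approx(2.25)

    def test_constant_feature_scores_zero(self):
        assert fm.f_score([2.0] * 8, [1, 1, 1, 1, 0, 0, 0, 0]) == 0.0

    def test_zero_variance_distinct_means_is_infinite(self):
        assert fm.f_score([1, 1, 1, 5, 5, 5], [1, 1, 1, 0, 0, 0]) == np.inf

    def test_one_class_raises(self):
        with pytest.raises(ValueError):
            fm.f_score([1, 2, 3], [1, 1, 1])

    @pytest.mark.parametrize("a,b", [(2.0, 0.0), (-3.0, 7.0), (0.5, -1.0)])
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(0)
        x = rng.normal(size=12)
        labels = np.r_[np.ones(6), np.zeros(6)].astype(int)
        assert fm.f_score(a * x + b, labels) == pytest.approx(fm.f_score(x, labels), rel=1e-9)


class TestMetrics:
    def test_all_correct(self):
        y = np.r_[np.ones(5), np.zeros(5)].astype(int)
        acc, sens, spec, auc = fm.classification_metrics(y, y, np.where(y == 1, 2.0, -2.0))
        assert (acc, sens, spec, auc) == (1.0, 1.0, 1.0, 1.0)

    def test_anti_ordered_decisions_give_zero_auc(self):
        y = np.array([1, 1, 0, 0])
        *_, auc = fm.classification_metrics(y, y, np.array([-2.0, -1.0, 1.0, 2.0]))
        assert auc == 0.0

    def test_counting_oracle(self):
        # 14 TP, 4 FN, 16 TN, 4 FP
        y_true = np.r_[np.ones(18), np.zeros(20)].astype(int)
        y_pred = np.r_[np.ones(14), np.zeros(4), np.zeros(16), np.ones(4)].astype(int)
        acc, sens, spec, _ = fm.classification_metrics(y_true, y_pred)
        assert acc == pytest.approx(30 / 38)
        assert sens == pytest.approx(14 / 18)
        assert spec == pytest.approx(16 / 20)

    def test_missing_class_raises(self):
        with pytest.raises(ValueError):
            fm.classification_metrics(np.ones(4, int), np.ones(4, int))


class TestLoocvClassify:
    def test_separable_clouds_are_perfectly_classified(self, feature_matrix_factory):
        rng = np.random.default_rng(1)
        labels = np.r_[np.ones(10), np.zeros(10)].astype(int)
        X = rng.normal(size=(20, 8))
        X[labels == 1] += 6.0
        feats = feature_matrix_factory(X, labels)
        cv = fm.loocv_classify(feats, k_grid=[1, 4, 8], config=fm.SVMConfig(covariates=()))
        np.testing.assert_allclose(cv.accuracy_curve, 1.0)
        assert cv.auc == 1.0 and cv.best_k == 1

    def test_null_features_hover_near_chance(self, feature_matrix_factory):
        accs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            labels = rng.permutation(np.r_[np.ones(15), np.zeros(15)]).astype(int)
            feats = feature_matrix_factory(rng.normal(size=(30, 500)), labels, rng)
            cv = fm.loocv_classify(feats, k_grid=[10], config=fm.SVMConfig(covariates=()))
            accs.append(cv.best_accuracy)
        inside = np.mean([(0.3 <= a <= 0.7) for a in accs])
        assert inside >= 0.9

    def test_single_feature_margin_classifier_hand_trace(self, feature_matrix_factory):
        # cleanly separated single feature: every left-out subject lies on
        # its own class's side of any soft-margin boundary fitted to the rest
        x = np.array([-10.0, -8.0, -9.0, -7.0, 7.0, 9.0, 8.0, 10.0])
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        feats = feature_matrix_factory(x[:, None], labels)
        cv = fm.loocv_classify(feats, k_grid=[1], config=fm.SVMConfig(covariates=()))
        np.testing.assert_array_equal(cv.oof_predictions[:, 0], labels)
        assert cv.best_accuracy == 1.0

    def test_subject_reordering_leaves_curves_unchanged(self, small_features):
        cv = fm.loocv_classify(small_features, k_grid=[5, 10])
        perm = np.random.default_rng(0).permutation(small_features.n_subjects)
        cv_p = fm.loocv_classify(small_features.subset_subjects(perm), k_grid=[5, 10])
        np.testing.assert_allclose(cv.accuracy_curve, cv_p.accuracy_curve, atol=1e-12)
        np.testing.assert_allclose(cv.sensitivity_curve, cv_p.sensitivity_curve, atol=1e-12)

    def test_fold_hygiene_training_never_sees_heldout(self, feature_matrix_factory, monkeypatch):
        rng = np.random.default_rng(2)
        labels = np.r_[np.ones(6), np.zeros(6)].astype(int)
        X = rng.normal(size=(12, 20))
        feats = feature_matrix_factory(X, labels)
        seen_shapes = []
        orig_fit = classify.SVC.fit

        def spy_fit(self, Xf, yf):
            seen_shapes.append(Xf.shape[0])
            return orig_fit(self, Xf, yf)

        monkeypatch.setattr(classify.SVC, "fit", spy_fit)
        screened_rows = []
        orig_screen = classify._screen_columns

        def spy_screen(Xs, ys, cov, q):
            screened_rows.append(Xs.shape[0])
            return orig_screen(Xs, ys, cov, q)

        monkeypatch.setattr(classify, "_screen_columns", spy_screen)
        fm.loocv_classify(feats, k_grid=[3], config=fm.SVMConfig(covariates=()))
        assert set(seen_shapes) == {11}  # every fit uses exactly n-1 subjects
        assert set(screened_rows) == {11}  # per-fold screening excludes held-out

    def test_accuracy_recomputable_from_oof_predictions(self, small_features):
        cv = fm.loocv_classify(small_features, k_grid=[5, 10, 20])
        j = int(np.flatnonzero(cv.k_grid == cv.best_k)[0])
        acc = (cv.oof_predictions[:, j] == cv.oof_labels).mean()
        assert acc == pytest.approx(cv.best_accuracy)
        assert cv.accuracy_curve.max() == cv.accuracy_curve[j]

    def test_too_few_subjects_raises(self, feature_matrix_factory):
        feats = feature_matrix_factory(np.random.default_rng(0).normal(size=(4, 3)),
                                       [1, 1, 0, 0])
        with pytest.raises(ValueError):
            fm.loocv_classify(feats, k_grid=[1])


class TestPermutationTest:
    def test_add_one_rule_when_observed_beats_all(self):
        labels = np.r_[np.ones(6), np.zeros(6)].astype(int)
        perm = fm.permutation_test(lambda y: 0.0, labels, n_perm=99, seed=0, observed=5.0)
        assert perm.p_value == pytest.approx(1 / 100)

    def test_label_independent_statistic_is_calibrated(self):
        rng = np.random.default_rng(0)
        labels = np.r_[np.ones(8), np.zeros(8)].astype(int)
        hits = 0
        for rep in range(200):
            draws = iter(rng.normal(size=101))

            def stat(y, _d=draws):
                return next(_d)

            p = fm.permutation_test(stat, labels, n_perm=100, seed=rep).p_value
            hits += p <= 0.05
        assert hits / 200 == pytest.approx(0.05, abs=0.03)

    def test_matches_exhaustive_enumeration_on_tiny_sample(self):
        data = np.array([1.0, 2.0, 3.0, 10.0])
        labels = np.array([0, 0, 1, 1])

        def stat(y):
            return data[y == 1].mean() - data[y == 0].mean()

        obs = stat(labels)
        null = [stat(np.array(p)) for p in itertools.permutations(labels)]
        p_exh = np.mean([v >= obs for v in null])
        p_mc = fm.permutation_test(stat, labels, n_perm=4000, seed=3).p_value
        assert p_mc == pytest.approx(p_exh, abs=0.03)

    def test_constant_labels_raise(self):
        with pytest.raises(ValueError):
            fm.permutation_test(lambda y: 0.0, np.ones(6), n_perm=10)

    def test_p_value_always_positive(self):
        labels = np.r_[np.ones(5), np.zeros(5)].astype(int)
        perm = fm.permutation_test(lambda y: 1.0, labels, n_perm=49, seed=0)
        assert 0 < perm.p_value <= 1
        assert perm.p_value == 1.0  # ties count toward the null
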