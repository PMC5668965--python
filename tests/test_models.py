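"""Latent models: scaling, PCA/PLS/OPLS fits, CV, permutation, CV-ANOVA."""

import numpy as np
import pytest
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from nmrmetab.models import (
    ModelSpec,
    cross_validated_q2,
    cv_anova,
    fit_oplsda,
    fit_pca,
    fit_plsda,
    permutation_test,
    scale_matrix,
)


def two_class_data(rng, n_per=12, p=60, effect=1.5, n_informative=8):
    """Two groups separated along a few informative columns."""
    x = rng.normal(size=(2 * n_per, p))
    x[n_per:, :n_informative] += effect
    groups = np.array(["A"] * n_per + ["B"] * n_per)
    return x, groups


class TestScaling:
    def test_mean_center(self):
        xs, spec = scale_matrix(np.array([[1.0], [3.0]]), "mean_center")
        assert np.allclose(xs, [[-1.0], [1.0]])
        assert spec.scale[0] == 1.0

    def test_pareto_hand_computed(self):
        # column (0, 0, 4): mean 4/3, sample sd sqrt(16/3); divisor sd^(1/2)
        col = np.array([[0.0], [0.0], [4.0]])
        xs, spec = scale_matrix(col, "pareto")
        sd = np.sqrt(16.0 / 3.0)
        assert spec.scale[0] == pytest.approx(np.sqrt(sd))
        assert np.allclose(xs[:, 0], (col[:, 0] - 4.0 / 3.0) / np.sqrt(sd))

    def test_pareto_inverse_roundtrip(self, rng):
        x = rng.normal(size=(6, 9))
        xs, spec = scale_matrix(x, "pareto")
        assert np.allclose(spec.invert(xs), x, atol=1e-10)

    def test_constant_column_flagged_and_unit_scaled(self):
        x = np.array([[1.0, 5.0], [1.0, 7.0], [1.0, 6.0]])
        xs, spec = scale_matrix(x, "pareto")
        assert spec.constant_columns[0] and not spec.constant_columns[1]
        assert spec.scale[0] == 1.0
        assert np.allclose(xs[:, 0], 0.0)


class TestPCA:
    def test_rank_one_two_samples(self):
        x = np.array([[1.0, 2.0, 0.0], [3.0, 6.0, 0.0]])
        xs, _ = scale_matrix(x, "mean_center")
        model = fit_pca(xs, 1)
        direction = model.loadings[:, 0]
        expected = np.array([1.0, 2.0, 0.0]) / np.sqrt(5.0)
        assert np.allclose(np.abs(direction), expected, atol=1e-12)

    def test_explained_variance_bounded(self, rng):
        xs, _ = scale_matrix(rng.normal(size=(9, 20)), "mean_center")
        model = fit_pca(xs, 5)
        assert model.r2x <= 1.0 + 1e-12
        assert np.all(np.diff(model.r2x_per_component) <= 1e-12)

    def test_agrees_with_independent_decomposition(self, rng):
        xs, _ = scale_matrix(rng.normal(size=(6, 20)), "mean_center")
        mine = fit_pca(xs, 3)
        ref = PCA(n_components=3).fit(xs)
        t_ref = ref.transform(xs)
        for a in range(3):
            err = min(
                np.max(np.abs(mine.scores[:, a] - s * t_ref[:, a]))
                for s in (1.0, -1.0)
            )
            assert err < 1e-8

    def test_too_many_components_rejected(self, rng):
        xs, _ = scale_matrix(rng.normal(size=(4, 5)), "mean_center")
        with pytest.raises(ValueError):
            fit_pca(xs, 4)

    def test_scores_orthogonal(self, rng):
        xs, _ = scale_matrix(rng.normal(size=(10, 15)), "mean_center")
        model = fit_pca(xs, 4)
        gram = model.scores.T @ model.scores
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8


class TestPLSDA:
    def test_perfect_predictor_column_gets_the_weight(self):
        rng = np.random.default_rng(1)
        n = 10
        y = np.array(["A"] * 5 + ["B"] * 5)
        x = np.zeros((n, 4))
        x[:, 2] = np.where(y == "B", 1.0, -1.0)
        model = fit_plsda(x, y, 1)
        w = np.abs(model.weights[:, 0])
        assert w[2] == pytest.approx(1.0)
        assert np.allclose(np.delete(w, 2), 0.0)

    def test_predictions_match_reference_nipals(self, rng):
        x = rng.normal(size=(8, 5))
        groups = np.array(["A"] * 4 + ["B"] * 4)
        y = np.where(groups == "B", 1.0, -1.0)
        xs = x - x.mean(axis=0)
        mine = fit_plsda(xs, groups, 2).predict_response(xs)
        ref = PLSRegression(n_components=2, scale=False).fit(xs, y)
        assert np.max(np.abs(mine - ref.predict(xs).ravel())) < 1e-8

    def test_three_group_cohort_clusters_in_score_space(self, normalized_matrix):
        xs, _ = scale_matrix(normalized_matrix.values, "pareto")
        model = fit_plsda(xs, normalized_matrix.groups, 2)
        sil = silhouette_score(model.scores[:, :2], normalized_matrix.groups)
        assert sil > 0.0

    def test_small_class_rejected(self):
        x = np.zeros((4, 3))
        with pytest.raises(ValueError):
            fit_plsda(x, ["A", "A", "A", "B"], 1)


class TestOPLSDA:
    def test_zero_orth_equals_single_component_pls(self, rng):
        x, groups = two_class_data(rng, n_per=5, p=30)
        xs, _ = scale_matrix(x, "pareto")
        opls = fit_oplsda(xs, groups, n_orth=0)
        pls = fit_plsda(xs, groups, 1)
        err = min(
            np.max(np.abs(opls.scores[:, 0] - s * pls.scores[:, 0]))
            for s in (1.0, -1.0)
        )
        assert err < 1e-10

    def test_orthogonal_scores_uncorrelated_with_response(self, rng):
        x, groups = two_class_data(rng)
        xs, _ = scale_matrix(x, "pareto")
        model = fit_oplsda(xs, groups, n_orth=2)
        y = np.where(groups == "B", 1.0, -1.0)
        for a in range(model.n_orthogonal):
            assert abs(np.corrcoef(model.scores_orth[:, a], y)[0, 1]) < 1e-8

    def test_orthogonal_filter_removes_structured_noise(self, rng):
        # data = y-correlated direction + large y-orthogonal structure
        n = 20
        y = np.array([-1.0] * 10 + [1.0] * 10)
        groups = np.where(y > 0, "B", "A")
        confound = rng.normal(size=n)
        confound -= confound @ y / (y @ y) * y  # orthogonal to y
        d1 = np.zeros(30); d1[:5] = 1.0
        d2 = np.zeros(30); d2[10:20] = 1.0
        x = np.outer(y, d1) + 6.0 * np.outer(confound, d2)
        x += 0.01 * rng.normal(size=x.shape)
        xs, _ = scale_matrix(x, "mean_center")
        opls = fit_oplsda(xs, groups, n_orth=1)
        pls1 = fit_plsda(xs, groups, 1)
        assert opls.r2y >= pls1.r2y - 1e-12
        assert opls.r2y > 0.95

    def test_predictive_score_sign_follows_positive_class(self, rng):
        x, groups = two_class_data(rng)
        xs, _ = scale_matrix(x, "pareto")
        model = fit_oplsda(xs, groups, n_orth=1)
        y = np.where(groups == "B", 1.0, -1.0)
        assert np.corrcoef(model.scores[:, 0], y)[0, 1] > 0

    def test_three_classes_rejected(self):
        x = np.zeros((6, 3))
        with pytest.raises(ValueError, match="pairwise"):
            fit_oplsda(x, ["A", "A", "B", "B", "C", "C"], 1)


class TestCrossValidation:
    def test_random_response_gives_negative_median_q2(self):
        q2s = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=(24, 40))
            groups = np.array(["A", "B"] * 12)
            q2s.append(
                cross_validated_q2(x, groups, ModelSpec(), k=6, seed=seed).q2
            )
        assert np.median(q2s) < 0.0

    def test_separable_data_gives_high_q2(self, rng):
        x, groups = two_class_data(rng, n_per=12, effect=2.0)
        res = cross_validated_q2(x, groups, ModelSpec(), k=10, seed=0)
        assert res.q2 > 0.5

    def test_stratified_folds_keep_both_classes(self, rng):
        x, groups = two_class_data(rng, n_per=10)
        res = cross_validated_q2(x, groups, ModelSpec(), k=5, seed=3)
        for fold in range(5):
            train = res.folds != fold
            assert set(groups[train]) == {"A", "B"}

    def test_k_larger_than_class_rejected(self, rng):
        x, groups = two_class_data(rng, n_per=4)
        with pytest.raises(ValueError):
            cross_validated_q2(x, groups, ModelSpec(), k=8, seed=0)

    def test_q2_below_r2y(self, rng):
        x, groups = two_class_data(rng, n_per=10, effect=1.0)
        xs, _ = scale_matrix(x, "pareto")
        model = fit_oplsda(xs, groups, n_orth=1)
        res = cross_validated_q2(x, groups, ModelSpec(), k=10, seed=1)
        assert res.q2 <= model.r2y + 1e-12

    def test_deterministic_given_seed(self, rng):
        x, groups = two_class_data(rng)
        a = cross_validated_q2(x, groups, ModelSpec(), k=6, seed=11)
        b = cross_validated_q2(x, groups, ModelSpec(), k=6, seed=11)
        assert a.q2 == b.q2 and np.array_equal(a.folds, b.folds)


class TestPermutation:
    def test_p_equals_one_over_n_plus_one_when_observed_best(self, rng):
        x, groups = two_class_data(rng, n_per=10, effect=3.0)
        res = permutation_test(x, groups, ModelSpec(), n=24, k=5, seed=0)
        assert res.permuted_q2.max() < res.observed_q2
        assert res.p_q2 == pytest.approx(1.0 / 25.0)
        assert res.permuted_q2.size == res.permuted_r2y.size == 24

    def test_deterministic_given_seed(self, rng):
        x, groups = two_class_data(rng, n_per=6, p=20)
        a = permutation_test(x, groups, ModelSpec(), n=10, k=3, seed=5)
        b = permutation_test(x, groups, ModelSpec(), n=10, k=3, seed=5)
        assert np.array_equal(a.permuted_q2, b.permuted_q2)
        assert a.p_q2 == b.p_q2

    def test_intercepts_reported(self, rng):
        x, groups = two_class_data(rng, n_per=8)
        res = permutation_test(x, groups, ModelSpec(), n=15, k=4, seed=2)
        assert np.isfinite(res.r2_intercept) and np.isfinite(res.q2_intercept)
        assert res.label_correlations.min() >= 0.0


class TestCvAnova:
    def test_no_predictive_power_clamps_to_zero(self, rng):
        x, groups = two_class_data(rng, n_per=6, effect=0.0)
        res = cross_validated_q2(x, groups, ModelSpec(), k=4, seed=0)
        if res.press >= res.ss:  # null data: PRESS usually exceeds SS
            anova = cv_anova(res)
            assert anova.f_statistic == 0.0 and anova.p_value == 1.0

    def test_p_decreases_as_press_shrinks(self, rng):
        x, groups = two_class_data(rng, n_per=10, effect=2.0)
        res = cross_validated_q2(x, groups, ModelSpec(), k=5, seed=0)
        ps = []
        for factor in (0.8, 0.4, 0.1):
            shrunk = cv_anova(
                type(res)(
                    q2=res.q2, press=res.ss * factor, ss=res.ss,
                    predictions=res.predictions, y=res.y, folds=res.folds,
                    n_samples=res.n_samples, spec=res.spec,
                )
            )
            ps.append(shrunk.p_value)
        assert ps[0] > ps[1] > ps[2]

    def test_strong_signal_significant(self, rng):
        x, groups = two_class_data(rng, n_per=12, effect=2.0)
        res = cross_validated_q2(x, groups, ModelSpec(), k=10, seed=0)
        anova = cv_anova(res)
        assert anova.p_value < 0.05
        assert anova.df_model == 2  # one predictive + one orthogonal
        assert anova.df_residual == 24 - 1 - 2

    def test_press_equal_ss_gives_f_zero(self, rng):
        x, groups = two_class_data(rng, n_per=6)
        res = cross_validated_q2(x, groups, ModelSpec(), k=4, seed=0)
        forced = type(res)(
            q2=0.0, press=res.ss, ss=res.ss, predictions=res.predictions,
            y=res.y, folds=res.folds, n_samples=res.n_samples, spec=res.spec,
        )
        anova = cv_anova(forced)
        assert anova.f_statistic == 0.0 and anova.p_value == 1.0
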