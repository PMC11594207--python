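"""SPXY partitioning, PLS/PLS-DA/random forest, and metrics — each checked
against an independent oracle where one exists."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from bananachem import (
    SyntheticConfig, generate_spectra_dataset, to_absorbance,
    evaluate_classification, evaluate_regression,
    fit_pls, fit_plsda, fit_rft, predict_pls, predict_plsda, predict_rft,
    spxy_split,
)
from bananachem.chemometrics import rmsecv_curve, venetian_folds
from bananachem.exceptions import ConfigurationError, DegenerateDataError

from _oracles import nipals_oracle, spxy_oracle


# ---------------------------------------------------------------------------
# SPXY

class TestSpxy:
    def test_collinear_extremes_selected(self):
        X = np.array([[0.0], [1.0], [2.0]])
        y = np.array([0.0, 1.0, 2.0])
        split = spxy_split(X, y, 2 / 3)
        assert np.array_equal(split.calibration_indices, [0, 2])
        assert np.array_equal(split.prediction_indices, [1])

    def test_deterministic_and_partitioning(self, rng):
        X = rng.random((15, 6))
        y = rng.random(15)
        s1 = spxy_split(X, y)
        s2 = spxy_split(X, y)
        assert np.array_equal(s1.calibration_indices, s2.calibration_indices)
        union = np.union1d(s1.calibration_indices, s1.prediction_indices)
        assert np.array_equal(union, np.arange(15))
        assert np.intersect1d(s1.calibration_indices, s1.prediction_indices).size == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.random((8, 4))
        y = rng.random(8)
        split = spxy_split(X, y, 5 / 8)
        assert list(split.calibration_indices) == spxy_oracle(X, y, 5)

    def test_degenerate_inputs_rejected(self):
        X = np.ones((5, 3))
        with pytest.raises(DegenerateDataError, match="identical"):
            spxy_split(X, np.arange(5.0))
        rng = np.random.default_rng(0)
        with pytest.raises(DegenerateDataError, match="spread"):
            spxy_split(rng.random((5, 3)), np.ones(5))


# ---------------------------------------------------------------------------
# PLS regression

class TestFitPls:
    def test_univariate_x_equals_ols_line(self, rng):
        x = rng.random(12)
        y = 2.5 * x + 1.0 + 0.1 * rng.standard_normal(12)
        model, _ = fit_pls(x[:, None], y, max_lv=1, cv_folds=3)
        slope, intercept = np.polyfit(x, y, 1)
        pred = predict_pls(model, x[:, None])
        assert np.allclose(pred, slope * x + intercept, atol=1e-8)

    def test_exact_linear_map_interpolated(self, rng):
        X = rng.random((10, 3))
        beta = np.array([1.0, -2.0, 0.5])
        y = X @ beta + 4.0
        model, _ = fit_pls(X, y, max_lv=3, cv_folds=5)
        _, rmsec = evaluate_regression(y, predict_pls(model, X))
        assert rmsec < 1e-8

    @pytest.mark.parametrize("seed", range(20))
    def test_coefficients_match_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.random((12, 5))
        y = rng.random(12)
        model, _ = fit_pls(X, y, max_lv=2, cv_folds=3)
        # refit at exactly 2 components for the comparison
        from bananachem._pls import nipals, coefficients
        W, P, Q, a = nipals(X - X.mean(0), y - y.mean(), 2)
        b = coefficients(W, P, Q, a)[:, 0]
        assert np.allclose(b, nipals_oracle(X.copy(), y.copy(), 2), atol=1e-6)

    def test_matches_sklearn_pls(self, rng):
        """Independent library cross-check of the regression vector."""
        X = rng.random((20, 6))
        y = rng.random(20)
        from bananachem._pls import nipals, coefficients
        W, P, Q, a = nipals(X - X.mean(0), y - y.mean(), 3)
        b = coefficients(W, P, Q, a)[:, 0]
        sk = PLSRegression(n_components=3, scale=False).fit(X, y)
        assert np.allclose(b, sk.coef_.ravel(), atol=1e-8)

    def test_full_rank_reproduces_pseudoinverse_fit(self, rng):
        X = rng.random((9, 4))
        y = rng.random(9)
        Xc = X - X.mean(0)
        from bananachem._pls import nipals, coefficients
        W, P, Q, a = nipals(Xc, y - y.mean(), 4)
        b = coefficients(W, P, Q, a)[:, 0]
        assert np.allclose(b, np.linalg.pinv(Xc) @ (y - y.mean()), atol=1e-6)

    def test_score_orthogonality_and_route_equivalence(self, rng):
        X = rng.random((15, 8))
        y = rng.random(15)
        model, _ = fit_pls(X, y, max_lv=4, cv_folds=5)
        Xc = X - model.x_mean
        T = Xc @ model.weights @ np.linalg.inv(model.x_loadings.T @ model.weights)
        off = T.T @ T - np.diag(np.diag(T.T @ T))
        assert np.all(np.abs(off) < 1e-8)
        latent = T @ model.y_loadings + model.y_mean
        assert np.allclose(latent, predict_pls(model, X), atol=1e-8)

    def test_rmsecv_matches_brute_force_refit_oracle(self):
        """The nested-component CV curve equals per-(fold, lv) refits."""
        rng = np.random.default_rng(42)
        X = rng.random((18, 6))
        y = X @ rng.random(6) + 0.3 * rng.standard_normal(18)
        max_lv, k = 4, 3
        curve = rmsecv_curve(X, y, max_lv, k)
        from bananachem._pls import nipals, coefficients
        oracle = np.zeros(max_lv)
        for lv in range(1, max_lv + 1):
            sq = 0.0
            for test_idx in venetian_folds(18, k):
                train = np.setdiff1d(np.arange(18), test_idx)
                Xt, yt = X[train], y[train]
                W, P, Q, a = nipals(Xt - Xt.mean(0), yt - yt.mean(), lv)
                b = coefficients(W, P, Q, a)[:, 0]
                pred = (X[test_idx] - Xt.mean(0)) @ b + yt.mean()
                sq += np.sum((y[test_idx] - pred) ** 2)
            oracle[lv - 1] = np.sqrt(sq / 18)
        assert np.allclose(curve, oracle, atol=1e-10)

    def test_prediction_at_calibration_mean_is_y_mean(self, rng):
        X = rng.random((10, 5))
        y = rng.random(10)
        model, _ = fit_pls(X, y, max_lv=3, cv_folds=5)
        assert np.allclose(predict_pls(model, X.mean(0)[None, :]), y.mean())

    def test_band_mismatch_and_degenerate_y(self, rng):
        X = rng.random((10, 5))
        model, _ = fit_pls(X, rng.random(10), max_lv=2, cv_folds=5)
        with pytest.raises(ConfigurationError, match="5"):
            predict_pls(model, rng.random((3, 4)))
        with pytest.raises(DegenerateDataError, match="variance"):
            fit_pls(X, np.ones(10), max_lv=2, cv_folds=5)


# ---------------------------------------------------------------------------
# PLS-DA and random forest

class TestPlsda:
    def test_perfectly_separated_classes(self, rng):
        X = rng.random((20, 4))
        labels = np.array(["a"] * 10 + ["b"] * 10)
        X[10:, 0] += 5.0
        model, _ = fit_plsda(X, labels, max_lv=3, cv_folds=5)
        assert evaluate_classification(labels, predict_plsda(model, X)) == 100.0

    def test_exact_tie_goes_to_lower_class_index(self):
        from bananachem.chemometrics import PLSDAModel
        model = PLSDAModel(
            classes=np.array(["a", "b"]), n_lv=1,
            weights=np.ones((2, 1)), x_loadings=np.ones((2, 1)),
            y_loadings=np.zeros((1, 2)), x_mean=np.zeros(2),
            y_mean=np.array([0.5, 0.5]),
            coefficients=np.zeros((2, 2)))
        assert predict_plsda(model, np.array([[1.0, 2.0]]))[0] == "a"

    def test_single_class_rejected(self, rng):
        with pytest.raises(DegenerateDataError, match="class"):
            fit_plsda(rng.random((10, 3)), np.array(["a"] * 10), 2, 2)

    def test_strong_class_effect_recovered_across_seeds(self):
        """With the class offset an order of magnitude above the noise, the
        origin labels are recovered on held-out samples (10 seeds)."""
        accs = []
        for seed in range(10):
            cfg = SyntheticConfig(seed=seed, n_samples=60, n_bands=40,
                                  class_effect=0.05, noise_sd=0.002)
            ds, _ = generate_spectra_dataset(cfg)
            a = to_absorbance(ds)
            classes, y_int = np.unique(ds.labels, return_inverse=True)
            split = spxy_split(a.X, y_int.astype(float))
            cal, pred = split.calibration_indices, split.prediction_indices
            model, _ = fit_plsda(a.X[cal], ds.labels[cal], max_lv=8, cv_folds=5)
            accs.append(evaluate_classification(
                ds.labels[pred], predict_plsda(model, a.X[pred])))
        assert np.mean(accs) >= 95.0


class TestRft:
    def test_memorizes_separable_samples(self, rng):
        X = rng.random((10, 5))
        labels = np.array(["a", "b"] * 5)
        model = fit_rft(X, labels, n_trees=200, seed=0)
        assert evaluate_classification(labels, predict_rft(model, X)) == 100.0

    def test_seeded_determinism(self, rng):
        X = rng.random((30, 6))
        labels = np.array(["a", "b"] * 15)
        Xnew = rng.random((10, 6))
        p1 = predict_rft(fit_rft(X, labels, 100, seed=3), Xnew)
        p2 = predict_rft(fit_rft(X, labels, 100, seed=3), Xnew)
        assert np.array_equal(p1, p2)

    def test_permuted_labels_score_near_majority_rate(self):
        """With labels shuffled, held-out accuracy collapses to roughly the
        majority-class rate (10 seeds)."""
        gaps = []
        for seed in range(10):
            cfg = SyntheticConfig(seed=seed, n_samples=60, n_bands=30)
            ds, _ = generate_spectra_dataset(cfg)
            a = to_absorbance(ds)
            rng = np.random.default_rng(seed + 1000)
            labels = rng.permutation(ds.labels)
            classes, y_int = np.unique(labels, return_inverse=True)
            split = spxy_split(a.X, y_int.astype(float))
            cal, pred = split.calibration_indices, split.prediction_indices
            model = fit_rft(a.X[cal], labels[cal], 200, seed=seed)
            acc = evaluate_classification(labels[pred], predict_rft(model, a.X[pred]))
            majority = 100.0 * max(np.mean(labels[pred] == c) for c in classes)
            gaps.append(acc - majority)
        assert abs(np.mean(gaps)) <= 10.0


# ---------------------------------------------------------------------------
# Metrics

class TestMetrics:
    def test_perfect_prediction(self):
        r2, rmse = evaluate_regression(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))
        assert r2 == 1.0 and rmse == 0.0

    def test_hand_arithmetic(self):
        r2, rmse = evaluate_regression(np.array([0.0, 2.0]), np.array([1.0, 1.0]))
        assert rmse == 1.0 and r2 == 0.0

    def test_accuracy_three_of_four(self):
        acc = evaluate_classification(np.array(list("aabb")), np.array(list("aaba")))
        assert acc == 75.0

    def test_zero_variance_truth_rejected(self):
        with pytest.raises(DegenerateDataError):
            evaluate_regression(np.ones(4), np.arange(4.0))
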