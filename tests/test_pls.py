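"""PLS core: NIPALS correctness against OLS and scikit-learn, prediction
linearity, metrics, nested CV, bootstrap OOB validation and the
capability-of-detection LoD."""

import numpy as np
import pytest
from scipy import stats

from sersquant import (
    bootstrap_validate,
    compute_metrics,
    double_cv_loco,
    fit_pls,
    load_model,
    pls_lod,
    predict,
    predict_all,
    save_model,
)


def _random_instance(seed, n=20, p=8, m=1, noise=0.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    B = rng.normal(size=(p, m))
    Y = X @ B + noise * rng.normal(size=(n, m))
    return X, Y


class TestFitPLS:
    def test_rank_one_exact_relation_fits_with_one_lv(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=30)
        X = np.outer(t, rng.normal(size=12))
        y = 2.0 * t + 1.0
        model = fit_pls(X, y, 1)
        resid = predict(model, X)[:, 0] - y
        assert np.abs(resid).max() < 1e-8 * (y.max() - y.min())

    @pytest.mark.parametrize("m", [1, 3])
    def test_max_lv_equals_pseudo_inverse_solution(self, m):
        X, Y = _random_instance(5, noise=0.3, m=m)
        model = fit_pls(X, Y, 8)
        Xc = X - X.mean(axis=0)
        Yc = Y - Y.mean(axis=0)
        B_ols = np.linalg.pinv(Xc) @ Yc
        assert np.abs(model.coefs(8) - B_ols).max() < 1e-8

    def test_pls2_with_single_column_matches_pls1(self):
        X, y = _random_instance(7, noise=0.5)
        m1 = fit_pls(X, y[:, 0], 4)
        m2 = fit_pls(X, y, 4)
        assert np.abs(m1.coefs(4) - m2.coefs(4)).max() < 1e-10

    def test_matches_sklearn_nipals(self):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X, Y = _random_instance(9, n=40, p=15, m=2, noise=0.4)
        for a in (1, 3, 5):
            ours = fit_pls(X, Y, a)
            ref = sklearn.PLSRegression(
                n_components=a, scale=False, tol=1e-10, max_iter=5000
            ).fit(X, Y)
            # sklearn iterates NIPALS to a tolerance; ours solves the inner
            # fixed point exactly, so agreement is bounded by sklearn's stop
            np.testing.assert_allclose(predict(ours, X), ref.predict(X), atol=1e-4)

    def test_lv_bound_enforced(self):
        X, Y = _random_instance(1)
        with pytest.raises(ValueError):
            fit_pls(X, Y, 9)
        with pytest.raises(ValueError):
            fit_pls(X, Y, 0)


class TestPredict:
    def test_training_recovery_and_mean_spectrum(self):
        X, Y = _random_instance(3, noise=0.0)
        model = fit_pls(X, Y, 8)
        np.testing.assert_allclose(predict(model, X), Y, atol=1e-8)
        np.testing.assert_allclose(
            predict(model, X.mean(axis=0)), Y.mean(axis=0)[None, :], atol=1e-8
        )

    def test_prediction_affine_in_input(self):
        X, Y = _random_instance(4, noise=0.2)
        model = fit_pls(X, Y, 4)
        x1, x2, a = X[0], X[1], 0.3
        p1, p2 = predict(model, x1), predict(model, x2)
        np.testing.assert_allclose(
            predict(model, a * x1 + (1 - a) * x2), a * p1 + (1 - a) * p2, atol=1e-10
        )

    def test_channel_mismatch_rejected(self):
        X, Y = _random_instance(2)
        model = fit_pls(X, Y, 3)
        with pytest.raises(ValueError, match="channel"):
            predict(model, np.ones(5))

    def test_predict_all_consistent_with_single_sizes(self):
        X, Y = _random_instance(6, noise=0.3)
        model = fit_pls(X, Y, 6)
        allp = predict_all(model, X)
        for a in (1, 3, 6):
            np.testing.assert_allclose(allp[a - 1], predict(model, X, a), atol=1e-12)


class TestComputeMetrics:
    def test_perfect_and_mean_predictions(self):
        y = np.array([0.1, 0.2, 0.3, 0.4])
        q2, rmse = compute_metrics(y, y.copy())
        assert q2[0] == pytest.approx(1.0) and rmse[0] == pytest.approx(0.0)
        q2, _ = compute_metrics(y, np.full(4, y.mean()))
        assert q2[0] == pytest.approx(0.0)

    def test_hand_computed_rmse(self):
        known = np.array([0.1, 0.2, 0.3, 0.4])
        pred = np.array([0.1, 0.2, 0.3, 0.5])
        _, rmse = compute_metrics(known, pred)
        assert rmse[0] == pytest.approx(0.05)

    def test_q2_rmse_consistency_identity(self):
        rng = np.random.default_rng(0)
        known = rng.uniform(size=25)
        pred = known + rng.normal(0, 0.1, 25)
        q2, rmse = compute_metrics(known, pred)
        tss = ((known - known.mean()) ** 2).sum()
        assert q2[0] == pytest.approx(1 - rmse[0] ** 2 * 25 / tss)

    def test_zero_variance_known_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(np.ones(5), np.arange(5.0))


class TestDoubleCV:
    def _leveled(self, seed, n_levels=6, reps=3, p=10, noise=0.0):
        rng = np.random.default_rng(seed)
        levels = np.linspace(0.1, 1.0, n_levels)
        y = np.repeat(levels, reps)
        basis = rng.normal(size=(2, p))
        X = np.outer(y, basis[0]) + np.outer(np.sqrt(y), basis[1])
        X = X + noise * rng.normal(size=X.shape)
        return X, y

    def test_noiseless_data_is_predicted_almost_perfectly(self):
        X, y = self._leveled(0)
        cv = double_cv_loco(X, y, [1, 2, 3])
        assert cv.q2_cv[0] > 0.999

    def test_outer_fold_count_equals_level_count(self):
        X, y = self._leveled(1, n_levels=7)
        cv = double_cv_loco(X, y, [1, 2])
        assert cv.n_outer_folds == 7

    def test_permuted_response_has_no_predictive_power(self):
        q2s = []
        for rep in range(10):
            X, y = self._leveled(rep, noise=0.05)
            rng = np.random.default_rng(100 + rep)
            y_perm = y[rng.permutation(len(y))]
            try:
                cv = double_cv_loco(X, y_perm, [1, 2, 3])
                q2s.append(cv.q2_cv[0])
            except ValueError:
                pass  # a permutation may collapse level structure
        assert np.mean(q2s) <= 0.2

    def test_capped_folds_still_cover_every_sample(self):
        X, y = self._leveled(2, n_levels=12)
        cv = double_cv_loco(X, y, [1, 2], max_outer_folds=4, max_inner_folds=3)
        assert cv.n_outer_folds == 4
        assert np.all(np.isfinite(cv.predictions))

    def test_single_level_rejected(self):
        X = np.random.default_rng(0).normal(size=(6, 4))
        with pytest.raises(ValueError):
            double_cv_loco(X, np.ones(6), [1])


class TestBootstrap:
    def test_noiseless_pooled_q2_near_one(self):
        X, Y = _random_instance(0, n=30, p=6, noise=0.0)
        boot = bootstrap_validate(X, Y, 6, n_resamples=30, seed=0)
        assert boot.q2_test[0] > 0.999

    def test_oob_fraction_matches_combinatorial_expectation(self):
        n = 360
        rng = np.random.default_rng(1)
        X = rng.normal(size=(n, 4))
        y = X @ rng.normal(size=4)
        boot = bootstrap_validate(X, y, 2, n_resamples=200, seed=2)
        # a with-replacement draw of n leaves (1 - 1/n)^n ~ 36.8% of rows
        # out-of-bag, i.e. 1 - (1 - 1/n)^n ~ 0.632 of rows in-bag
        unique_in_bag = 1 - boot.mean_oob_fraction
        assert unique_in_bag == pytest.approx(1 - (1 - 1 / n) ** n, rel=0.02)
        assert boot.all_oob

    def test_same_seed_reproduces_identical_result(self):
        X, Y = _random_instance(3, noise=0.5)
        a = bootstrap_validate(X, Y, 3, n_resamples=25, seed=9)
        b = bootstrap_validate(X, Y, 3, n_resamples=25, seed=9)
        assert np.array_equal(a.oob_mean, b.oob_mean, equal_nan=True)
        assert np.array_equal(a.q2_test, b.q2_test)
        assert np.array_equal(a.rmsep, b.rmsep)


class TestPLSLoD:
    def test_zero_residuals_give_zero_lod(self):
        known = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.1, 0.2, 0.3, 0.4, 0.5])
        est = pls_lod(known, known.copy())
        assert est.value == pytest.approx(0.0, abs=1e-12)

    def test_matches_closed_form_on_average(self):
        # Monte-Carlo oracle of the capability-of-detection closed form
        rng = np.random.default_rng(0)
        known = np.tile(np.linspace(0.1, 1.0, 8), 3)
        sigma = 0.04
        n = known.size
        xbar = known.mean()
        sxx = ((known - xbar) ** 2).sum()
        closed = 3.2897 * sigma * np.sqrt(1 + 1 / n + xbar**2 / sxx)
        vals = [
            pls_lod(known, known + rng.normal(0, sigma, n)).value
            for _ in range(200)
        ]
        assert np.mean(vals) == pytest.approx(closed, rel=0.2)

    def test_halving_noise_halves_lod(self):
        rng = np.random.default_rng(1)
        known = np.tile(np.linspace(0.1, 1.0, 8), 3)
        lods = []
        for sigma in (0.08, 0.04):
            vals = [
                pls_lod(known, known + rng.normal(0, sigma, known.size)).value
                for _ in range(200)
            ]
            lods.append(np.mean(vals))
        assert lods[0] / lods[1] == pytest.approx(2.0, rel=0.1)

    def test_t_quantile_delta_larger_than_normal(self):
        rng = np.random.default_rng(2)
        known = np.tile(np.linspace(0.1, 1.0, 6), 2)
        pred = known + rng.normal(0, 0.05, known.size)
        assert pls_lod(known, pred, delta_method="t").value > \
            pls_lod(known, pred, delta_method="normal").value

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            pls_lod(np.array([1, 2, 3, 4.0]), np.array([1, 2, 3, 4.0]))
        known = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        with pytest.raises(ValueError, match="slope"):
            pls_lod(known, -known)


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path):
        X, Y = _random_instance(4, m=2, noise=0.3)
        model = fit_pls(X, Y, 5, analytes=["a", "b"])
        model.chain = "pls_chain"
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        np.testing.assert_array_equal(back.coefficients, model.coefficients)
        assert back.analytes == ["a", "b"] and back.chain == "pls_chain"
        np.testing.assert_allclose(predict(back, X), predict(model, X))
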