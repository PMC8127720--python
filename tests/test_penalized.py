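import numpy as np
import pytest
from sklearn.base import clone
from sklearn.linear_model import ElasticNet as SkElasticNet

from belugaclock import _cd
from belugaclock.penalized import (
    CVElasticNetCD,
    ElasticNetCD,
    ElasticNetConfig,
    LassoLogisticCV,
    check_kkt,
    cv_select_lambda,
    elastic_net_objective,
    fit_elastic_net,
    fit_lasso_logistic,
    make_lambda_path,
)


def random_problem(seed, n=None, p=None, signal=3):
    rng = np.random.default_rng(seed)
    n = n or int(rng.integers(20, 61))
    p = p or int(rng.integers(5, 201))
    X = rng.standard_normal((n, p))
    y = X[:, :signal] @ rng.standard_normal(signal) + rng.standard_normal(n)
    return X, y


class TestSingleFit:
    def test_constant_response(self, rng):
        X = rng.random((15, 6))
        y = np.full(15, 7.5)
        f = fit_elastic_net(X, y, ElasticNetConfig(alpha=0.5), lam=0.1)
        assert np.all(f.coef == 0.0)
        assert f.intercept == pytest.approx(7.5)

    def test_null_model_at_lambda_max(self):
        X, y = random_problem(0, n=40, p=30)
        cfg = ElasticNetConfig(alpha=0.9)
        path = make_lambda_path(X, y, cfg)
        hi = fit_elastic_net(X, y, cfg, path[0] * (1 + 1e-9))
        lo = fit_elastic_net(X, y, cfg, path[1])
        assert hi.n_nonzero == 0
        assert hi.intercept == pytest.approx(y.mean())
        assert lo.n_nonzero >= 1

    def test_lambda_zero_matches_least_squares(self, rng):
        X = rng.standard_normal((20, 5))
        y = rng.standard_normal(20)
        f = fit_elastic_net(X, y, ElasticNetConfig(alpha=1.0, tol=1e-13), lam=0.0)
        b = np.linalg.lstsq(np.column_stack([np.ones(20), X]), y, rcond=None)[0]
        assert np.abs(np.r_[f.intercept, f.coef] - b).max() < 1e-8

    def test_lasso_on_orthonormal_design_is_soft_threshold(self, rng):
        n, p = 60, 8
        raw = rng.standard_normal((n, p))
        raw -= raw.mean(axis=0)
        Q, _ = np.linalg.qr(raw)
        X = Q * np.sqrt(n)  # standardized orthonormal columns: (1/n) X'X = I
        y = rng.standard_normal(n)
        yc = y - y.mean()
        b_ols = X.T @ yc / n
        lam = float(np.median(np.abs(b_ols)))
        f = fit_elastic_net(X, y, ElasticNetConfig(alpha=1.0, tol=1e-13), lam)
        expected = np.sign(b_ols) * np.maximum(np.abs(b_ols) - lam, 0.0)
        # the design is already standardized, so coefficients are comparable
        assert np.abs(f.coef - expected).max() < 1e-8

    def test_non_finite_input_rejected(self):
        X = np.array([[0.1, np.inf], [0.2, 0.3]])
        with pytest.raises(ValueError, match="non-finite"):
            fit_elastic_net(X, np.array([1.0, 2.0]), ElasticNetConfig(), 0.1)

    def test_zero_variance_predictor_gets_zero(self, rng):
        X = rng.standard_normal((30, 4))
        X[:, 2] = 0.77
        y = X[:, 0] + rng.standard_normal(30) * 0.1
        f = fit_elastic_net(X, y, ElasticNetConfig(alpha=0.5), 0.01)
        assert f.coef[2] == 0.0


class TestLambdaPath:
    def test_grid_shape_and_monotonicity(self):
        X, y = random_problem(1)
        cfg = ElasticNetConfig(alpha=0.7, n_lambda=55)
        path = make_lambda_path(X, y, cfg)
        assert len(path) == 55
        assert np.all(np.diff(path) < 0) and np.all(path > 0)

    def test_orthogonal_response_gives_tiny_lambda_max(self, rng):
        X = rng.standard_normal((30, 5))
        y = rng.standard_normal(30)
        # project out every centered predictor from the centered response
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        coef, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
        y_orth = yc - Xc @ coef
        path = make_lambda_path(X, y_orth, ElasticNetConfig(alpha=1.0))
        assert path[0] < 1e-10 * max(1.0, np.abs(y_orth).max()) + 1e-9

    def test_ridge_requires_explicit_grid(self):
        X, y = random_problem(2)
        with pytest.raises(ValueError, match="alpha > 0"):
            make_lambda_path(X, y, ElasticNetConfig(alpha=0.0))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ElasticNetConfig(alpha=1.5)
        with pytest.raises(ValueError):
            ElasticNetConfig(lambda_grid=np.array([0.1, 0.5]))  # ascending
        with pytest.raises(ValueError):
            ElasticNetConfig(lambda_grid=np.array([0.5, -0.1]))


class TestSolverProperties:
    def test_objective_monotone_over_sweeps(self, rng):
        X = rng.standard_normal((25, 40))
        y = rng.standard_normal(25)
        mu, sd = X.mean(0), X.std(0)
        XT = np.ascontiguousarray(((X - mu) / sd).T)
        yc = y - y.mean()
        beta = np.zeros(40)
        r = yc.copy()
        active = np.arange(40)
        lam, alpha = 0.05, 0.5
        objs = [elastic_net_objective(XT.T, yc, beta, lam, alpha)]
        for _ in range(30):
            _cd.cd_sweep(XT, r, beta, lam, alpha, active)
            objs.append(elastic_net_objective(XT.T, yc, beta, lam, alpha))
        diffs = np.diff(objs)
        assert np.all(diffs <= 1e-12)

    @pytest.mark.parametrize("seed,alpha", [(10, 0.1), (11, 0.5), (12, 0.9), (13, 1.0)])
    def test_agreement_with_reference_solver(self, seed, alpha):
        X, y = random_problem(seed)
        cfg = ElasticNetConfig(alpha=alpha, tol=1e-10)
        lam = float(make_lambda_path(X, y, cfg)[40])
        f = fit_elastic_net(X, y, cfg, lam)
        mu, sd = X.mean(0), X.std(0)
        sk = SkElasticNet(alpha=lam, l1_ratio=alpha, tol=1e-12,
                          max_iter=500_000).fit((X - mu) / sd, y)
        ours_std = f.coef * sd
        scale = max(np.abs(sk.coef_).max(), 1e-8)
        assert np.abs(ours_std - sk.coef_).max() / scale < 1e-6

    @pytest.mark.parametrize("seed", [21, 22, 23])
    def test_kkt_conditions_hold(self, seed):
        X, y = random_problem(seed)
        cfg = ElasticNetConfig(alpha=0.9)
        path = make_lambda_path(X, y, cfg)
        for lam in (path[10], path[60]):
            f = fit_elastic_net(X, y, cfg, float(lam))
            assert check_kkt(X, y, f) < 1e-5

    def test_warm_path_continuity_under_refinement(self):
        X, y = random_problem(30, n=50, p=80)

        def max_adjacent_jump(n_lambda):
            cfg = ElasticNetConfig(alpha=0.9, n_lambda=n_lambda)
            lambdas = make_lambda_path(X, y, cfg)
            from belugaclock.penalized import _path_original_scale
            _, coefs, B, _ = _path_original_scale(X, y, lambdas, cfg)
            return np.abs(np.diff(B, axis=0)).max()

        coarse = max_adjacent_jump(25)
        fine = max_adjacent_jump(100)
        assert fine < coarse


class TestCVSelection:
    def test_pure_noise_prefers_near_null_models(self):
        """On pure-noise responses lambda.min can drift below the path entry
        (the CV curve is flat then noisy — the reference solver behaves the
        same way), but the null model stays within one CV standard error of
        the minimum, i.e. a 1-SE rule would select it."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(500 + seed)
            X = rng.standard_normal((50, 200))
            y = rng.standard_normal(50)
            cfg = ElasticNetConfig(alpha=0.9, rng_seed=seed)
            cv = cv_select_lambda(X, y, cfg)
            i = cv.lambda_min_index
            null_within_1se = (cv.mean_cv_error[0]
                               <= cv.mean_cv_error[i] + cv.cv_se[i])
            hits += null_within_1se
        assert hits >= 8

    def test_strong_signal_selects_small_lambda_and_predictor(self):
        rng = np.random.default_rng(77)
        X = rng.standard_normal((100, 50))
        y = 3.0 * X[:, 0] + rng.standard_normal(100) * 0.3
        cfg = ElasticNetConfig(alpha=0.9, rng_seed=1)
        path = make_lambda_path(X, y, cfg)
        cv = cv_select_lambda(X, y, cfg, path)
        assert cv.lambda_min < path[0] / 10
        f = fit_elastic_net(X, y, cfg, cv.lambda_min)
        assert f.coef[0] != 0.0

    def test_same_seed_identical_result(self):
        X, y = random_problem(40, n=45, p=60)
        cfg = ElasticNetConfig(alpha=0.5, rng_seed=9)
        cv1 = cv_select_lambda(X, y, cfg)
        cv2 = cv_select_lambda(X, y, cfg)
        assert cv1.lambda_min == cv2.lambda_min
        np.testing.assert_array_equal(cv1.fold_assignment, cv2.fold_assignment)
        np.testing.assert_array_equal(cv1.mean_cv_error, cv2.mean_cv_error)

    def test_tie_goes_to_larger_lambda(self):
        # at and above the path entry all models are null, so CV errors tie
        X, y = random_problem(41, n=40, p=20)
        cfg = ElasticNetConfig(alpha=0.9, rng_seed=2)
        entry = make_lambda_path(X, y, cfg)[0]
        grid = np.array([entry * 8, entry * 4, entry * 2])
        cv = cv_select_lambda(X, y, cfg, grid)
        assert cv.lambda_min == grid[0]

    def test_fold_sizes_and_errors(self):
        X, y = random_problem(42, n=23, p=10)
        cfg = ElasticNetConfig(alpha=0.9, cv_folds=10, rng_seed=0)
        cv = cv_select_lambda(X, y, cfg)
        sizes = np.bincount(cv.fold_assignment)
        assert sizes.max() - sizes.min() <= 1
        with pytest.raises(ValueError, match="< 2 samples"):
            cv_select_lambda(X[:15], y[:15], ElasticNetConfig(cv_folds=10))
        with pytest.raises(ValueError, match="exceed"):
            cv_select_lambda(X[:5], y[:5], ElasticNetConfig(cv_folds=10))


class TestLassoLogistic:
    def test_single_dominant_predictor_selected(self, rng):
        n = 60
        y = (rng.random(n) < 0.5).astype(float)
        X = rng.standard_normal((n, 20)) * 0.3
        X[:, 7] = 0.9 - 0.45 * y + rng.normal(0, 0.02, n)  # anti-correlated
        fit, cv = fit_lasso_logistic(X, y, ElasticNetConfig(alpha=1.0, rng_seed=5))
        assert set(np.flatnonzero(fit.coef)) == {7}
        assert fit.coef[7] < 0
        pred = (1 / (1 + np.exp(-(fit.intercept + X @ fit.coef))) > 0.5)
        assert np.array_equal(pred.astype(float), y)

    def test_shuffled_labels_give_near_null_models(self):
        """With labels shuffled against the predictors the selected model is
        intercept-only, or at worst the null model sits within one CV
        standard error of the deviance minimum."""
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(900 + seed)
            X = rng.standard_normal((60, 40))
            y = rng.permutation(np.repeat([0.0, 1.0], 30))
            fit, cv = fit_lasso_logistic(X, y, ElasticNetConfig(alpha=1.0, rng_seed=seed))
            i = cv.lambda_min_index
            ok = fit.n_nonzero == 0 or (
                cv.mean_cv_error[0] <= cv.mean_cv_error[i] + cv.cv_se[i])
            hits += ok
        assert hits >= 4

    def test_no_informative_predictors_gives_class_frequency_intercept(self):
        X = np.full((30, 5), 0.5)  # zero-variance predictors
        y = np.repeat([0.0, 1.0], 15)
        fit, _ = fit_lasso_logistic(X, y, ElasticNetConfig(alpha=1.0, rng_seed=0))
        assert fit.n_nonzero == 0
        assert fit.intercept == pytest.approx(0.0, abs=1e-6)  # logit(0.5)

    def test_single_class_rejected(self, rng):
        X = rng.random((20, 3))
        with pytest.raises(ValueError, match="both classes"):
            fit_lasso_logistic(X, np.ones(20), ElasticNetConfig())

    def test_non_binary_labels_rejected(self, rng):
        X = rng.random((20, 3))
        with pytest.raises(ValueError, match="0/1"):
            fit_lasso_logistic(X, rng.random(20), ElasticNetConfig())

    def test_separation_never_returns_lambda_zero(self, rng):
        # perfectly separable single predictor
        y = np.repeat([0.0, 1.0], 15)
        X = np.column_stack([y * 0.5 + 0.2, rng.random(30)])
        fit, cv = fit_lasso_logistic(X, y, ElasticNetConfig(alpha=1.0, rng_seed=3))
        assert cv.lambda_min > 0
        assert np.all(np.isfinite(fit.coef))


class TestEstimatorProtocol:
    def test_clone_and_params_roundtrip(self):
        est = CVElasticNetCD(alpha=0.3, cv_folds=5, random_state=4)
        params = est.get_params()
        est2 = clone(est)
        assert est2.get_params() == params
        est2.set_params(alpha=0.8)
        assert est2.alpha == 0.8 and est.alpha == 0.3

    def test_fixed_lambda_estimator_fits_and_predicts(self):
        X, y = random_problem(50, n=40, p=12)
        est = ElasticNetCD(alpha=0.9, lam=0.05).fit(X, y)
        assert est.coef_.shape == (12,)
        assert est.predict(X).shape == (40,)
        assert est.converged_

    def test_cv_estimator_matches_function_api(self):
        X, y = random_problem(51, n=50, p=30)
        est = CVElasticNetCD(alpha=0.9, random_state=7).fit(X, y)
        cfg = ElasticNetConfig(alpha=0.9, rng_seed=7)
        cv = cv_select_lambda(X, y, cfg)
        assert est.lambda_min_ == cv.lambda_min
        f = fit_elastic_net(X, y, cfg, cv.lambda_min)
        np.testing.assert_allclose(est.coef_, f.coef, atol=1e-10)

    def test_logistic_estimator_threshold(self, rng):
        n = 40
        y = np.repeat([0.0, 1.0], 20)
        X = rng.standard_normal((n, 5)) * 0.1
        X[:, 0] += y
        est = LassoLogisticCV(random_state=2).fit(X, y)
        proba = est.predict_proba(X)
        assert proba.shape == (n, 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        assert np.array_equal(est.predict(X), (proba[:, 1] > 0.5).astype(float))
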