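"""Elastic-net linear regression and LASSO logistic regression.

Solvers are implemented from scratch by cyclic coordinate descent on
standardized predictors (mean 0, population 1/n variance 1), with an
unpenalized intercept and the objective

    (1/2n) * RSS + lambda * [ (1 - alpha)/2 * ||b||_2^2 + alpha * ||b||_1 ]

where ``alpha`` is the mixing parameter between ridge (alpha = 0) and lasso
(alpha = 1) and ``lambda`` the penalty strength. Coefficients are
back-transformed to the original predictor scale after fitting. Lambda is
chosen on a log-spaced path from ``lambda_max`` (the smallest penalty with an
all-zero solution) by k-fold cross-validation, taking the grid value with
minimal mean CV error ("lambda.min"); ties go to the larger lambda (the
sparser model).

The public surface follows the scikit-learn estimator protocol
(:class:`ElasticNetCD`, :class:`CVElasticNetCD`, :class:`LassoLogisticCV`);
the module-level functions are thin wrappers kept for pipeline use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin

from . import _cd

__all__ = [
    "ElasticNetConfig",
    "ElasticNetFit",
    "CVResult",
    "ElasticNetCD",
    "CVElasticNetCD",
    "LassoLogisticCV",
    "fit_elastic_net",
    "make_lambda_path",
    "cv_select_lambda",
    "fit_lasso_logistic",
    "check_kkt",
    "elastic_net_objective",
]


@dataclass
class ElasticNetConfig:
    """Solver and cross-validation settings.

    ``alpha`` is the elastic-net mixing parameter in [0, 1]; ``tol`` is the
    convergence threshold on the maximum standardized-coefficient change per
    sweep; ``lambda_min_ratio`` defaults to 0.01 when predictors outnumber
    samples and 1e-4 otherwise.
    """

    alpha: float = 0.9
    lambda_grid: np.ndarray | None = None
    n_lambda: int = 100
    lambda_min_ratio: float | None = None
    tol: float = 1e-7
    max_iter: int = 100_000
    cv_folds: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must be in [0, 1]")
        if self.lambda_grid is not None:
            g = np.asarray(self.lambda_grid, dtype=float)
            if np.any(g <= 0) or np.any(np.diff(g) >= 0):
                raise ValueError("lambda_grid must be strictly positive and descending")
            self.lambda_grid = g

    def min_ratio(self, n: int, p: int) -> float:
        if self.lambda_min_ratio is not None:
            return self.lambda_min_ratio
        return 0.01 if p >= n else 1e-4


@dataclass
class ElasticNetFit:
    """Solver output on the original predictor scale."""

    intercept: float
    coef: np.ndarray
    alpha: float
    lam: float
    converged: bool
    objective: float
    trait: str = "age_linear"
    feature_names: list[str] | None = None

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.coef))

    @property
    def coefficients(self) -> dict[str, float]:
        names = self.feature_names or [f"x{j}" for j in range(len(self.coef))]
        return {n: float(c) for n, c in zip(names, self.coef)}

    def nonzero_coefficients(self) -> dict[str, float]:
        return {n: c for n, c in self.coefficients.items() if c != 0.0}

    def predict_linear(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(X, float) @ self.coef


@dataclass
class CVResult:
    """Record of a cross-validated lambda selection."""

    lambda_grid: np.ndarray
    mean_cv_error: np.ndarray
    cv_se: np.ndarray
    lambda_min: float
    fold_assignment: np.ndarray
    alpha: float
    metric: str = "mse"
    coef_path: np.ndarray | None = field(default=None, repr=False)

    @property
    def lambda_min_index(self) -> int:
        return int(np.flatnonzero(self.lambda_grid == self.lambda_min)[0])


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------

def _as_2d(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional (samples x predictors)")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    return X


def _standardize(X: np.ndarray):
    """Center and scale columns by the population (1/n) standard deviation.

    Zero-variance columns become all-zero (their coefficients stay 0)."""
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # population, matching the reference solver convention
    sd_safe = np.where(sd > 0, sd, 1.0)
    Xs = (X - mean) / sd_safe
    XT = np.ascontiguousarray(Xs.T)
    return XT, mean, sd_safe, sd > 0


def _backtransform(b_std: np.ndarray, mean, sd_safe, ybar: float):
    coef = b_std / sd_safe
    intercept = ybar - float(coef @ mean)
    return intercept, coef


def elastic_net_objective(Xs: np.ndarray, yc: np.ndarray, b: np.ndarray,
                          lam: float, alpha: float) -> float:
    """Standardized-scale objective value (what the solver minimizes)."""
    n = len(yc)
    r = yc - Xs @ b
    penalty = lam * ((1 - alpha) / 2 * float(b @ b) + alpha * float(np.abs(b).sum()))
    return float(r @ r) / (2 * n) + penalty


def make_lambda_path(X, y, cfg: ElasticNetConfig) -> np.ndarray:
    """Descending log-spaced grid from lambda_max down to
    lambda_max * lambda_min_ratio.

    lambda_max = max_j |<standardized x_j, y - ybar>| / (n * alpha), the
    smallest penalty at which every coefficient is zero. Requires alpha > 0
    (at alpha = 0 no finite penalty nulls the model; supply a grid).
    """
    if cfg.lambda_grid is not None:
        return cfg.lambda_grid
    if cfg.alpha <= 0.0:
        raise ValueError("lambda path construction requires alpha > 0; "
                         "supply lambda_grid explicitly for ridge")
    X = _as_2d(X)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    XT, _, _, _ = _standardize(X)
    yc = y - y.mean()
    lam_max = float(np.max(np.abs(XT @ yc)) / (n * cfg.alpha))
    lam_max = max(lam_max, 1e-10)
    return np.geomspace(lam_max, lam_max * cfg.min_ratio(n, p), cfg.n_lambda)


def fit_elastic_net(X, y, cfg: ElasticNetConfig, lam: float,
                    feature_names: Sequence[str] | None = None) -> ElasticNetFit:
    """Solve the elastic-net problem at a single penalty value."""
    X = _as_2d(X)
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite values")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    XT, mean, sd_safe, _ = _standardize(X)
    ybar = y.mean()
    yc = y - ybar
    beta = np.zeros(X.shape[1])
    _, converged, _r = _cd.cd_single(XT, yc, float(lam), cfg.alpha,
                                     cfg.tol, cfg.max_iter, beta)
    obj = elastic_net_objective(XT.T, yc, beta, lam, cfg.alpha)
    intercept, coef = _backtransform(beta, mean, sd_safe, ybar)
    return ElasticNetFit(
        intercept=intercept, coef=coef, alpha=cfg.alpha, lam=float(lam),
        converged=bool(converged), objective=obj,
        feature_names=list(feature_names) if feature_names is not None else None,
    )


def _path_original_scale(X, y, lambdas, cfg: ElasticNetConfig):
    """Fit the full path; return (intercepts, coefs) on the original scale
    plus the standardized-scale coefficients."""
    XT, mean, sd_safe, _ = _standardize(X)
    ybar = y.mean()
    yc = y - ybar
    B, n_iter, conv = _cd.enet_path(XT, yc, np.asarray(lambdas, float),
                                    cfg.alpha, cfg.tol, cfg.max_iter)
    coefs = B / sd_safe
    intercepts = ybar - coefs @ mean
    return intercepts, coefs, B, conv


def _fold_assignment(n: int, k: int, seed: int) -> np.ndarray:
    """Seeded shuffle into k folds with sizes differing by at most one."""
    if k > n:
        raise ValueError("cv_folds may not exceed the number of samples")
    if k < 2:
        raise ValueError("need at least 2 folds")
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    if sizes.min() < 2:
        raise ValueError(f"{k}-fold split of {n} samples leaves a fold with < 2 samples")
    perm = np.random.default_rng(seed).permutation(n)
    fold = np.empty(n, dtype=np.int64)
    start = 0
    for f, s in enumerate(sizes):
        fold[perm[start:start + s]] = f
        start += s
    return fold


def cv_select_lambda(X, y, cfg: ElasticNetConfig,
                     lambdas: np.ndarray | None = None) -> CVResult:
    """k-fold cross-validated lambda selection for the gaussian model.

    The per-lambda CV error is the unweighted mean of per-fold mean squared
    prediction errors; its SE is taken across folds. ``lambda_min`` is the
    grid value minimizing the mean CV error; exact ties resolve to the larger
    (sparser) lambda.
    """
    X = _as_2d(X)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if lambdas is None:
        lambdas = make_lambda_path(X, y, cfg)
    lambdas = np.asarray(lambdas, float)
    fold = _fold_assignment(n, cfg.cv_folds, cfg.rng_seed)
    k = cfg.cv_folds
    fold_mse = np.empty((k, len(lambdas)))
    for f in range(k):
        tr = fold != f
        te = ~tr
        b0s, coefs, _, _ = _path_original_scale(X[tr], y[tr], lambdas, cfg)
        preds = X[te] @ coefs.T + b0s  # (n_te, L)
        fold_mse[f] = np.mean((preds - y[te, None]) ** 2, axis=0)
    mean_err = fold_mse.mean(axis=0)
    se = fold_mse.std(axis=0, ddof=1) / np.sqrt(k)
    # grid is descending, so the first argmin is the largest lambda among ties
    lam_min = float(lambdas[int(np.argmin(mean_err))])
    return CVResult(
        lambda_grid=lambdas, mean_cv_error=mean_err, cv_se=se,
        lambda_min=lam_min, fold_assignment=fold, alpha=cfg.alpha,
        metric="mse",
    )


def check_kkt(X, y, fit: ElasticNetFit, tol: float = 1e-6) -> float:
    """Maximum KKT violation of a gaussian elastic-net fit.

    On the standardized scale: for zero coefficients the score must satisfy
    |g_j| <= lambda * alpha; for nonzero ones
    g_j - lambda * alpha * sign(b_j) - lambda * (1 - alpha) * b_j = 0,
    with g_j = (1/n) <x_j, residual>. Returns the largest violation (0 when
    all conditions hold within ``tol``)."""
    X = _as_2d(X)
    y = np.asarray(y, dtype=float)
    XT, mean, sd_safe, nz = _standardize(X)
    yc = y - y.mean()
    b_std = fit.coef * sd_safe
    r = yc - XT.T @ b_std
    g = (XT @ r) / len(y)
    lam, alpha = fit.lam, fit.alpha
    viol = np.zeros_like(g)
    zero = b_std == 0
    viol[zero] = np.maximum(np.abs(g[zero]) - lam * alpha, 0.0)
    nzm = ~zero
    viol[nzm] = np.abs(g[nzm] - lam * alpha * np.sign(b_std[nzm])
                       - lam * (1 - alpha) * b_std[nzm])
    viol[~nz] = 0.0  # zero-variance predictors carry no condition
    return float(np.max(viol)) if len(viol) else 0.0


# ---------------------------------------------------------------------------
# logistic family
# ---------------------------------------------------------------------------

def _binomial_deviance(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-10, 1 - 1e-10)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def fit_lasso_logistic(X, y_binary, cfg: ElasticNetConfig,
                       feature_names: Sequence[str] | None = None,
                       ) -> tuple[ElasticNetFit, CVResult]:
    """LASSO (or elastic-net) logistic regression with CV lambda selection.

    The binomial log-likelihood is maximized by IRLS with an inner penalized
    weighted coordinate descent; lambda is selected on a warm-started path by
    k-fold cross-validated binomial deviance. The linear predictor feeds the
    inverse logit: p = 1 / (1 + exp(-eta)). The path never includes
    lambda = 0, so complete separation cannot drive the solution off to
    infinity.
    """
    X = _as_2d(X)
    y = np.asarray(y_binary, dtype=float)
    classes = np.unique(y)
    if not np.all(np.isin(classes, (0.0, 1.0))):
        raise ValueError("y must be coded 0/1")
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    n = X.shape[0]
    if cfg.alpha <= 0.0:
        raise ValueError("logistic path requires alpha > 0")
    XT, mean, sd_safe, _ = _standardize(X)
    pbar = y.mean()
    lam_max = float(np.max(np.abs(XT @ (y - pbar))) / (n * cfg.alpha))
    lam_max = max(lam_max, 1e-10)
    lambdas = (cfg.lambda_grid if cfg.lambda_grid is not None
               else np.geomspace(lam_max, lam_max * cfg.min_ratio(n, X.shape[1]),
                                 cfg.n_lambda))
    fold = _fold_assignment(n, cfg.cv_folds, cfg.rng_seed)
    k = cfg.cv_folds
    fold_dev = np.empty((k, len(lambdas)))
    for f in range(k):
        tr = fold != f
        te = ~tr
        XTtr, m_tr, s_tr, _ = _standardize(X[tr])
        B, b0s, _ = _cd.logistic_path(XTtr, y[tr], lambdas, cfg.alpha,
                                      cfg.tol, cfg.max_iter)
        coefs = B / s_tr
        intercepts = b0s - coefs @ m_tr
        etas = X[te] @ coefs.T + intercepts
        probs = 1.0 / (1.0 + np.exp(-etas))
        for li in range(len(lambdas)):
            fold_dev[f, li] = _binomial_deviance(y[te], probs[:, li])
    mean_err = fold_dev.mean(axis=0)
    se = fold_dev.std(axis=0, ddof=1) / np.sqrt(k)
    idx = int(np.argmin(mean_err))
    lam_min = float(lambdas[idx])
    # final fit on all samples at lambda.min
    B, b0s, conv = _cd.logistic_path(XT, y, lambdas[: idx + 1], cfg.alpha,
                                     cfg.tol, cfg.max_iter)
    b_std = B[idx]
    coef = b_std / sd_safe
    intercept = float(b0s[idx] - coef @ mean)
    eta = intercept + X @ coef
    fit = ElasticNetFit(
        intercept=intercept, coef=coef, alpha=cfg.alpha, lam=lam_min,
        converged=bool(conv[idx]),
        objective=_binomial_deviance(y, 1.0 / (1.0 + np.exp(-eta))) / 2.0,
        trait="sex_logistic",
        feature_names=list(feature_names) if feature_names is not None else None,
    )
    cv = CVResult(lambda_grid=lambdas, mean_cv_error=mean_err, cv_se=se,
                  lambda_min=lam_min, fold_assignment=fold, alpha=cfg.alpha,
                  metric="binomial_deviance")
    return fit, cv


# ---------------------------------------------------------------------------
# scikit-learn estimator facade
# ---------------------------------------------------------------------------

class ElasticNetCD(RegressorMixin, BaseEstimator):
    """Elastic-net linear regression at a fixed penalty, by coordinate descent.

    Parameters
    ----------
    alpha : float, mixing parameter (0 = ridge, 1 = lasso).
    lam : float, penalty strength.
    tol, max_iter : convergence control (max standardized-coefficient change).
    """

    def __init__(self, alpha: float = 0.9, lam: float = 1.0,
                 tol: float = 1e-7, max_iter: int = 100_000):
        self.alpha = alpha
        self.lam = lam
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        cfg = ElasticNetConfig(alpha=self.alpha, tol=self.tol, max_iter=self.max_iter)
        f = fit_elastic_net(X, y, cfg, self.lam)
        self.coef_ = f.coef
        self.intercept_ = f.intercept
        self.converged_ = f.converged
        self.objective_ = f.objective
        self.n_nonzero_ = f.n_nonzero
        self.fit_result_ = f
        self.n_features_in_ = len(f.coef)
        return self

    def predict(self, X):
        return self.intercept_ + np.asarray(X, float) @ self.coef_


class CVElasticNetCD(RegressorMixin, BaseEstimator):
    """Elastic-net regression with path construction and k-fold CV selection
    of lambda ("lambda.min"), then a final fit on all samples."""

    def __init__(self, alpha: float = 0.9, n_lambda: int = 100,
                 lambda_min_ratio: float | None = None, cv_folds: int = 10,
                 tol: float = 1e-7, max_iter: int = 100_000,
                 random_state: int = 0):
        self.alpha = alpha
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        self.cv_folds = cv_folds
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def _config(self) -> ElasticNetConfig:
        return ElasticNetConfig(
            alpha=self.alpha, n_lambda=self.n_lambda,
            lambda_min_ratio=self.lambda_min_ratio, cv_folds=self.cv_folds,
            tol=self.tol, max_iter=self.max_iter, rng_seed=self.random_state,
        )

    def fit(self, X, y):
        cfg = self._config()
        X = _as_2d(X)
        y = np.asarray(y, dtype=float)
        lambdas = make_lambda_path(X, y, cfg)
        cv = cv_select_lambda(X, y, cfg, lambdas)
        idx = cv.lambda_min_index
        b0s, coefs, _, conv = _path_original_scale(X, y, lambdas[: idx + 1], cfg)
        self.cv_result_ = cv
        self.lambda_path_ = lambdas
        self.lambda_min_ = cv.lambda_min
        self.coef_ = coefs[idx]
        self.intercept_ = float(b0s[idx])
        self.converged_ = bool(conv[idx])
        self.n_nonzero_ = int(np.count_nonzero(self.coef_))
        self.n_features_in_ = X.shape[1]
        XT, mean, sd_safe, _ = _standardize(X)
        obj = elastic_net_objective(XT.T, y - y.mean(), self.coef_ * sd_safe,
                                    cv.lambda_min, cfg.alpha)
        self.fit_result_ = ElasticNetFit(
            intercept=self.intercept_, coef=self.coef_, alpha=cfg.alpha,
            lam=cv.lambda_min, converged=self.converged_,
            objective=obj,
        )
        return self

    def predict(self, X):
        return self.intercept_ + np.asarray(X, float) @ self.coef_


class LassoLogisticCV(ClassifierMixin, BaseEstimator):
    """L1-penalized logistic regression with CV-selected lambda.

    ``predict`` returns 1 where the predicted probability exceeds 0.5
    (probability exactly 0.5 maps to class 0)."""

    def __init__(self, alpha: float = 1.0, n_lambda: int = 100,
                 lambda_min_ratio: float | None = None, cv_folds: int = 10,
                 tol: float = 1e-7, max_iter: int = 100_000,
                 random_state: int = 0):
        self.alpha = alpha
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        self.cv_folds = cv_folds
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y):
        cfg = ElasticNetConfig(
            alpha=self.alpha, n_lambda=self.n_lambda,
            lambda_min_ratio=self.lambda_min_ratio, cv_folds=self.cv_folds,
            tol=self.tol, max_iter=self.max_iter, rng_seed=self.random_state,
        )
        f, cv = fit_lasso_logistic(X, y, cfg)
        self.coef_ = f.coef
        self.intercept_ = f.intercept
        self.lambda_min_ = cv.lambda_min
        self.cv_result_ = cv
        self.fit_result_ = f
        self.classes_ = np.array([0.0, 1.0])
        self.n_features_in_ = len(f.coef)
        return self

    def decision_function(self, X):
        return self.intercept_ + np.asarray(X, float) @ self.coef_

    def predict_proba(self, X):
        p1 = 1.0 / (1.0 + np.exp(-self.decision_function(X)))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] > 0.5).astype(float)
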