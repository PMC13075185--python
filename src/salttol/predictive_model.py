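"""Regularized prediction of the multi-trait tolerance score from STIs.

The model family is penalized least squares in the glmnet parameterization,

    (1/2n) * sum_i (y_i - b0 - x_i'b)^2
        + lambda * (alpha * ||b||_1 + (1 - alpha)/2 * ||b||_2^2),

with mixing alpha = 1 for the LASSO, 0 for Ridge and intermediate values for
the Elastic Net. Predictors are standardized internally (mean 0, variance 1
with the 1/n convention) and coefficients are reported back-transformed to
the original predictor scale, so exported prediction equations apply to raw
STIs. Optimization is cyclic coordinate descent with soft-thresholding,
warm-started along a decreasing lambda path; alpha and lambda are chosen by
seeded k-fold cross-validation on mean squared error, recording both the
minimizing lambda and the one-standard-error lambda.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

log = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# multicollinearity diagnostics

def vif(X, names: list[str] | None = None) -> pd.Series:
    """Variance inflation factor per predictor: 1 / (1 - R2_j) with R2_j
    from OLS of column j on the remaining columns.

    Exactly collinear predictors get +inf with a logged warning.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more rows than predictors")
    if names is None:
        names = [f"x{j}" for j in range(p)]
    if np.any(np.std(X, axis=0) == 0):
        raise ValueError("constant column in predictor matrix")
    out = np.empty(p)
    for j in range(p):
        yj = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        sst = np.sum((yj - yj.mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / sst
        if r2 >= 1.0 - 1e-12:
            log.warning("predictor %r is exactly collinear; VIF = inf",
                        names[j])
            out[j] = np.inf
        else:
            out[j] = 1.0 / (1.0 - r2)
    return pd.Series(out, index=names, name="vif")


# ----------------------------------------------------------------------
# stratified split

def stratified_split(labels, train_fraction: float = 0.8,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Per-class train/test split without replacement.

    Train count per class is floor(fraction * class size); a singleton class
    goes entirely to training (an empty training class would harm
    stratification more than an empty test class). Returns integer index
    arrays (train, test), disjoint and exhaustive.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls in pd.unique(labels):
        idx = np.where(labels == cls)[0]
        if len(idx) == 0:  # pragma: no cover - unique() never yields empties
            continue
        if len(idx) == 1:
            log.warning("class %r has a single member; assigned to training",
                        cls)
            train.extend(idx)
            continue
        perm = rng.permutation(idx)
        k = int(np.floor(train_fraction * len(idx)))
        if k == 0:
            log.warning("class %r too small for the train fraction; "
                        "assigned to training", cls)
            k = len(idx)
        train.extend(perm[:k])
        test.extend(perm[k:])
    return np.sort(np.array(train, int)), np.sort(np.array(test, int))


# ----------------------------------------------------------------------
# coordinate-descent elastic net

def soft_threshold(z: float, gamma: float) -> float:
    return np.sign(z) * max(abs(z) - gamma, 0.0)


def _standardize(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)  # 1/n convention, as glmnet
    if np.any(sd == 0):
        raise ValueError("constant predictor column")
    Xs = (X - mu) / sd
    ybar = y.mean()
    return Xs, y - ybar, mu, sd, ybar


def _cd_solve(Xs, yc, alpha, lam, beta0=None, tol=1e-7, max_iter=100_000,
              track_objective=False):
    """Cyclic coordinate descent on standardized, centered data.

    Uses covariance updates: the sweep works on the Gram matrix X'X/n and
    the correlation vector X'y/n, so each coordinate update costs O(p)
    regardless of n. Returns (beta, n_sweeps, objective_path); convergence
    when the largest coefficient change in a sweep is below tol.
    """
    n, p = Xs.shape
    G = Xs.T @ Xs / n
    c = Xs.T @ yc / n
    yty = float(yc @ yc) / n
    return _cd_solve_gram(G, c, yty, alpha, lam, beta0=beta0, tol=tol,
                          max_iter=max_iter, track_objective=track_objective)


try:  # JIT-compiled sweep kernel; the Python loop below is the reference
    from numba import njit

    @njit(cache=False)
    def _cd_sweeps(G, gram_diag, grad, beta, l1, l2, tol, max_iter):
        p = beta.shape[0]
        for sweep in range(1, max_iter + 1):
            delta = 0.0
            for j in range(p):
                bj = beta[j]
                zj = grad[j] + gram_diag[j] * bj
                az = abs(zj) - l1
                bnew = 0.0
                if az > 0.0:
                    bnew = np.sign(zj) * az / (gram_diag[j] + l2)
                if bnew != bj:
                    for i in range(p):
                        grad[i] += G[i, j] * (bj - bnew)
                    beta[j] = bnew
                    d = abs(bnew - bj)
                    if d > delta:
                        delta = d
            if delta < tol:
                return sweep
        return -max_iter
except ImportError:  # pragma: no cover
    _cd_sweeps = None


def _cd_solve_gram(G, c, yty, alpha, lam, beta0=None, tol=1e-7,
                   max_iter=100_000, track_objective=False):
    p = len(c)
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    if _cd_sweeps is not None and not track_objective:
        G = np.ascontiguousarray(G, dtype=np.float64)
        gram_diag = np.ascontiguousarray(np.diag(G))
        grad = c - G @ beta
        sweeps = _cd_sweeps(G, gram_diag, grad, beta,
                            lam * alpha, lam * (1.0 - alpha),
                            tol, max_iter)
        if sweeps < 0:
            log.warning("coordinate descent hit max_iter=%d without "
                        "converging", max_iter)
            sweeps = -sweeps
        return beta, sweeps, []
    gram_diag = np.ascontiguousarray(np.diag(G))
    # grad_part[j] = c_j - (G beta)_j, maintained incrementally
    grad = c - G @ beta
    l1 = lam * alpha
    l2 = lam * (1.0 - alpha)
    objective = []

    def obj():
        pen = lam * (alpha * np.abs(beta).sum()
                     + 0.5 * (1 - alpha) * np.dot(beta, beta))
        loss = 0.5 * (yty - 2.0 * np.dot(c, beta) + beta @ G @ beta)
        return loss + pen

    for sweep in range(1, max_iter + 1):
        delta = 0.0
        for j in range(p):
            bj = beta[j]
            zj = grad[j] + gram_diag[j] * bj
            bnew = soft_threshold(zj, l1) / (gram_diag[j] + l2)
            if bnew != bj:
                grad += G[:, j] * (bj - bnew)
                beta[j] = bnew
                d = abs(bnew - bj)
                if d > delta:
                    delta = d
        if track_objective:
            objective.append(obj())
        if delta < tol:
            return beta, sweep, objective
    log.warning("coordinate descent hit max_iter=%d without converging",
                max_iter)
    return beta, max_iter, objective


class ElasticNetCD(BaseEstimator, RegressorMixin):
    """Glmnet-style elastic net fitted by cyclic coordinate descent.

    Parameters
    ----------
    alpha : L1/L2 mixing in [0, 1] (1 = LASSO, 0 = Ridge).
    lam : penalty strength (lambda >= 0) on the standardized scale.
    tol : convergence threshold on the largest per-sweep coefficient change.
    max_iter : maximum number of full coordinate sweeps.
    track_objective : record the penalized objective after every sweep in
        ``objective_path_`` (used to assert monotone descent).

    Fitted attributes: ``coef_`` and ``intercept_`` on the original
    predictor scale, ``n_iter_``, ``objective_path_``.
    """

    def __init__(self, alpha: float = 1.0, lam: float = 0.0, tol: float = 1e-7,
                 max_iter: int = 100_000, track_objective: bool = False):
        self.alpha = alpha
        self.lam = lam
        self.tol = tol
        self.max_iter = max_iter
        self.track_objective = track_objective

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
            raise ValueError("non-finite values in X or y")
        if X.ndim != 2 or len(y) != X.shape[0]:
            raise ValueError("X must be 2-D with one row per y element")
        if X.shape[0] < 2:
            raise ValueError("need at least 2 observations")
        if not (0.0 <= self.alpha <= 1.0) or self.lam < 0:
            raise ValueError("alpha must be in [0, 1] and lam >= 0")
        Xs, yc, mu, sd, ybar = _standardize(X, y)
        beta_std, self.n_iter_, self.objective_path_ = _cd_solve(
            Xs, yc, self.alpha, self.lam, tol=self.tol,
            max_iter=self.max_iter, track_objective=self.track_objective)
        self.coef_ = beta_std / sd
        self.intercept_ = ybar - float(self.coef_ @ mu)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        return np.asarray(X, float) @ self.coef_ + self.intercept_


def lambda_path(Xs, yc, alpha: float, n_lambdas: int = 60,
                min_ratio: float | None = None) -> np.ndarray:
    """Decreasing log-spaced lambda path starting at the smallest lambda
    that zeroes every coefficient (glmnet convention)."""
    n, p = Xs.shape
    lam_max = np.max(np.abs(Xs.T @ yc)) / (n * max(alpha, 1e-3))
    if min_ratio is None:
        min_ratio = 1e-4 if n > p else 1e-2
    return lam_max * np.logspace(0, np.log10(min_ratio), n_lambdas)


def enet_path(Xs, yc, alpha, lambdas, tol=1e-7, max_iter=100_000):
    """Warm-started coefficient path on standardized data: returns an array
    of shape (len(lambdas), p)."""
    n, p = Xs.shape
    G = Xs.T @ Xs / n
    c = Xs.T @ yc / n
    yty = float(yc @ yc) / n
    betas = np.empty((len(lambdas), p))
    beta = np.zeros(p)
    for i, lam in enumerate(lambdas):
        beta, _, _ = _cd_solve_gram(G, c, yty, alpha, lam, beta0=beta,
                                    tol=tol, max_iter=max_iter)
        betas[i] = beta
    return betas


# ----------------------------------------------------------------------
# cross-validated selection

@dataclass
class CVResult:
    alpha: float
    lambda_min: float
    lambda_1se: float
    cv_table: pd.DataFrame = field(repr=False)


def cv_select(X, y, alpha_grid=None, k: int = 10, seed: int = 0,
              n_lambdas: int = 60) -> CVResult:
    """Choose (alpha, lambda) by k-fold cross-validated MSE.

    For each alpha a shared lambda path is fitted per training fold with
    warm starts; the best alpha minimizes CV MSE at its lambda_min, and
    lambda_1se is the largest lambda on that path whose CV MSE lies within
    one standard error (over folds) of the minimum. Fold assignment is
    seeded and shared across alphas.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if alpha_grid is None or len(alpha_grid) == 0:
        alpha_grid = [round(0.1 * i, 1) for i in range(11)]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    rng = np.random.default_rng(seed)
    fold = rng.permutation(np.arange(n) % k)

    rows = []
    best = None
    for alpha in alpha_grid:
        Xs_full, yc_full, _, _, _ = _standardize(X, y)
        lambdas = lambda_path(Xs_full, yc_full, alpha, n_lambdas)
        fold_mse = np.empty((k, len(lambdas)))
        for f in range(k):
            tr, va = fold != f, fold == f
            Xs, yc, mu, sd, ybar = _standardize(X[tr], y[tr])
            betas = enet_path(Xs, yc, alpha, lambdas)
            coefs = betas / sd  # back to original scale
            inter = ybar - coefs @ mu
            pred = X[va] @ coefs.T + inter
            fold_mse[f] = np.mean((y[va][:, None] - pred) ** 2, axis=0)
        cvm = fold_mse.mean(axis=0)
        cvse = fold_mse.std(axis=0, ddof=1) / np.sqrt(k)
        i_min = int(np.argmin(cvm))
        within = np.where(cvm <= cvm[i_min] + cvse[i_min])[0]
        i_1se = int(within[0])  # lambdas decreasing: first index = largest
        for lam, m, s in zip(lambdas, cvm, cvse):
            rows.append((alpha, lam, m, s))
        cand = (cvm[i_min], alpha, lambdas[i_min], lambdas[i_1se])
        if best is None or cand[0] < best[0]:
            best = cand
    table = pd.DataFrame(rows, columns=["alpha", "lambda", "cv_mse", "cv_se"])
    return CVResult(alpha=best[1], lambda_min=float(best[2]),
                    lambda_1se=float(best[3]), cv_table=table)


# ----------------------------------------------------------------------
# reporting containers

@dataclass
class RegularizedModel:
    """A fitted penalized model on the original predictor scale."""

    alpha: float
    lambda_min: float
    lambda_1se: float
    lam: float  # lambda actually used for the reported fit
    intercept: float
    coefficients: dict[str, float]
    metrics: dict[str, float] = field(default_factory=dict)
    cv_table: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def active_set(self) -> list[str]:
        return [k for k, v in self.coefficients.items() if v != 0.0]

    def predict(self, sti_vector: dict[str, float]) -> float:
        return predict_score(self, sti_vector)

    def equation(self, decimals: int = 3) -> str:
        terms = [f"{self.intercept:.{decimals}f}"]
        for name, b in self.coefficients.items():
            if b == 0.0:
                continue
            sign = "+" if b >= 0 else "-"
            terms.append(f"{sign} {abs(b):.{decimals}f} × {name}")
        return "Y = " + " ".join(terms)

    def to_dict(self) -> dict:
        return {"alpha": self.alpha, "lambda_min": self.lambda_min,
                "lambda_1se": self.lambda_1se, "lambda_used": self.lam,
                "intercept": self.intercept,
                "coefficients": self.coefficients,
                "active_set": self.active_set,
                "metrics": self.metrics,
                "equation": self.equation()}


def fit_glmnet_like(X, y, alpha: float, lam: float,
                    names: list[str] | None = None) -> RegularizedModel:
    """Fit one elastic net at fixed (alpha, lambda); thin wrapper over
    :class:`ElasticNetCD` returning the reporting container."""
    X = np.asarray(X, dtype=float)
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    est = ElasticNetCD(alpha=alpha, lam=lam).fit(X, y)
    return RegularizedModel(
        alpha=alpha, lambda_min=lam, lambda_1se=lam, lam=lam,
        intercept=float(est.intercept_),
        coefficients={n: float(b) for n, b in zip(names, est.coef_)})


def fit_cv_model(X, y, names: list[str] | None = None, alpha_grid=None,
                 k: int = 10, seed: int = 0,
                 use_1se: bool = False) -> RegularizedModel:
    """CV-select (alpha, lambda) then refit on all rows; training metrics
    attached."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    cv = cv_select(X, y, alpha_grid=alpha_grid, k=k, seed=seed)
    lam = cv.lambda_1se if use_1se else cv.lambda_min
    model = fit_glmnet_like(X, y, cv.alpha, lam, names=names)
    model.lambda_min = cv.lambda_min
    model.lambda_1se = cv.lambda_1se
    model.cv_table = cv.cv_table
    pred = X @ np.array(list(model.coefficients.values())) + model.intercept
    model.metrics = fit_metrics(y, pred, p=len(model.active_set))
    return model


# ----------------------------------------------------------------------
# metrics

def predict_score(model: RegularizedModel, sti_vector: dict[str, float]) -> float:
    """Evaluate the exported prediction equation for one genotype."""
    missing = [k for k in model.coefficients if k not in sti_vector]
    if missing:
        raise ValueError(f"missing predictors: {missing}")
    return model.intercept + sum(
        b * sti_vector[name] for name, b in model.coefficients.items())


def fit_metrics(y_obs, y_pred, p: int) -> dict[str, float]:
    """MSE, RMSE, NMSE (= MSE / population variance of y), R2, adjusted R2."""
    y_obs = np.asarray(y_obs, float)
    y_pred = np.asarray(y_pred, float)
    if len(y_obs) != len(y_pred):
        raise ValueError("length mismatch")
    n = len(y_obs)
    var = float(np.var(y_obs))  # population convention
    if var == 0:
        raise ValueError("zero variance in observed values")
    mse = float(np.mean((y_obs - y_pred) ** 2))
    sse = float(np.sum((y_obs - y_pred) ** 2))
    sst = float(np.sum((y_obs - y_obs.mean()) ** 2))
    r2 = 1.0 - sse / sst
    out = {"mse": mse, "rmse": float(np.sqrt(mse)), "nmse": mse / var,
           "r2": r2}
    if n > p + 1:
        out["adj_r2"] = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    else:
        out["adj_r2"] = float("nan")
    return out


def single_trait_r2(amfv, sti_trait) -> float:
    """Squared Pearson correlation between the multi-trait score and one
    trait's STI."""
    a = np.asarray(amfv, float)
    b = np.asarray(sti_trait, float)
    if len(a) < 3:
        raise ValueError("need at least 3 genotypes")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance input")
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def rank_single_trait_r2(amfv, sti_wide: pd.DataFrame) -> pd.Series:
    """R2 of AMFV against each trait STI column, sorted descending."""
    r2 = {t: single_trait_r2(amfv, sti_wide[t]) for t in sti_wide.columns}
    return pd.Series(r2, name="r2").sort_values(ascending=False)
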