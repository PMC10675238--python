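"""Gaussian process regression with an RBF kernel and metaheuristic tuning.

Exact GP inference via Cholesky factorization of ``K + sigma_n^2 I``;
the three kernel hyperparameters (length-scale, signal variance, noise
variance) are optimized in natural-log space, by default by minimizing
the negative log marginal likelihood with the improved seagull
optimizer.  A 5-fold CV-RMSE criterion is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.spatial.distance import cdist

from .isoa import SwarmConfig, isoa_minimize

__all__ = [
    "Hyperparams",
    "GPRModel",
    "NumericalError",
    "rbf_kernel",
    "nlml",
    "gpr_fit",
    "gpr_predict",
    "tune_with_isoa",
]

_JITTERS = (0.0, 1e-10, 1e-8, 1e-6)


class NumericalError(np.linalg.LinAlgError):
    """Covariance not positive definite even after the jitter ladder."""


@dataclass(frozen=True)
class Hyperparams:
    """Kernel hyperparameters stored as natural logs."""

    log_lengthscale: float = 0.0
    log_signal_var: float = 0.0
    log_noise_var: float = -2.0

    @property
    def lengthscale(self) -> float:
        return float(np.exp(self.log_lengthscale))

    @property
    def signal_var(self) -> float:
        return float(np.exp(self.log_signal_var))

    @property
    def noise_var(self) -> float:
        return float(np.exp(self.log_noise_var))

    def as_array(self) -> np.ndarray:
        return np.array([self.log_lengthscale, self.log_signal_var, self.log_noise_var])

    @classmethod
    def from_array(cls, v: np.ndarray) -> "Hyperparams":
        return cls(float(v[0]), float(v[1]), float(v[2]))


def rbf_kernel(A: np.ndarray, B: np.ndarray, hyper: Hyperparams) -> np.ndarray:
    """Squared-exponential kernel sigma_f^2 exp(-||a-b||^2 / (2 l^2))."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("A and B must share their feature dimension")
    sq = cdist(A, B, metric="sqeuclidean")
    return hyper.signal_var * np.exp(-0.5 * sq / hyper.lengthscale**2)


def _factor(X: np.ndarray, hyper: Hyperparams):
    """Cholesky of K + sigma_n^2 I with an escalating jitter ladder."""
    K = rbf_kernel(X, X, hyper)
    n = K.shape[0]
    base = K + hyper.noise_var * np.eye(n)
    for jitter in _JITTERS:
        try:
            L = cho_factor(base + jitter * np.eye(n), lower=True, check_finite=False)
            return L
        except np.linalg.LinAlgError:
            continue
    raise NumericalError("covariance not positive definite after max jitter 1e-6")


@dataclass
class GPRModel:
    """Fitted GP: training inputs, centered targets, cached factorization."""

    X_train: np.ndarray
    y_train: np.ndarray          # centered
    y_mean: float
    hyper: Hyperparams
    L: object                     # (cho_factor output)
    alpha: np.ndarray

    @property
    def n(self) -> int:
        return self.X_train.shape[0]


def nlml(hyper: Hyperparams, X: np.ndarray, y: np.ndarray) -> float:
    """Negative log marginal likelihood of centered targets.

    0.5 y^T (K + s_n^2 I)^-1 y + 0.5 log|K + s_n^2 I| + n/2 log(2 pi),
    computed from the Cholesky factor.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = y.shape[0]
    if n < 2:
        raise ValueError("need at least 2 rows")
    L = _factor(X, hyper)
    alpha = cho_solve(L, y, check_finite=False)
    logdet = 2.0 * np.sum(np.log(np.diag(L[0])))
    return float(0.5 * y @ alpha + 0.5 * logdet + 0.5 * n * np.log(2.0 * np.pi))


def gpr_fit(X: np.ndarray, y: np.ndarray, hyper: Hyperparams) -> GPRModel:
    """Fit (factorize) a GP at fixed hyperparameters; deterministic."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y row counts disagree")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("X and y must be finite")
    y_mean = float(y.mean())
    yc = y - y_mean
    L = _factor(X, hyper)
    alpha = cho_solve(L, yc, check_finite=False)
    return GPRModel(X_train=X, y_train=yc, y_mean=y_mean, hyper=hyper, L=L, alpha=alpha)


def gpr_predict(model: GPRModel, Xstar: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predictive mean and variance (includes observation noise).

    mean = K*^T alpha + y_mean;  var = k** - ||L^-1 K*||^2 + sigma_n^2,
    clipped at zero elementwise.
    """
    Xstar = np.atleast_2d(np.asarray(Xstar, dtype=float))
    if Xstar.shape[1] != model.X_train.shape[1]:
        raise ValueError(
            f"Xstar has {Xstar.shape[1]} features, model expects {model.X_train.shape[1]}"
        )
    Ks = rbf_kernel(model.X_train, Xstar, model.hyper)   # (n, m)
    mean = Ks.T @ model.alpha + model.y_mean
    Lmat, lower = model.L
    v = solve_triangular(Lmat if lower else Lmat.T, Ks, lower=True, check_finite=False)
    var = model.hyper.signal_var - np.sum(v * v, axis=0) + model.hyper.noise_var
    return mean, np.clip(var, 0.0, None)


def _cv_rmse(hyper: Hyperparams, X: np.ndarray, y: np.ndarray, n_folds: int = 5) -> float:
    """Deterministic contiguous k-fold CV RMSE at fixed hyperparameters."""
    n = y.shape[0]
    if n < n_folds:
        raise ValueError("need at least n_folds rows")
    idx = np.arange(n)
    folds = np.array_split(idx, n_folds)
    se = 0.0
    for fold in folds:
        train = np.setdiff1d(idx, fold)
        m = gpr_fit(X[train], y[train], hyper)
        mu, _ = gpr_predict(m, X[fold])
        se += float(np.sum((y[fold] - mu) ** 2))
    return float(np.sqrt(se / n))


def tune_with_isoa(
    X: np.ndarray,
    y: np.ndarray,
    cfg: SwarmConfig | None = None,
    criterion: str = "nlml",
    log_bounds: tuple[float, float] = (-5.0, 5.0),
    n_folds: int = 5,
) -> tuple[GPRModel, dict]:
    """Tune the three log hyperparameters with ISOA and fit at the optimum.

    ``criterion`` is "nlml" (default) or "cv_rmse".  Hyperparameter
    draws where the covariance is numerically singular receive a large
    finite penalty so the swarm simply avoids them.

    Returns the fitted model and an info dict with the best criterion
    value and the per-iteration history.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if criterion not in ("nlml", "cv_rmse"):
        raise ValueError("criterion must be 'nlml' or 'cv_rmse'")
    if criterion == "cv_rmse" and y.shape[0] < max(5, n_folds):
        raise ValueError("cv_rmse needs at least max(5, n_folds) rows")
    cfg = cfg or SwarmConfig(population=12, max_iter=30)
    cfg = replace(cfg, lower=log_bounds[0], upper=log_bounds[1])
    yc = y - y.mean()   # the model itself is fit on centered targets

    def objective(v: np.ndarray) -> float:
        hyper = Hyperparams.from_array(v)
        try:
            if criterion == "nlml":
                return nlml(hyper, X, yc)
            return _cv_rmse(hyper, X, y, n_folds)
        except NumericalError:
            return 1e10

    best, best_val, history = isoa_minimize(objective, 3, cfg)
    hyper = Hyperparams.from_array(best)
    model = gpr_fit(X, y, hyper)
    return model, {"criterion": criterion, "best_value": float(best_val), "history": history}
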