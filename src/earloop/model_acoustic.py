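"""Sparse linear regression of z-scored pleasure on acoustic features.

The fitted objective is

    min over (b0, b) of  (1/N) * sum_i (y_i - b0 - b.x_i)^2 + lam * ||b||_1

with the regularization weight chosen by K-fold cross-validation over a
log-spaced grid descending from lam_max (the smallest lam that zeroes every
coefficient). Ties in CV error break toward the larger lam (sparser model).
Features are assumed pre-standardized; the intercept is unpenalized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import Lasso, lasso_path
from sklearn.model_selection import KFold

from .errors import DegenerateInputError, ParameterError, SchemaError, StateError


@dataclass
class PleasureRegressor:
    beta0: float = 0.0
    beta: np.ndarray | None = None
    lam: float = 0.0
    lambda_grid: np.ndarray | None = None
    cv_folds: int = 0
    cv_errors: np.ndarray | None = None
    fit_rows: int = 0
    fitted: bool = False
    fitted_values: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "beta0": self.beta0,
            "beta": self.beta.tolist(),
            "lam": self.lam,
            "lambda_grid": self.lambda_grid.tolist() if self.lambda_grid is not None else None,
            "cv_folds": self.cv_folds,
            "fit_rows": self.fit_rows,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "PleasureRegressor":
        grid = doc.get("lambda_grid")
        return cls(
            beta0=float(doc["beta0"]),
            beta=np.array(doc["beta"], dtype=float),
            lam=float(doc["lam"]),
            lambda_grid=np.array(grid, dtype=float) if grid is not None else None,
            cv_folds=int(doc["cv_folds"]),
            fit_rows=int(doc["fit_rows"]),
            fitted=True,
        )


def objective(X: np.ndarray, y: np.ndarray, beta0: float, beta: np.ndarray, lam: float) -> float:
    """The penalized loss actually minimized; exposed for oracle comparisons."""
    resid = y - beta0 - X @ beta
    return float(np.mean(resid**2) + lam * np.abs(beta).sum())


def default_lambda_grid(
    X: np.ndarray, y: np.ndarray, n_values: int = 100, min_ratio: float = 1e-4
) -> np.ndarray:
    """Log-spaced grid descending from lam_max (all-zero solution) down to
    ``min_ratio * lam_max``."""
    n = X.shape[0]
    lam_max = 2.0 * np.max(np.abs(X.T @ (y - y.mean()))) / n
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max, lam_max * min_ratio, n_values)


def _solve_lasso(X: np.ndarray, y: np.ndarray, lam: float) -> tuple[float, np.ndarray]:
    # Our objective divides the squared error by N while sklearn's Lasso uses
    # 1/(2N), so alpha = lam / 2.
    model = Lasso(alpha=lam / 2.0, fit_intercept=True, max_iter=50000, tol=1e-10)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)
    return float(model.intercept_), np.asarray(model.coef_, dtype=float)


def _solve_lasso_path(
    X: np.ndarray,
    y: np.ndarray,
    lambda_grid: np.ndarray,
    tol: float = 1e-4,
    max_iter: int = 300,
) -> tuple[np.ndarray, np.ndarray]:
    """Warm-started whole-path solve; grid must be descending.

    Returns ``(intercepts (L,), coefs (p, L))``. The unpenalized intercept is
    recovered by centering both sides before the path solve. The default
    tolerance is loose because this only serves CV error estimation; the
    final model is refit tightly at the selected lambda.
    """
    xm = X.mean(axis=0)
    ym = y.mean()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, coefs, _ = lasso_path(
            X - xm, y - ym, alphas=lambda_grid / 2.0, tol=tol, max_iter=max_iter
        )
    intercepts = ym - xm @ coefs
    return intercepts, coefs


def fit_pleasure_regressor(
    X: np.ndarray,
    y: np.ndarray,
    cv_folds: int = 5,
    lambda_grid: np.ndarray | None = None,
    seed: int = 0,
) -> PleasureRegressor:
    """Fit the L1-penalized regressor with CV-selected regularization."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ParameterError(f"need at least 3 rows, got {n}")
    if cv_folds < 2:
        raise ParameterError(f"cv_folds must be >= 2, got {cv_folds}")
    if np.ptp(y) == 0:
        raise DegenerateInputError("response is constant; nothing to regress")
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(X, y)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    order = np.argsort(lambda_grid)[::-1]
    lambda_grid = lambda_grid[order]  # descending: ties resolve to larger lam

    folds = min(cv_folds, n)
    if folds < cv_folds:
        warnings.warn(f"cv_folds reduced from {cv_folds} to {folds} (only {n} rows)")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    cv_err = np.zeros(len(lambda_grid))
    for train_idx, test_idx in kf.split(X):
        ytr = y[train_idx]
        if np.ptp(ytr) == 0:
            pred = np.full((len(test_idx), len(lambda_grid)), float(ytr[0]))
        else:
            b0s, bs = _solve_lasso_path(X[train_idx], ytr, lambda_grid)
            pred = X[test_idx] @ bs + b0s  # (n_test, L)
        cv_err += np.sum((y[test_idx, None] - pred) ** 2, axis=0)
    cv_err /= n
    best = int(np.argmin(cv_err))  # first minimum = largest lam among ties
    lam = float(lambda_grid[best])
    beta0, beta = _solve_lasso(X, y, lam)
    return PleasureRegressor(
        beta0=beta0,
        beta=beta,
        lam=lam,
        lambda_grid=lambda_grid,
        cv_folds=folds,
        cv_errors=cv_err,
        fit_rows=n,
        fitted=True,
        fitted_values=beta0 + X @ beta,
    )


def fit_at_lambda(X: np.ndarray, y: np.ndarray, lam: float) -> PleasureRegressor:
    """Fit at a fixed regularization weight (no CV)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta0, beta = _solve_lasso(X, y, lam)
    return PleasureRegressor(
        beta0=beta0,
        beta=beta,
        lam=float(lam),
        cv_folds=0,
        fit_rows=X.shape[0],
        fitted=True,
        fitted_values=beta0 + X @ beta,
    )


def predict_pleasure(model: PleasureRegressor, features: np.ndarray) -> np.ndarray:
    """Affine map ``beta0 + X @ beta`` over feature rows (z-pleasure units)."""
    if not model.fitted:
        raise StateError("regressor is not fitted")
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != model.beta.shape[0]:
        raise SchemaError(
            f"feature width {X.shape[1]} != coefficient width {model.beta.shape[0]}"
        )
    return model.beta0 + X @ model.beta
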