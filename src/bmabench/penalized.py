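"""Penalized-likelihood baselines: lasso (CV-min and 1-SE) and elastic net.

These minimize ||y - X b||^2 / (2n) + penalty(b) on the standardized,
centered data (no intercept needed). The penalty weight lambda is chosen
by K-fold cross-validation over a fixed log-spaced grid running from
lambda_max — the smallest penalty at which no variable enters, equal to
max_j |x_j' y| / n for the lasso — down to 1e-4 lambda_max. The 1-SE rule
picks the sparsest lambda whose CV risk is within one standard error of
the minimum. The inner coordinate-descent solver is delegated to
scikit-learn; the grid / fold / rule contract is fixed here so results are
solver-portable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import ElasticNet, Lasso, enet_path, lasso_path
from sklearn.model_selection import KFold

from .data import RegressionData

__all__ = ["PenalizedFit", "fit_penalized", "coefficient_path", "lambda_max"]

_METHODS = ("lasso", "lasso_1se", "elastic_net")
_EN_L1_GRID = (0.25, 0.5, 0.75)
_GRID_POINTS = 100
_GRID_EPS = 1e-4


@dataclass
class PenalizedFit:
    coefficients: np.ndarray
    lambda_selected: float
    rule: str
    path: list[tuple[float, np.ndarray]]
    l1_ratio: float = 1.0

    @property
    def support_size(self) -> int:
        return int(np.count_nonzero(self.coefficients))

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        return np.atleast_2d(X_new) @ self.coefficients


def lambda_max(data: RegressionData, l1_ratio: float = 1.0) -> float:
    """Smallest penalty for which the fitted model is empty."""
    lm = float(np.max(np.abs(data.X.T @ data.y))) / data.n
    return lm / l1_ratio


def default_grid(data: RegressionData, l1_ratio: float = 1.0) -> np.ndarray:
    lm = lambda_max(data, l1_ratio)
    return np.geomspace(lm, _GRID_EPS * lm, _GRID_POINTS)


def _cv_risk(data: RegressionData, grid: np.ndarray, l1_ratio: float,
             n_folds: int, seed: int) -> np.ndarray:
    """Per-(lambda, fold) test MSE along the path; shape (len(grid), folds)."""
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    risks = np.empty((len(grid), n_folds))
    for k, (tr, te) in enumerate(kf.split(data.X)):
        _, coefs, _ = enet_path(data.X[tr], data.y[tr], alphas=grid,
                                l1_ratio=l1_ratio)
        resid = data.y[te, None] - data.X[te] @ coefs
        risks[:, k] = np.mean(resid ** 2, axis=0)
    return risks


def _select_lambda(grid: np.ndarray, risks: np.ndarray, rule: str):
    mean = risks.mean(axis=1)
    se = risks.std(axis=1, ddof=1) / np.sqrt(risks.shape[1])
    imin = int(np.argmin(mean))
    if rule == "cv_min":
        return float(grid[imin]), imin
    # cv_1se: grid is descending, so the smallest index within one SE is
    # the largest (sparsest) admissible lambda.
    ok = np.flatnonzero(mean <= mean[imin] + se[imin])
    i1 = int(ok[0])
    return float(grid[i1]), i1


def fit_penalized(data: RegressionData, method: str = "lasso",
                  n_folds: int = 5, seed: int = 0) -> PenalizedFit:
    """Cross-validated penalized fit.

    ``lasso`` uses the CV-risk minimizer, ``lasso_1se`` the one-standard-
    error rule, and ``elastic_net`` additionally tunes the convex mixing
    weight over {0.25, 0.5, 0.75} by CV-min.
    """
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}")
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if np.allclose(data.y, data.y[0]):
        raise ValueError("constant response")

    if method == "elastic_net":
        best = None
        for l1 in _EN_L1_GRID:
            grid = default_grid(data, l1)
            risks = _cv_risk(data, grid, l1, n_folds, seed)
            lam, i = _select_lambda(grid, risks, "cv_min")
            score = risks.mean(axis=1)[i]
            if best is None or score < best[0]:
                best = (score, lam, l1, grid)
        _, lam, l1, grid = best
        rule = "cv_min"
    else:
        l1 = 1.0
        grid = default_grid(data, 1.0)
        risks = _cv_risk(data, grid, 1.0, n_folds, seed)
        rule = "cv_min" if method == "lasso" else "cv_1se"
        lam, _ = _select_lambda(grid, risks, rule)

    est_cls = Lasso if l1 == 1.0 else ElasticNet
    kwargs = {} if l1 == 1.0 else {"l1_ratio": l1}
    est = est_cls(alpha=lam, fit_intercept=False, max_iter=50_000, **kwargs)
    est.fit(data.X, data.y)
    path = coefficient_path(data, method, grid, l1_ratio=l1)
    return PenalizedFit(coefficients=np.asarray(est.coef_, dtype=float),
                        lambda_selected=lam, rule=rule, path=path, l1_ratio=l1)


def coefficient_path(data: RegressionData, method: str = "lasso",
                     lambda_grid: np.ndarray | None = None,
                     l1_ratio: float | None = None) -> list[tuple[float, np.ndarray]]:
    """Coefficient vectors along a strictly positive, descending lambda grid."""
    if l1_ratio is None:
        l1_ratio = 1.0 if method != "elastic_net" else 0.5
    if lambda_grid is None:
        lambda_grid = default_grid(data, l1_ratio)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if np.any(lambda_grid <= 0) or np.any(np.diff(lambda_grid) > 0):
        raise ValueError("lambda grid must be strictly positive and descending")
    if l1_ratio == 1.0:
        _, coefs, _ = lasso_path(data.X, data.y, alphas=lambda_grid)
    else:
        _, coefs, _ = enet_path(data.X, data.y, alphas=lambda_grid, l1_ratio=l1_ratio)
    return [(float(lam), coefs[:, i].copy()) for i, lam in enumerate(lambda_grid)]
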