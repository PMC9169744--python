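"""Regression data container with the standardization contract.

All downstream machinery (g-prior marginals, model search, penalized fits)
assumes predictors with mean 0 / variance 1 and a centered response, so the
intercept and error scale can be handled by the flat prior pi(alpha, sigma)
propto 1/sigma and drop out of every Bayes factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_STD_TOL = 1e-8


@dataclass
class Standardizer:
    """Training-set standardization parameters, reusable on new rows."""

    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float

    def transform_X(self, X_raw: np.ndarray) -> np.ndarray:
        return (np.asarray(X_raw, dtype=float) - self.x_mean) / self.x_scale

    def transform_y(self, y_raw: np.ndarray) -> np.ndarray:
        return np.asarray(y_raw, dtype=float) - self.y_mean


@dataclass
class RegressionData:
    """Standardized design matrix and centered response.

    Invariants: every column of ``X`` has mean 0 and variance 1 (within
    1e-8), ``y`` has mean 0, and ``n >= 3``.
    """

    X: np.ndarray
    y: np.ndarray
    column_names: list[str] = field(default_factory=list)
    standardizer: Standardizer | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y disagree on the number of observations")
        if self.n < 3:
            raise ValueError("need at least 3 observations")
        if not self.column_names:
            self.column_names = [f"x{j}" for j in range(self.p)]
        if len(self.column_names) != self.p:
            raise ValueError("column_names length does not match p")
        self._validate()

    def _validate(self) -> None:
        if abs(float(np.mean(self.y))) > _STD_TOL * max(1.0, float(np.std(self.y))):
            raise ValueError("response is not centered")
        mu = self.X.mean(axis=0)
        var = self.X.var(axis=0)
        if np.any(np.abs(mu) > 1e-6) or np.any(np.abs(var - 1.0) > 1e-6):
            raise ValueError("predictors are not standardized to mean 0, variance 1")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


def standardize(X_raw: np.ndarray, y_raw: np.ndarray,
                column_names: list[str] | None = None) -> RegressionData:
    """Standardize predictors and center the response.

    Uses the population (1/n) variance so the standardized columns satisfy
    the container invariants exactly. Constant columns are rejected.
    """
    X_raw = np.asarray(X_raw, dtype=float)
    y_raw = np.asarray(y_raw, dtype=float).ravel()
    x_mean = X_raw.mean(axis=0)
    x_scale = X_raw.std(axis=0)
    if np.any(x_scale <= 0):
        bad = [j for j, s in enumerate(x_scale) if s <= 0]
        raise ValueError(f"constant predictor column(s): {bad}")
    y_mean = float(y_raw.mean())
    std = Standardizer(x_mean=x_mean, x_scale=x_scale, y_mean=y_mean)
    return RegressionData(
        X=(X_raw - x_mean) / x_scale,
        y=y_raw - y_mean,
        column_names=list(column_names) if column_names else [],
        standardizer=std,
    )


def load_regression_data(path, response: str, sep: str | None = None) -> RegressionData:
    """Read a delimited table (header row required) and standardize it.

    ``response`` names the response column; every remaining numeric column
    becomes a candidate predictor.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    if response not in df.columns:
        raise KeyError(f"response column {response!r} not in table")
    y = df[response].to_numpy(dtype=float)
    Xdf = df.drop(columns=[response]).select_dtypes(include=[np.number])
    return standardize(Xdf.to_numpy(dtype=float), y, list(Xdf.columns))
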