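"""Model-averaged (BMA) and MAP-model (BMS) estimation and prediction.

Given a posterior over models, the conditional posterior of the included
coefficients under a g-prior is multivariate Student-t with n-1 degrees of
freedom, location (g/(1+g)) beta_hat (the shrunken OLS estimate) and scale
built from sigma^2 | y ~ InvGamma((n-1)/2, SSR_g/2) with
SSR_g = TSS (1 - (g/(1+g)) R^2). BMA quantities mix these conditionals
over the posterior model masses, with a point mass at zero for excluded
coefficients; intervals are equal-tailed quantiles of the mixture obtained
from seeded Monte Carlo draws.

Adaptive variants draw g per sample from its conditional posterior
p(g | gamma, y) by 1-D inverse-CDF sampling on a grid in u = g/(1+g);
EB-local uses its plug-in g-hat, and the BIC / AIC weight approximations
use the unit-information plug-in g = n and g = 1 respectively.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .data import RegressionData
from .gprior import GPriorSpec, ModelScorer, jzs_log_density_g, resolve_g
from .search import PosteriorOverModels, map_model

__all__ = ["CoefficientSummary", "PredictionResult",
           "bma_coefficients", "bma_predict", "bms_infer"]

_GRID_SIZE = 2048


@dataclass
class CoefficientSummary:
    posterior_mean: np.ndarray
    interval_lower: np.ndarray
    interval_upper: np.ndarray
    inclusion_prob: np.ndarray

    def to_frame(self, column_names=None):
        import pandas as pd

        names = column_names or [f"x{j}" for j in range(len(self.posterior_mean))]
        return pd.DataFrame({
            "variable": names,
            "mean": self.posterior_mean,
            "lower": self.interval_lower,
            "upper": self.interval_upper,
            "inclusion_prob": self.inclusion_prob,
        })


@dataclass
class PredictionResult:
    point: np.ndarray
    pred_lower: np.ndarray
    pred_upper: np.ndarray


def _g_conditional_grid(variant: str, r2: float, n: int, d: int, hyper_a: float):
    """Normalized conditional density of u = g/(1+g) on a grid, plus E[u]."""
    u = np.linspace(1e-7, 1.0 - 1e-7, _GRID_SIZE)
    g = u / (1.0 - u)
    lbf = (0.5 * (n - 1 - d) * np.log1p(g)
           - 0.5 * (n - 1) * np.log1p(g * (1.0 - r2)))
    if variant == "hyper_g":
        lprior = -0.5 * hyper_a * np.log1p(g)
    elif variant == "jzs":
        lprior = jzs_log_density_g(g, n)
    else:
        raise ValueError(variant)
    logpdf = lbf + lprior + 2.0 * np.log1p(g)  # Jacobian dg/du = (1+g)^2
    logpdf -= logpdf.max()
    pdf = np.exp(logpdf)
    Z = np.trapezoid(pdf, u)
    pdf /= Z
    mean_u = float(np.trapezoid(u * pdf, u))
    return u, pdf, mean_u


def _sample_u_from_grid(u, pdf, size, rng):
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (pdf[1:] + pdf[:-1]) * np.diff(u))])
    cdf /= cdf[-1]
    return np.interp(rng.random(size), cdf, np.concatenate([[u[0]], u[1:]]))


def _plugin_u(gspec: GPriorSpec, r2: float, n: int, d: int, p: int) -> float:
    if gspec.variant == "fixed_g":
        g = resolve_g(gspec.g_rule, n, p)
    elif gspec.variant == "eb_local":
        F = (r2 / d) / ((1.0 - r2) / (n - 1 - d)) if d > 0 and r2 < 1 else math.inf
        g = max(F - 1.0, 0.0)
        if g == 0.0:
            return 0.0
        if not math.isfinite(g):
            return 1.0
    elif gspec.variant == "bic":
        g = float(n)
    elif gspec.variant == "aic":
        g = 1.0
    else:
        raise ValueError(gspec.variant)
    return g / (1.0 + g)


class _ModelSampler:
    """Per-model machinery shared by coefficient and predictive sampling."""

    def __init__(self, data: RegressionData, gspec: GPriorSpec):
        self.data = data
        self.gspec = gspec
        self.scorer = ModelScorer(data)
        self.n = data.n
        self.p = data.p

    def prepare(self, gamma: np.ndarray):
        gamma = np.asarray(gamma, dtype=bool)
        d = int(gamma.sum())
        r2, coef, rss = self.scorer.fit(gamma)
        chol = None
        if d > 0:
            Gs = self.scorer.G[np.ix_(gamma, gamma)]
            chol = linalg.cholesky(Gs, lower=True, check_finite=False)
        return gamma, d, r2, coef, chol

    def mean_shrinkage(self, r2: float, d: int) -> float:
        """E[g/(1+g) | gamma, y] — the shrinkage applied to the OLS mean."""
        if d == 0:
            return 0.0
        if self.gspec.variant in ("hyper_g", "jzs"):
            _, _, mean_u = _g_conditional_grid(
                self.gspec.variant, r2, self.n, d, self.gspec.hyper_a)
            return mean_u
        return _plugin_u(self.gspec, r2, self.n, d, self.p)

    def draw(self, gamma, d, r2, coef, chol, size, rng):
        """Draw (beta, sigma2, alpha) jointly, `size` samples for one model."""
        n = self.n
        if d > 0 and self.gspec.variant in ("hyper_g", "jzs"):
            u_grid, pdf, _ = _g_conditional_grid(
                self.gspec.variant, r2, n, d, self.gspec.hyper_a)
            u = _sample_u_from_grid(u_grid, pdf, size, rng)
        else:
            u = np.full(size, _plugin_u(self.gspec, r2, n, d, self.p) if d > 0 else 0.0)
        ssr_g = self.scorer.tss * (1.0 - u * r2)
        sigma2 = ssr_g / (2.0 * rng.gamma(0.5 * (n - 1), 1.0, size=size))
        beta = np.zeros((size, self.p))
        if d > 0:
            z = rng.standard_normal((d, size))
            t = linalg.solve_triangular(chol.T, z, lower=False, check_finite=False)
            beta[:, gamma] = (u[:, None] * coef[None, :]
                              + (np.sqrt(sigma2 * u) * t).T)
        alpha = rng.standard_normal(size) * np.sqrt(sigma2 / n)
        return beta, sigma2, alpha


def _allocate(post: PosteriorOverModels, n_draws: int, rng) -> np.ndarray:
    return rng.multinomial(n_draws, post.posterior_mass / post.posterior_mass.sum())


def bma_coefficients(data: RegressionData, post: PosteriorOverModels,
                     gspec: GPriorSpec, alpha: float = 0.05,
                     n_draws: int = 10_000, seed: int = 0) -> CoefficientSummary:
    """Model-averaged coefficient means and equal-tailed mixture intervals.

    The posterior mean is computed analytically as the mass-weighted mixture
    of shrunken OLS means; intervals come from ``n_draws`` seeded samples of
    the mixture (including the point mass at 0 for model exclusion).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if n_draws < 1000:
        warnings.warn("n_draws < 1000: interval Monte Carlo error may be large")
    rng = np.random.default_rng(seed)
    sampler = _ModelSampler(data, gspec)
    p = data.p
    mean = np.zeros(p)
    counts = _allocate(post, n_draws, rng)
    draws = np.zeros((n_draws, p))
    pos = 0
    for ms, w, c in zip(post.models, post.posterior_mass, counts):
        gamma, d, r2, coef, chol = sampler.prepare(ms.gamma)
        if d > 0:
            mean[gamma] += w * sampler.mean_shrinkage(r2, d) * coef
        if c > 0:
            beta, _, _ = sampler.draw(gamma, d, r2, coef, chol, int(c), rng)
            draws[pos:pos + int(c)] = beta
            pos += int(c)
    lower = np.quantile(draws, alpha / 2.0, axis=0)
    upper = np.quantile(draws, 1.0 - alpha / 2.0, axis=0)
    return CoefficientSummary(
        posterior_mean=mean,
        interval_lower=np.minimum(lower, upper),
        interval_upper=np.maximum(lower, upper),
        inclusion_prob=np.asarray(post.inclusion_prob, dtype=float),
    )


def bma_predict(data: RegressionData, post: PosteriorOverModels,
                gspec: GPriorSpec, X_new: np.ndarray, alpha: float = 0.05,
                n_draws: int = 10_000, seed: int = 0) -> PredictionResult:
    """Point predictions and posterior predictive intervals for new rows.

    ``X_new`` must already be on the training standardization scale.
    Predictive draws include model, coefficient, intercept and noise
    uncertainty; predictions are on the centered-response scale.
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != data.p:
        raise ValueError("X_new has wrong number of columns")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    sampler = _ModelSampler(data, gspec)
    m = X_new.shape[0]
    point = np.zeros(m)
    counts = _allocate(post, n_draws, rng)
    draws = np.empty((n_draws, m))
    pos = 0
    for ms, w, c in zip(post.models, post.posterior_mass, counts):
        gamma, d, r2, coef, chol = sampler.prepare(ms.gamma)
        if d > 0:
            point += w * sampler.mean_shrinkage(r2, d) * (X_new[:, gamma] @ coef)
        if c > 0:
            c = int(c)
            beta, sigma2, a0 = sampler.draw(gamma, d, r2, coef, chol, c, rng)
            mu = beta @ X_new.T + a0[:, None]
            draws[pos:pos + c] = mu + rng.standard_normal((c, m)) * np.sqrt(sigma2)[:, None]
            pos += c
    lower = np.quantile(draws, alpha / 2.0, axis=0)
    upper = np.quantile(draws, 1.0 - alpha / 2.0, axis=0)
    return PredictionResult(point=point, pred_lower=lower, pred_upper=upper)


def bms_infer(data: RegressionData, post: PosteriorOverModels, gspec: GPriorSpec,
              X_new: np.ndarray | None = None, alpha: float = 0.05,
              n_draws: int = 10_000, seed: int = 0):
    """Bayesian model selection: the same machinery conditioned on the MAP
    model only. Returns (CoefficientSummary, PredictionResult | None)."""
    gamma = map_model(post)
    idx = next(i for i, ms in enumerate(post.models)
               if np.array_equal(ms.gamma, gamma))
    degenerate = PosteriorOverModels(
        models=[post.models[idx]],
        posterior_mass=np.array([1.0]),
        inclusion_prob=gamma.astype(float),
        method=post.method + "+map",
        n_iterations=post.n_iterations,
    )
    coefs = bma_coefficients(data, degenerate, gspec, alpha, n_draws, seed)
    preds = None
    if X_new is not None:
        preds = bma_predict(data, degenerate, gspec, X_new, alpha, n_draws, seed + 1)
    return coefs, preds
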