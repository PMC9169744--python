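"""Marginal likelihoods and Bayes factors for the Zellner g-prior family.

The regression model is y = alpha 1 + X_gamma beta_gamma + eps with
eps ~ N(0, sigma^2 I), the flat prior pi(alpha, sigma) propto 1/sigma, and
the g-prior beta_gamma | sigma^2 ~ N(0, g sigma^2 (X'X)^{-1}) on the
included coefficients. Integrating out (alpha, beta, sigma) gives the
closed-form Bayes factor against the null (intercept-only) model

    log B = ((n - 1 - d)/2) log(1 + g) - ((n - 1)/2) log(1 + g (1 - R^2)),

where d is the model size and R^2 the OLS coefficient of determination of
the model on the centered data. Everything here is reported on the log
scale relative to the null model, which is the shared anchor with log
Bayes factor 0.

Variants: fixed g (with the usual rules sqrt(n), n, 1, max(n, p^2)), the
hyper-g prior (closed form via the Gaussian hypergeometric function 2F1),
local empirical Bayes (per-model plug-in g-hat), the Jeffreys-Zellner-Siow
Cauchy prior (1-D quadrature over g), and BIC/AIC approximate weights.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import mpmath
import numpy as np
from scipy import integrate, linalg, special

from .data import RegressionData

__all__ = [
    "GPriorSpec",
    "ModelPriorSpec",
    "ModelScore",
    "ModelScorer",
    "RankDeficientModelError",
    "SaturatedModelError",
    "model_fit_stats",
    "resolve_g",
    "log_bf_fixed_g",
    "max_log_bf_fixed_g",
    "log_bf_hyper_g",
    "log_bf_eb_local",
    "log_bf_jzs",
    "log_weight_ic",
    "model_log_prior",
    "jzs_log_density_g",
]


class RankDeficientModelError(ValueError):
    """The selected columns do not form a full-rank submatrix."""


class SaturatedModelError(ValueError):
    """Model size exceeds n - 2, leaving no residual degrees of freedom."""


# ---------------------------------------------------------------------------
# OLS sufficient statistics


@dataclass
class ModelScore:
    """Score of one model: indicator, fit quality, and log weights."""

    gamma: np.ndarray
    r2: float
    log_marginal: float
    log_prior: float

    @property
    def d(self) -> int:
        return int(self.gamma.sum())

    @property
    def key(self) -> bytes:
        return np.packbits(self.gamma.astype(np.uint8)).tobytes()


class ModelScorer:
    """Cached OLS sufficient statistics for submodels of one dataset.

    Precomputes the Gram matrix X'X, the cross-products X'y and the total
    sum of squares once; each submodel fit is then a small positive-definite
    solve. Rank deficiency is detected by the Cholesky factorization.
    """

    def __init__(self, data: RegressionData):
        self.data = data
        self.G = data.X.T @ data.X
        self.Xy = data.X.T @ data.y
        self.tss = float(data.y @ data.y)
        self.n = data.n
        self.p = data.p

    def fit(self, gamma: np.ndarray):
        """Return (r2, ols_coefficients, residual_ss) for the submodel."""
        gamma = np.asarray(gamma, dtype=bool)
        d = int(gamma.sum())
        if d == 0:
            return 0.0, np.zeros(0), self.tss
        if d > self.n - 2:
            raise SaturatedModelError(f"model size {d} exceeds n - 2 = {self.n - 2}")
        Gs = self.G[np.ix_(gamma, gamma)]
        bs = self.Xy[gamma]
        try:
            c, low = linalg.cho_factor(Gs, lower=True, check_finite=False)
        except linalg.LinAlgError as exc:
            raise RankDeficientModelError("rank-deficient model") from exc
        # Cholesky succeeds on near-singular matrices; guard the conditioning.
        diag = np.diag(c)
        if np.min(diag) <= 1e-8 * np.max(diag):
            raise RankDeficientModelError("rank-deficient model")
        coef = linalg.cho_solve((c, low), bs, check_finite=False)
        ess = float(bs @ coef)
        rss = max(self.tss - ess, 0.0)
        r2 = min(max(ess / self.tss, 0.0), 1.0) if self.tss > 0 else 0.0
        return r2, coef, rss


def model_fit_stats(data: RegressionData, gamma: np.ndarray):
    """OLS fit statistics (r2, coefficients, RSS) for one submodel."""
    return ModelScorer(data).fit(gamma)


# ---------------------------------------------------------------------------
# g rules


def resolve_g(g_rule, n: int, p: int = 0) -> float:
    """Resolve a g rule to a positive scalar.

    Rules: ``"sqrt_n"`` -> sqrt(n) (prior sample size sqrt(n)); ``"n"`` ->
    the unit information prior; ``"one"`` -> g = 1 (prior sample size n);
    ``"benchmark"`` -> max(n, p^2); or any positive number.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if isinstance(g_rule, str):
        if g_rule == "sqrt_n":
            return math.sqrt(n)
        if g_rule == "n":
            return float(n)
        if g_rule == "one":
            return 1.0
        if g_rule == "benchmark":
            return float(max(n, p * p))
        raise ValueError(f"unknown g rule: {g_rule!r}")
    g = float(g_rule)
    if not g > 0:
        raise ValueError("g must be strictly positive")
    return g


# ---------------------------------------------------------------------------
# Bayes factors against the null model


def log_bf_fixed_g(r2: float, n: int, d: int, g: float) -> float:
    """Exact log Bayes factor vs the null model for a fixed g.

    Finite for every r2 in [0, 1]; at r2 = 1 it attains the upper bound
    ((n-1-d)/2) log(1+g) — the information-paradox ceiling of fixed-g
    priors.
    """
    if d == 0:
        return 0.0
    if not (0.0 <= r2 <= 1.0):
        raise ValueError("r2 must lie in [0, 1]")
    if not g > 0:
        raise ValueError("g must be positive")
    return 0.5 * (n - 1 - d) * math.log1p(g) - 0.5 * (n - 1) * math.log1p(g * (1.0 - r2))


def max_log_bf_fixed_g(n: int, d: int, g: float) -> float:
    """Supremum over r2 of the fixed-g log Bayes factor (attained at r2=1)."""
    if d == 0:
        return 0.0
    return 0.5 * (n - 1 - d) * math.log1p(g)


def log_bf_hyper_g(r2: float, n: int, d: int, a: float = 3.0) -> float:
    """Log Bayes factor under the hyper-g prior pi(g) propto (1+g)^(-a/2).

    Closed form ((a-2)/(d+a-2)) * 2F1((n-1)/2, 1; (d+a)/2; r2). Diverges to
    +inf as r2 -> 1 whenever (d+a)/2 <= (n+1)/2, which resolves the
    information paradox. High-precision arithmetic is used near r2 = 1
    where the series suffers cancellation/overflow.
    """
    if d == 0:
        return 0.0
    if not a > 2:
        raise ValueError("hyper-g requires a > 2")
    if not (0.0 <= r2 <= 1.0):
        raise ValueError("r2 must lie in [0, 1]")
    c = 0.5 * (d + a)
    b1 = 0.5 * (n - 1)
    if r2 >= 1.0:
        # 2F1(b1, 1; c; 1) converges only if c > b1 + 1 (Gauss).
        if c <= b1 + 1.0:
            return math.inf
        return math.log((a - 2.0) / (d + a - 2.0)) + math.log(
            float(mpmath.hyp2f1(b1, 1.0, c, 1.0))
        )
    f = special.hyp2f1(b1, 1.0, c, r2) if r2 <= 0.95 else np.nan
    if np.isfinite(f) and f > 0:
        logf = math.log(f)
    elif r2 > 0.95 and n <= 200:
        # high precision where the series suffers cancellation at small n
        with mpmath.workdps(50):
            logf = float(mpmath.log(mpmath.hyp2f1(b1, 1.0, c, r2)))
    else:
        # float64 overflow (large n) or instability: evaluate the identical
        # mixture integral over g in log space instead
        return _log_bf_hyper_g_quad(r2, n, d, a)
    out = math.log((a - 2.0) / (d + a - 2.0)) + logf
    if not math.isfinite(out):
        warnings.warn("hyper-g Bayes factor overflowed; reporting +inf")
        return math.inf
    return out


def _hyper_g_log_integrand_scalar(u: float, r2: float, n: int, d: int, a: float) -> float:
    # log of BF_fixed_g(g) pi(g) dg/du with pi(g) = ((a-2)/2)(1+g)^(-a/2)
    if u <= 0.0 or u >= 1.0:
        return -math.inf
    g = u / (1.0 - u)
    return (0.5 * (n - 1 - d - a) * math.log1p(g)
            - 0.5 * (n - 1) * math.log1p(g * (1.0 - r2))
            + math.log(0.5 * (a - 2.0))
            - 2.0 * math.log1p(-u))


def _log_bf_hyper_g_quad(r2: float, n: int, d: int, a: float) -> float:
    grid = np.linspace(1e-9, 1.0 - 1e-9, 513)
    lv = np.array([_hyper_g_log_integrand_scalar(u, r2, n, d, a) for u in grid])
    imax = int(np.argmax(lv))
    M, umax = float(lv[imax]), float(grid[imax])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, err = integrate.quad(
            lambda u: math.exp(min(_hyper_g_log_integrand_scalar(u, r2, n, d, a) - M, 700.0)),
            0.0, 1.0, points=[umax], limit=200, epsabs=0.0, epsrel=1e-10,
        )
    if not (val > 0 and np.isfinite(val)):
        raise RuntimeError(f"hyper-g quadrature failed: r2={r2}, n={n}, d={d}")
    return M + math.log(val)


def log_bf_eb_local(r2: float, n: int, d: int) -> float:
    """Local empirical Bayes: plug the per-model MLE of g into the fixed-g BF.

    g-hat = max(F - 1, 0) with F the usual overall F statistic of the model;
    r2 small enough that F <= 1 gives g-hat = 0 and a log Bayes factor of 0.
    """
    if d == 0:
        return 0.0
    if n - 1 - d <= 0:
        raise SaturatedModelError("EB-local needs n - 1 - d > 0")
    if r2 >= 1.0:
        return math.inf
    F = (r2 / d) / ((1.0 - r2) / (n - 1 - d))
    ghat = max(F - 1.0, 0.0)
    if ghat == 0.0:
        return 0.0
    return log_bf_fixed_g(r2, n, d, ghat)


def jzs_log_density_g(g: np.ndarray, n: int) -> np.ndarray:
    """Log density of the Zellner-Siow mixing prior on g.

    pi(g) = (n/2)^(1/2) Gamma(1/2)^(-1) g^(-3/2) exp(-n/(2g)), i.e. g is
    inverse-gamma(1/2, n/2); marginally beta is multivariate Cauchy.
    """
    g = np.asarray(g, dtype=float)
    return (0.5 * math.log(n / 2.0) - math.lgamma(0.5)
            - 1.5 * np.log(g) - n / (2.0 * g))


_LGAMMA_HALF = math.lgamma(0.5)


def _jzs_log_integrand(u: np.ndarray, r2: float, n: int, d: int) -> np.ndarray:
    """Log integrand of the JZS Bayes factor after u = g/(1+g)."""
    u = np.asarray(u, dtype=float)
    g = u / (1.0 - u)
    lbf = (0.5 * (n - 1 - d) * np.log1p(g)
           - 0.5 * (n - 1) * np.log1p(g * (1.0 - r2)))
    return lbf + jzs_log_density_g(g, n) - 2.0 * np.log1p(-u)


def _jzs_log_integrand_scalar(u: float, r2: float, n: int, d: int) -> float:
    # scalar twin of _jzs_log_integrand, kept numpy-free for quad speed
    if u <= 0.0 or u >= 1.0:
        return -math.inf
    g = u / (1.0 - u)
    return (0.5 * (n - 1 - d) * math.log1p(g)
            - 0.5 * (n - 1) * math.log1p(g * (1.0 - r2))
            + 0.5 * math.log(n / 2.0) - _LGAMMA_HALF
            - 1.5 * math.log(g) - n / (2.0 * g)
            - 2.0 * math.log1p(-u))


def log_bf_jzs(r2: float, n: int, d: int) -> float:
    """Log Bayes factor under the Jeffreys-Zellner-Siow Cauchy prior.

    Integrates the fixed-g Bayes factor against the inverse-gamma(1/2, n/2)
    mixing density by adaptive quadrature on u = g/(1+g) in (0, 1), which
    tames the heavy right tail. The integrand is exponentiated around its
    maximum for stability.
    """
    if d == 0:
        return 0.0
    if d > n - 2:
        raise SaturatedModelError("JZS needs d <= n - 2")
    if r2 >= 1.0:
        return math.inf
    grid = np.linspace(1e-9, 1.0 - 1e-9, 513)
    lv = _jzs_log_integrand(grid, r2, n, d)
    imax = int(np.argmax(lv))
    M = float(lv[imax])
    umax = float(grid[imax])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, err = integrate.quad(
            lambda u: math.exp(min(_jzs_log_integrand_scalar(u, r2, n, d) - M, 700.0)),
            0.0, 1.0, points=[umax], limit=200, epsabs=0.0, epsrel=1e-10,
        )
    if not (val > 0 and np.isfinite(val)):
        raise RuntimeError(
            f"JZS quadrature failed: r2={r2}, n={n}, d={d}, value={val}, err={err}"
        )
    if err / val > 1e-8:
        warnings.warn(f"JZS quadrature tolerance not met (rel err {err / val:.2e})")
    return M + math.log(val)


def log_weight_ic(criterion: str, r2: float, n: int, d: int) -> float:
    """BIC / AIC approximate log model weight (up to a shared constant).

    BIC: -(n log(1-r2) + d log n)/2, approximating the unit information
    prior; AIC: -(n log(1-r2) + 2d)/2. Only differences between models are
    meaningful; the null model has weight 0.
    """
    if criterion not in ("bic", "aic"):
        raise ValueError("criterion must be 'bic' or 'aic'")
    if r2 >= 1.0:
        warnings.warn(f"{criterion.upper()} weight is +inf at r2 = 1 (saturated fit)")
        return math.inf
    penalty = d * math.log(n) if criterion == "bic" else 2.0 * d
    return -0.5 * (n * math.log1p(-r2) + penalty)


# ---------------------------------------------------------------------------
# Model-space priors


@dataclass
class ModelPriorSpec:
    """Prior over inclusion vectors gamma.

    ``beta_binomial_11`` is the default (uniform on model size, then uniform
    within size); ``truncated_beta_binomial_11`` additionally assigns zero
    mass to models larger than n - 2, for the p > n regime, and renormalizes.
    """

    kind: str = "beta_binomial_11"

    def log_prior(self, d: int, p: int, n: int) -> float:
        return model_log_prior(self, d, p, n)


def model_log_prior(spec: ModelPriorSpec, d: int, p: int, n: int) -> float:
    """Log prior mass of one model of size d among p candidates."""
    if not 0 <= d <= p:
        raise ValueError("need 0 <= d <= p")
    if spec.kind == "uniform":
        return -p * math.log(2.0)
    log_choose = special.gammaln(p + 1) - special.gammaln(d + 1) - special.gammaln(p - d + 1)
    if spec.kind == "beta_binomial_11":
        return -math.log(p + 1) - float(log_choose)
    if spec.kind == "truncated_beta_binomial_11":
        m = min(p, n - 2)
        if d > m:
            return -math.inf
        # admissible mass is (m+1)/(p+1); renormalize
        return -math.log(m + 1) - float(log_choose)
    raise ValueError(f"unknown model prior kind: {spec.kind!r}")


# ---------------------------------------------------------------------------
# Parameter-prior spec with a uniform dispatch surface


@dataclass
class GPriorSpec:
    """Which parameter prior to use for marginal likelihoods.

    variant: one of fixed_g, hyper_g, eb_local, jzs, bic, aic.
    g_rule: for fixed_g, one of 'sqrt_n', 'n', 'one', 'benchmark' or a
    positive number. hyper_a: hyper-g hyperparameter (a > 2, default 3).
    """

    variant: str = "fixed_g"
    g_rule: object = "sqrt_n"
    hyper_a: float = 3.0

    _VARIANTS = ("fixed_g", "hyper_g", "eb_local", "jzs", "bic", "aic")

    def __post_init__(self):
        if self.variant not in self._VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.variant == "hyper_g" and not self.hyper_a > 2:
            raise ValueError("hyper_a must exceed 2")

    def log_marginal(self, r2: float, n: int, d: int, p: int = 0) -> float:
        """Log marginal likelihood up to the constant shared by all models."""
        if self.variant == "fixed_g":
            return log_bf_fixed_g(r2, n, d, resolve_g(self.g_rule, n, p))
        if self.variant == "hyper_g":
            return _log_bf_hyper_g_cached(round(r2, 12), n, d, self.hyper_a)
        if self.variant == "eb_local":
            return log_bf_eb_local(r2, n, d)
        if self.variant == "jzs":
            return _log_bf_jzs_cached(round(r2, 12), n, d)
        return log_weight_ic(self.variant, r2, n, d)

    def label(self) -> str:
        if self.variant == "fixed_g":
            return f"g={self.g_rule}"
        return self.variant


@lru_cache(maxsize=200_000)
def _log_bf_jzs_cached(r2: float, n: int, d: int) -> float:
    return log_bf_jzs(r2, n, d)


@lru_cache(maxsize=200_000)
def _log_bf_hyper_g_cached(r2: float, n: int, d: int, a: float) -> float:
    return log_bf_hyper_g(r2, n, d, a)
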