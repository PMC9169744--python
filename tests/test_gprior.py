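"""Unit and property tests for the g-prior marginal-likelihood engine."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

import bmabench as bb
from bmabench.gprior import (
    ModelScorer,
    RankDeficientModelError,
    SaturatedModelError,
    _log_bf_hyper_g_quad,
)


# ---------------------------------------------------------------------------
# Independent oracle: numerically integrated marginal likelihood.
# The intercept is integrated analytically under its flat prior (a plain
# Gaussian integral); beta (d=1) and sigma are integrated numerically, so
# the oracle never touches the closed-form Bayes-factor expression.


def _log_marginal_numeric(y, x, g):
    """log m(y) for a single-predictor model, flat pi(alpha, sigma) ~ 1/sigma.

    After integrating alpha: m(y|beta,sigma) =
    (2 pi sigma^2)^(-(n-1)/2) n^(-1/2) exp(-||yc - xc b||^2 / (2 sigma^2)).
    beta prior: N(0, g sigma^2 / (xc'xc)).
    """
    n = len(y)
    yc = y - y.mean()
    xc = x - x.mean()
    sxx = float(xc @ xc)

    bhat = float(xc @ yc) / sxx

    def integrand(b, log_s):
        s2 = math.exp(2 * log_s)
        rss = float(np.sum((yc - b * xc) ** 2))
        logv = (-(n - 1) / 2 * math.log(2 * math.pi * s2) - 0.5 * math.log(n)
                - rss / (2 * s2)
                - 0.5 * math.log(2 * math.pi * g * s2 / sxx)
                - b * b * sxx / (2 * g * s2))
        # sigma -> log sigma Jacobian cancels the 1/sigma prior
        return math.exp(logv)

    def inner(log_s):
        # beta-integrand is Gaussian-ish: cover likelihood and prior widths
        s = math.exp(log_s)
        w = 40.0 * s * math.sqrt((1.0 + g) / sxx)
        lo = min(0.0, bhat) - w
        hi = max(0.0, bhat) + w
        val, _ = integrate.quad(lambda b: integrand(b, log_s), lo, hi,
                                points=[bhat, 0.0], limit=200,
                                epsabs=0.0, epsrel=1e-11)
        return val

    val, err = integrate.quad(inner, -10, 20, limit=400, epsabs=0.0, epsrel=1e-10)
    assert err < 1e-8 * val
    return math.log(val)


def _log_marginal_null_numeric(y):
    n = len(y)
    yc = y - y.mean()
    tss = float(yc @ yc)

    def integrand(log_s):
        s2 = math.exp(2 * log_s)
        return math.exp(-(n - 1) / 2 * math.log(2 * math.pi * s2)
                        - 0.5 * math.log(n) - tss / (2 * s2))

    val, err = integrate.quad(integrand, -10, 20, limit=400, epsabs=0.0, epsrel=1e-12)
    assert err < 1e-9 * val
    return math.log(val)


@pytest.mark.parametrize("g", [math.sqrt(3), 3.0, 1.0])
def test_fixed_g_bf_matches_numerical_integration(g):
    """The closed-form Bayes factor equals the ratio of numerically
    integrated marginals on the three height pairs, to 1e-6."""
    x = np.array([62.5, 67.5, 70.5])
    y = np.array([64.5, 69.5, 72.5])
    log_bf_numeric = _log_marginal_numeric(y, x, g) - _log_marginal_null_numeric(y)
    closed = bb.log_bf_fixed_g(1.0, 3, 1, g)
    assert closed == pytest.approx(log_bf_numeric, abs=1e-6)


def test_father_son_bayes_factor_is_1_65(father_son):
    """At R^2 = 1 with n = 3, the g = sqrt(n) prior gives BF 1.65: positive
    but weak evidence instead of the infinite F-statistic."""
    r2, coef, rss = bb.model_fit_stats(father_son, np.array([1]))
    assert r2 == pytest.approx(1.0, abs=1e-12)
    bf = math.exp(bb.log_bf_fixed_g(r2, 3, 1, math.sqrt(3)))
    assert round(bf, 2) == 1.65
    # unit information prior g = n = 3 gives exactly (1+3)^(1/2) = 2
    assert math.exp(bb.log_bf_fixed_g(1.0, 3, 1, 3.0)) == pytest.approx(2.0, rel=1e-12)


def test_fit_stats_null_and_orthogonal():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((50, 3))
    X = (X - X.mean(0)) / X.std(0)
    y = rng.standard_normal(50)
    y -= y.mean()
    data = bb.RegressionData(X, y)
    r2, coef, rss = bb.model_fit_stats(data, np.zeros(3, dtype=int))
    assert r2 == 0.0 and coef.size == 0 and rss == pytest.approx(float(y @ y))
    # y orthogonal to an included column -> r2 = 0
    x0 = X[:, 0]
    y_perp = y - x0 * (x0 @ y) / (x0 @ x0)
    y_perp -= y_perp.mean()
    # re-orthogonalize after centering (centering x0 already: x0 has mean 0)
    y_perp = y_perp - x0 * (x0 @ y_perp) / (x0 @ x0)
    d2 = bb.RegressionData(X, y_perp - y_perp.mean())
    r2b, _, _ = bb.model_fit_stats(d2, np.array([1, 0, 0]))
    assert r2b == pytest.approx(0.0, abs=1e-12)


def test_fit_stats_error_paths():
    rng = np.random.default_rng(1)
    X = rng.standard_normal((10, 3))
    X[:, 2] = X[:, 1]  # duplicated column
    X = (X - X.mean(0)) / X.std(0)
    y = rng.standard_normal(10)
    data = bb.RegressionData(X, y - y.mean())
    with pytest.raises(RankDeficientModelError):
        bb.model_fit_stats(data, np.array([0, 1, 1]))
    Xw = rng.standard_normal((5, 4))
    Xw = (Xw - Xw.mean(0)) / Xw.std(0)
    yw = rng.standard_normal(5)
    dw = bb.RegressionData(Xw, yw - yw.mean())
    with pytest.raises(SaturatedModelError):
        bb.model_fit_stats(dw, np.ones(4, dtype=int))


@pytest.mark.parametrize("rule,n,p,expected", [
    ("sqrt_n", 100, 5, 10.0),
    ("benchmark", 50, 10, 100.0),
    ("one", 3116, 3116, 1.0),
    ("n", 40, 2, 40.0),
    (2.5, 40, 2, 2.5),
])
def test_resolve_g(rule, n, p, expected):
    assert bb.resolve_g(rule, n, p) == expected


def test_resolve_g_rejects_bad_rules():
    with pytest.raises(ValueError):
        bb.resolve_g("ric", 10, 2)
    with pytest.raises(ValueError):
        bb.resolve_g(-1.0, 10, 2)


def test_exact_formula_identity():
    """-2 log B == (n-1) log{1 + g(1-R^2)} - (n-1-d) log(1+g) on 200
    random tuples, to 1e-10."""
    rng = np.random.default_rng(42)
    for _ in range(200):
        n = int(rng.integers(5, 5000))
        d = int(rng.integers(1, min(n - 2, 40)))
        r2 = float(rng.random())
        g = float(rng.uniform(0.1, n * n))
        lhs = -2.0 * bb.log_bf_fixed_g(r2, n, d, g)
        rhs = (n - 1) * math.log(1 + g * (1 - r2)) - (n - 1 - d) * math.log(1 + g)
        assert lhs == pytest.approx(rhs, abs=1e-10 * max(1, abs(rhs)))


def test_bf_upper_bound_over_4_million_at_n_20():
    bf_max = math.exp(bb.max_log_bf_fixed_g(20, 1, math.sqrt(20)))
    assert bf_max > 4e6
    # attained at r2 = 1, and monotone in n under the sqrt(n) rule
    assert bb.max_log_bf_fixed_g(3, 1, math.sqrt(3)) == pytest.approx(
        bb.log_bf_fixed_g(1.0, 3, 1, math.sqrt(3)))
    sups = [bb.max_log_bf_fixed_g(n, 1, math.sqrt(n)) for n in (10, 100, 1000)]
    assert sups == sorted(sups)
    assert bb.max_log_bf_fixed_g(50, 0, 7.0) == 0.0


def test_information_paradox_dichotomy():
    """At R^2 -> 1 the fixed-g Bayes factor stays finite while hyper-g and
    EB-local diverge."""
    assert math.isfinite(bb.log_bf_fixed_g(1.0, 3, 1, math.sqrt(3)))
    assert bb.log_bf_hyper_g(1.0, 3, 1, 3.0) == math.inf
    assert bb.log_bf_eb_local(1.0, 3, 1) == math.inf
    # near-1 behaviour: hyper-g grows without bound, fixed-g saturates
    seq = [bb.log_bf_hyper_g(r2, 50, 2) for r2 in (0.99, 0.999, 0.9999)]
    assert seq == sorted(seq)
    assert seq[-1] > bb.log_bf_fixed_g(0.9999, 50, 2, math.sqrt(50)) > 0


def test_bartlett_paradox():
    """For fixed data with 0 < R^2 < 1 the fixed-g Bayes factor tends to
    -inf as g grows: unbounded prior variance selects the null model."""
    vals = [bb.log_bf_fixed_g(0.6, 50, 2, g) for g in (1e2, 1e6, 1e12, 1e24, 1e40)]
    assert all(a > b for a, b in zip(vals, vals[1:]))
    assert vals[-1] < -30


def test_nesting_monotonicity_and_null_anchors():
    """Adding a variable that leaves R^2 unchanged strictly lowers every
    Bayes factor with d in its penalty; the null model scores 0 under all
    six variants."""
    r2, n = 0.5, 100
    for fn in (lambda d: bb.log_bf_fixed_g(r2, n, d, 10.0),
               lambda d: bb.log_bf_hyper_g(r2, n, d),
               lambda d: bb.log_bf_eb_local(r2, n, d),
               lambda d: bb.log_bf_jzs(r2, n, d),
               lambda d: bb.log_weight_ic("bic", r2, n, d),
               lambda d: bb.log_weight_ic("aic", r2, n, d)):
        assert fn(3) < fn(2)
    for spec in [bb.GPriorSpec("fixed_g", "sqrt_n"), bb.GPriorSpec("hyper_g"),
                 bb.GPriorSpec("eb_local"), bb.GPriorSpec("jzs"),
                 bb.GPriorSpec("bic"), bb.GPriorSpec("aic")]:
        assert spec.log_marginal(0.0, n, 0, 5) == 0.0


def test_hyper_g_against_quadrature_oracle():
    """Closed form equals the 1-D integral of the fixed-g BF against the
    hyper-g density pi(g) = ((a-2)/2)(1+g)^(-a/2)."""
    for (r2, n, d, a) in [(0.5, 50, 3, 3.0), (0.2, 20, 1, 4.0), (0.9, 200, 5, 3.0)]:
        def f(g):
            return math.exp(bb.log_bf_fixed_g(r2, n, d, g)) * (a - 2) / 2 * (1 + g) ** (-a / 2)
        val, _ = integrate.quad(f, 0, np.inf, limit=400)
        assert bb.log_bf_hyper_g(r2, n, d, a) == pytest.approx(math.log(val), abs=1e-6)
    # internal log-space quadrature agrees with the closed form too
    assert _log_bf_hyper_g_quad(0.5, 50, 3, 3.0) == pytest.approx(
        bb.log_bf_hyper_g(0.5, 50, 3, 3.0), abs=1e-7)


def test_hyper_g_validates():
    with pytest.raises(ValueError):
        bb.log_bf_hyper_g(0.5, 50, 3, a=2.0)
    assert bb.log_bf_hyper_g(0.7, 50, 0) == 0.0


def test_eb_local_grid_search_oracle():
    """EB-local equals the maximum over g of the fixed-g log Bayes factor."""
    r2, n, d = 0.5, 50, 3
    gs = np.geomspace(1e-6, 1e8, 200_001)
    lb = (0.5 * (n - 1 - d) * np.log1p(gs) - 0.5 * (n - 1) * np.log1p(gs * (1 - r2)))
    assert bb.log_bf_eb_local(r2, n, d) == pytest.approx(float(lb.max()), abs=1e-6)
    # clipped-at-zero branch: F <= 1 -> g-hat = 0 -> log BF = 0
    assert bb.log_bf_eb_local(0.01, 50, 10) == 0.0
    with pytest.raises(SaturatedModelError):
        bb.log_bf_eb_local(0.5, 5, 4)


def test_jzs_against_monte_carlo_oracle():
    """Quadrature agrees with a brute-force Monte Carlo average of the
    fixed-g BF over draws of g ~ inverse-gamma(1/2, n/2), within 3 MC SE."""
    r2, n, d = 0.5, 50, 3
    g = stats.invgamma(0.5, scale=n / 2).rvs(size=1_000_000,
                                             random_state=np.random.default_rng(7))
    lbf = 0.5 * (n - 1 - d) * np.log1p(g) - 0.5 * (n - 1) * np.log1p(g * (1 - r2))
    m = lbf.max()
    w = np.exp(lbf - m)
    est = m + math.log(w.mean())
    se_log = w.std() / (math.sqrt(len(w)) * w.mean())
    assert bb.log_bf_jzs(r2, n, d) == pytest.approx(est, abs=3 * se_log)


def test_jzs_against_laplace_oracle():
    """Laplace approximation to the same integral agrees to 2 significant
    digits at r2=0.9, n=200, d=5."""
    r2, n, d = 0.9, 200, 5

    def neg_logint(logg):
        g = math.exp(logg)
        # integrand over log g: BF(g) pi(g) g
        return -(0.5 * (n - 1 - d) * math.log1p(g) - 0.5 * (n - 1) * math.log1p(g * (1 - r2))
                 + 0.5 * math.log(n / 2) - math.lgamma(0.5) - 1.5 * math.log(g)
                 - n / (2 * g) + logg)

    from scipy.optimize import minimize_scalar
    res = minimize_scalar(neg_logint, bounds=(-5, 20), method="bounded")
    h = 1e-4
    second = (neg_logint(res.x + h) - 2 * neg_logint(res.x) + neg_logint(res.x - h)) / h ** 2
    laplace = -res.fun + 0.5 * math.log(2 * math.pi / second)
    assert bb.log_bf_jzs(r2, n, d) == pytest.approx(laplace, rel=0.01)
    assert bb.log_bf_jzs(0.3, 50, 0) == 0.0


def test_ic_weights_match_statsmodels_differences():
    """BIC/AIC log-weight differences reproduce the standard information
    criteria computed by an independent OLS fit."""
    import statsmodels.api as sm

    assert bb.log_weight_ic("bic", 0.0, 100, 0) == 0.0
    assert bb.log_weight_ic("bic", 0.5, 100, 2) == pytest.approx(
        -(100 * math.log(0.5) + 2 * math.log(100)) / 2)

    rng = np.random.default_rng(3)
    X = rng.standard_normal((80, 4))
    X = (X - X.mean(0)) / X.std(0)
    y = X[:, 0] * 0.7 + rng.standard_normal(80)
    y -= y.mean()
    data = bb.RegressionData(X, y)
    scorer = ModelScorer(data)
    gam1 = np.array([1, 0, 0, 0], dtype=bool)
    gam2 = np.array([1, 1, 0, 1], dtype=bool)
    for crit, attr in (("bic", "bic"), ("aic", "aic")):
        ours = []
        theirs = []
        for gam in (gam1, gam2):
            r2, _, _ = scorer.fit(gam)
            ours.append(bb.log_weight_ic(crit, r2, data.n, int(gam.sum())))
            fit = sm.OLS(y, sm.add_constant(X[:, gam])).fit()
            theirs.append(getattr(fit, attr))
        # IC = -2 log weight + shared constant, so differences match
        assert (ours[1] - ours[0]) == pytest.approx(-(theirs[1] - theirs[0]) / 2, abs=1e-8)


def test_half_penalty_relation():
    """The per-variable penalty log(1 + sqrt(n)) in the exact g = sqrt(n)
    Bayes factor is within 10% of (log n)/2 — half the BIC's log n —
    across n from 1e2 to 1e5."""
    for n in (100, 1000, 10_000, 100_000):
        exact_penalty = math.log(1 + math.sqrt(n))
        assert exact_penalty == pytest.approx(math.log(n) / 2, rel=0.10)


def test_ic_weight_r2_one_flagged():
    with pytest.warns(UserWarning):
        assert bb.log_weight_ic("bic", 1.0, 10, 2) == math.inf


def test_model_log_prior_enumeration():
    """Beta-binomial(1,1) masses over p=2: {1/3, 1/6, 1/6, 1/3}, summing
    to 1 (enumeration oracle)."""
    spec = bb.ModelPriorSpec("beta_binomial_11")
    masses = [math.exp(bb.model_log_prior(spec, d, 2, 100)) for d in (0, 1, 1, 2)]
    assert masses == pytest.approx([1 / 3, 1 / 6, 1 / 6, 1 / 3])
    assert sum(masses) == pytest.approx(1.0)

    uni = bb.ModelPriorSpec("uniform")
    assert bb.model_log_prior(uni, 2, 3, 100) == pytest.approx(math.log(1 / 8))

    trunc = bb.ModelPriorSpec("truncated_beta_binomial_11")
    assert bb.model_log_prior(trunc, 9, 120, 10) == -math.inf
    # truncated masses renormalize to 1 over admissible sizes
    from scipy.special import comb
    total = sum(comb(5, d) * math.exp(bb.model_log_prior(trunc, d, 5, 6))
                for d in range(5))
    assert total == pytest.approx(1.0)
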