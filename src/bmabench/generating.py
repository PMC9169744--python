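"""Deriving a data-generating model from a dataset, and re-simulating it.

The pipeline mirrors a standard workflow for building an empirically
grounded simulation: (1) if there are more than 30 candidate predictors,
screen down to 30 by (iterative) sure independence screening and
univariate R^2 ranking; (2) find the best subset of each size by
branch-and-bound all-subsets regression; (3) take the largest size whose
best model has every coefficient significant at the 0.05 level, and refit
it by OLS to obtain the generating coefficients, intercept and noise SD;
(4) re-simulate responses from that model by the parametric bootstrap,
keeping the design matrix fixed.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import RegressionData
from .gprior import ModelScorer

__all__ = [
    "GeneratingModel",
    "screen_variables",
    "best_subset_search",
    "select_generating_model",
    "parametric_bootstrap",
    "train_test_split",
]


@dataclass
class GeneratingModel:
    """The data-generating truth for a simulation study."""

    support: np.ndarray          # binary length-p inclusion vector
    beta_DG: np.ndarray          # length-p, zero off support
    alpha_DG: float
    sigma_DG: float
    r2_source: float

    def __post_init__(self):
        self.support = np.asarray(self.support, dtype=np.uint8)
        self.beta_DG = np.asarray(self.beta_DG, dtype=float)
        on = self.support.astype(bool)
        if np.any(self.beta_DG[~on] != 0.0):
            raise ValueError("beta_DG must be zero off the support")
        if self.sigma_DG < 0:
            raise ValueError("sigma_DG must be nonnegative")

    @property
    def size(self) -> int:
        return int(self.support.sum())

    def to_json(self) -> str:
        return json.dumps({
            "support": "".join(str(int(b)) for b in self.support),
            "beta": list(map(float, self.beta_DG)),
            "alpha": self.alpha_DG,
            "sigma": self.sigma_DG,
            "r2_source": self.r2_source,
        })

    @classmethod
    def from_json(cls, s: str) -> "GeneratingModel":
        obj = json.loads(s)
        return cls(
            support=np.array([int(c) for c in obj["support"]], dtype=np.uint8),
            beta_DG=np.array(obj["beta"], dtype=float),
            alpha_DG=float(obj["alpha"]),
            sigma_DG=float(obj["sigma"]),
            r2_source=float(obj["r2_source"]),
        )


# ---------------------------------------------------------------------------
# Screening


def _univariate_r2(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Univariate R^2 of y on each (centered) column: (x'y)^2 / (x'x y'y)."""
    ssy = float(y @ y)
    if ssy == 0:
        return np.zeros(X.shape[1])
    ssx = np.sum(X ** 2, axis=0)
    return np.where(ssx > 0, (X.T @ y) ** 2 / (ssx * ssy), 0.0)


def screen_variables(data: RegressionData, target_count: int = 30,
                     iterative: bool = True) -> np.ndarray:
    """Reduce to ``target_count`` variables by sure independence screening.

    Non-iterative mode ranks by univariate R^2. Iterative mode takes half
    the budget by marginal ranking, fits OLS on that block, re-ranks the
    remaining variables by correlation with the residual, and fills the
    rest of the budget — recovering signals masked by correlated decoys.
    Returns the selected column indices in rank order. With p <= target
    (or target >= p/2 in iterative mode, where a second round adds little)
    screening degenerates gracefully.
    """
    p = data.p
    if p <= target_count:
        return np.arange(p)
    r2 = _univariate_r2(data.X, data.y)
    order = np.argsort(-r2, kind="stable")
    if not iterative or target_count >= p / 2:
        return order[:target_count]
    k1 = max(target_count // 2, 1)
    first = order[:k1]
    gamma = np.zeros(p, dtype=bool)
    gamma[first] = True
    _, coef, _ = ModelScorer(data).fit(gamma)
    resid = data.y - data.X[:, first] @ coef
    rest = order[k1:]
    rr2 = _univariate_r2(data.X[:, rest], resid)
    second = rest[np.argsort(-rr2, kind="stable")][: target_count - k1]
    return np.concatenate([first, second])


# ---------------------------------------------------------------------------
# Best-subset (all-subsets) regression by branch and bound


def best_subset_search(data: RegressionData, max_p: int = 30) -> dict[int, tuple[np.ndarray, float]]:
    """Best (max-R^2) model of each size, by branch-and-bound.

    Uses the monotone RSS bound: the RSS of the model spanned by a node's
    included and remaining candidate variables lower-bounds the RSS of any
    completion, so subtrees that cannot beat the incumbent of a size are
    pruned. Exhaustive (every subset visited or provably dominated) for
    any p <= max_p; variables are pre-ordered by univariate R^2 to tighten
    pruning. Returns {size: (gamma, r2)} for sizes 1..min(p, n-2).
    """
    p = data.p
    if p > max_p:
        raise ValueError(
            f"p = {p} exceeds max_p = {max_p}; screen_variables first")
    scorer = ModelScorer(data)
    kmax = min(p, data.n - 2)
    order = np.argsort(-_univariate_r2(data.X, data.y), kind="stable")

    rss_cache: dict[frozenset, float] = {}

    def rss_of(idx: frozenset) -> float:
        if idx not in rss_cache:
            gamma = np.zeros(p, dtype=bool)
            gamma[list(idx)] = True
            try:
                _, _, rss = scorer.fit(gamma)
            except Exception:
                rss = math.inf
            rss_cache[idx] = rss
        return rss_cache[idx]

    best: dict[int, tuple[frozenset, float]] = {}

    def visit(included: frozenset, pos: int):
        k = len(included)
        if 1 <= k <= kmax:
            r = rss_of(included)
            if k not in best or r < best[k][1]:
                best[k] = (included, r)
        if k == kmax or pos == p:
            return
        remaining = [int(order[i]) for i in range(pos, p)]
        # bound: no completion from this node can beat rss(included + rest)
        hull = included | frozenset(remaining)
        lb = rss_of(hull) if len(hull) <= data.n - 2 else 0.0
        improvable = any(
            kk not in best or lb < best[kk][1] - 1e-12
            for kk in range(k + 1, min(kmax, k + len(remaining)) + 1)
        )
        if not improvable:
            return
        for i in range(pos, p):
            visit(included | {int(order[i])}, i + 1)

    import sys
    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, p + 100))
    try:
        visit(frozenset(), 0)
    finally:
        sys.setrecursionlimit(old)

    out = {}
    for k, (idx, rss) in sorted(best.items()):
        gamma = np.zeros(p, dtype=np.uint8)
        gamma[list(idx)] = 1
        out[k] = (gamma, 1.0 - rss / scorer.tss if scorer.tss > 0 else 0.0)
    return out


def _ols_refit(data: RegressionData, gamma: np.ndarray):
    """Unshrunken OLS refit with residual SD and per-coefficient p-values."""
    gamma = np.asarray(gamma, dtype=bool)
    d = int(gamma.sum())
    scorer = ModelScorer(data)
    r2, coef, rss = scorer.fit(gamma)
    n = data.n
    dof = n - d - 1  # intercept estimated implicitly by centering
    sigma = math.sqrt(rss / dof) if dof > 0 else 0.0
    if d == 0:
        return r2, coef, sigma, np.zeros(0)
    Gs = data.X[:, gamma].T @ data.X[:, gamma]
    cov = np.linalg.inv(Gs) * (rss / dof if dof > 0 else 0.0)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, coef / se, np.inf)
    pvals = 2.0 * stats.t.sf(np.abs(tstat), dof) if dof > 0 else np.zeros(d)
    return r2, coef, sigma, pvals


def select_generating_model(data: RegressionData, max_p: int = 30,
                            sig_level: float = 0.05) -> GeneratingModel:
    """Largest best-per-size model with all coefficients significant.

    Walks the best-subset table from the largest size down and returns the
    first model in which every coefficient's two-sided t-test has
    p < ``sig_level``; if no size qualifies, falls back to the best
    single-variable model with a warning. The chosen support is refit by
    OLS to give the generating coefficients and residual SD.
    """
    table = best_subset_search(data, max_p=max_p)
    chosen = None
    for k in sorted(table, reverse=True):
        gamma, _ = table[k]
        _, _, _, pvals = _ols_refit(data, gamma)
        if len(pvals) and np.all(pvals < sig_level):
            chosen = gamma
            break
    if chosen is None:
        warnings.warn("no model has all coefficients significant; "
                      "falling back to the best single-variable model")
        chosen = table[min(table)][0]
    r2, coef, sigma, _ = _ols_refit(data, chosen)
    beta = np.zeros(data.p)
    beta[chosen.astype(bool)] = coef
    return GeneratingModel(support=chosen, beta_DG=beta, alpha_DG=0.0,
                           sigma_DG=sigma, r2_source=r2)


# ---------------------------------------------------------------------------
# Parametric bootstrap and splits


def parametric_bootstrap(gm: GeneratingModel, X: np.ndarray,
                         n_reps: int = 100, seed: int = 0) -> np.ndarray:
    """Simulate responses y* = alpha + X beta + N(0, sigma^2) per replicate.

    Returns an (n_reps, n) array; the design is held fixed across
    replicates and replicates are independent given the seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    mean = gm.alpha_DG + X @ gm.beta_DG
    eps = rng.standard_normal((n_reps, X.shape[0])) * gm.sigma_DG
    return mean[None, :] + eps


def train_test_split(n: int, fraction: float = 0.75, n_splits: int = 100,
                     seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Random disjoint, exhaustive train/test index pairs.

    The train size is ceil(fraction * n); with fraction 0.75 and n = 100
    this is the usual 75-25 split.
    """
    if n < 8:
        raise ValueError("n must be >= 8 to split")
    rng = np.random.default_rng(seed)
    n_train = math.ceil(fraction * n)
    out = []
    for _ in range(n_splits):
        perm = rng.permutation(n)
        out.append((np.sort(perm[:n_train]), np.sort(perm[n_train:])))
    return out
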