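"""Posterior over the model space: exact enumeration and MC3 sampling.

For p candidate predictors there are 2^p submodels; up to p = 25 (hard cap,
configurable) the posterior can be enumerated exactly. Beyond that the
model space is explored by MC3: a Metropolis-Hastings random walk over
inclusion vectors whose proposal mixes single-variable add/delete moves
with a random swap between a currently included and a currently excluded
variable. Posterior masses from MC3 are estimated by visit frequencies
(the estimator recommended for MCMC-based model search); renormalized
marginal-likelihood masses over the unique visited models are kept as a
diagnostic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .data import RegressionData
from .gprior import (
    GPriorSpec,
    ModelPriorSpec,
    ModelScore,
    ModelScorer,
    RankDeficientModelError,
    SaturatedModelError,
)

__all__ = ["PosteriorOverModels", "enumerate_posterior", "mc3_sample", "map_model"]

ENUMERATION_CAP = 25


@dataclass
class PosteriorOverModels:
    """Distinct visited models with normalized posterior masses."""

    models: list[ModelScore]
    posterior_mass: np.ndarray
    inclusion_prob: np.ndarray
    method: str
    n_iterations: int = 0
    visit_counts: np.ndarray | None = None
    renormalized_mass: np.ndarray | None = None

    @property
    def p(self) -> int:
        return len(self.inclusion_prob)

    def expected_model_size(self) -> float:
        return float(np.sum(self.inclusion_prob))

    def to_json(self) -> str:
        payload = {
            "method": self.method,
            "n_iterations": self.n_iterations,
            "models": [
                {
                    "gamma": "".join(str(int(b)) for b in m.gamma),
                    "r2": m.r2,
                    "log_marginal": m.log_marginal,
                    "log_prior": m.log_prior,
                    "mass": float(w),
                }
                for m, w in zip(self.models, self.posterior_mass)
            ],
            "inclusion_prob": [float(q) for q in self.inclusion_prob],
        }
        return json.dumps(payload)


def _score_model(scorer: ModelScorer, gamma: np.ndarray, gspec: GPriorSpec,
                 mprior: ModelPriorSpec) -> ModelScore | None:
    """Score a model; returns None for inadmissible (zero-prior) models.

    Rank-deficient or saturated models get prior mass zero rather than
    erroring the search, mirroring the intent of the truncated prior in
    the p > n regime.
    """
    n, p = scorer.n, scorer.p
    d = int(gamma.sum())
    lp = mprior.log_prior(d, p, n)
    if lp == -math.inf:
        return None
    try:
        r2, _, _ = scorer.fit(gamma)
    except (RankDeficientModelError, SaturatedModelError):
        return None
    lm = gspec.log_marginal(r2, n, d, p)
    if lm == math.inf:
        # A saturated (r2 = 1) fit dominates everything; keep it but flag.
        lm = 1e300
    return ModelScore(gamma=gamma.copy(), r2=r2, log_marginal=lm, log_prior=lp)


def _inclusion_from_masses(models: list[ModelScore], mass: np.ndarray, p: int) -> np.ndarray:
    incl = np.zeros(p)
    for m, w in zip(models, mass):
        incl[m.gamma.astype(bool)] += w
    return np.clip(incl, 0.0, 1.0)


def enumerate_posterior(data: RegressionData, gspec: GPriorSpec,
                        mprior: ModelPriorSpec | None = None,
                        cap: int = ENUMERATION_CAP) -> PosteriorOverModels:
    """Exact posterior over all 2^p models (p <= cap)."""
    mprior = mprior or ModelPriorSpec()
    p = data.p
    if p > cap:
        raise ValueError(
            f"p = {p} exceeds the enumeration cap ({cap}); use mc3_sample instead"
        )
    scorer = ModelScorer(data)
    models: list[ModelScore] = []
    for code in range(1 << p):
        gamma = np.array([(code >> j) & 1 for j in range(p)], dtype=np.uint8)
        ms = _score_model(scorer, gamma, gspec, mprior)
        if ms is not None:
            models.append(ms)
    if not models:
        raise ValueError("no admissible model under this prior")
    logw = np.array([m.log_marginal + m.log_prior for m in models])
    mass = np.exp(logw - logsumexp(logw))
    mass /= mass.sum()
    return PosteriorOverModels(
        models=models,
        posterior_mass=mass,
        inclusion_prob=_inclusion_from_masses(models, mass, p),
        method="enumeration",
    )


def mc3_sample(data: RegressionData, gspec: GPriorSpec,
               mprior: ModelPriorSpec | None = None,
               n_iter: int = 10_000, seed: int = 0,
               swap_prob: float = 0.5, burn_in: int = 0) -> PosteriorOverModels:
    """MC3 Metropolis-Hastings over inclusion vectors.

    Proposal mixture: with probability ``swap_prob`` a random swap of one
    included variable for one excluded variable (size-preserving), else a
    uniform single-coordinate add/delete flip; degenerate cases (empty or
    full model) fall back to add/delete. Both proposals are symmetric, so
    acceptance is by the ratio of marginal x prior. Deterministic given
    (data, seed). No burn-in by default: the visit-frequency estimator uses
    the full chain.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    mprior = mprior or ModelPriorSpec()
    rng = np.random.default_rng(seed)
    scorer = ModelScorer(data)
    p = data.p

    cache: dict[bytes, ModelScore | None] = {}

    def score(gamma: np.ndarray) -> ModelScore | None:
        key = gamma.tobytes()
        if key not in cache:
            cache[key] = _score_model(scorer, gamma, gspec, mprior)
        return cache[key]

    gamma = np.zeros(p, dtype=np.uint8)
    current = score(gamma)
    if current is None:
        raise ValueError("null model inadmissible under the supplied prior")

    visit: dict[bytes, int] = {}
    incl_sum = np.zeros(p)
    kept = 0
    for it in range(n_iter):
        d = int(gamma.sum())
        prop = gamma.copy()
        use_swap = rng.random() < swap_prob and 0 < d < p
        if use_swap:
            inc = np.flatnonzero(gamma)
            exc = np.flatnonzero(gamma == 0)
            prop[inc[rng.integers(len(inc))]] = 0
            prop[exc[rng.integers(len(exc))]] = 1
        else:
            j = rng.integers(p)
            prop[j] = 1 - prop[j]
        cand = score(prop)
        if cand is not None:
            delta = (cand.log_marginal + cand.log_prior
                     - current.log_marginal - current.log_prior)
            if delta >= 0 or rng.random() < math.exp(delta):
                gamma, current = prop, cand
        if it >= burn_in:
            visit[gamma.tobytes()] = visit.get(gamma.tobytes(), 0) + 1
            incl_sum += gamma
            kept += 1

    keys = list(visit.keys())
    models = [cache[k] for k in keys]
    counts = np.array([visit[k] for k in keys], dtype=float)
    mass = counts / counts.sum()
    logw = np.array([m.log_marginal + m.log_prior for m in models])
    renorm = np.exp(logw - logsumexp(logw))
    renorm /= renorm.sum()
    return PosteriorOverModels(
        models=models,
        posterior_mass=mass,
        inclusion_prob=incl_sum / kept,
        method="mc3",
        n_iterations=n_iter,
        visit_counts=counts,
        renormalized_mass=renorm,
    )


def map_model(post: PosteriorOverModels) -> np.ndarray:
    """Highest-posterior-mass model; ties go to the smaller model, then to
    the lexicographically smaller inclusion vector."""
    if not post.models:
        raise ValueError("empty posterior")
    best = None
    best_key = None
    for m, w in zip(post.models, post.posterior_mass):
        key = (-w, m.d, tuple(m.gamma))
        if best_key is None or key < best_key:
            best, best_key = m, key
    return best.gamma.copy()
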