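# Methods

## Model and priors

All machinery targets the Gaussian linear model

    y = α·1ₙ + X_γ β_γ + ε,   ε ~ N(0, σ² I),

where γ ∈ {0,1}ᵖ selects a subset of candidate predictors. Predictors are
standardized to mean 0, variance 1 and the response is centered, so the
intercept and error scale can carry the improper reference prior
π(α, σ) ∝ 1/σ and drop out of every model comparison. The included
coefficients carry Zellner's g-prior

    β_γ | σ², g ~ N(0, g σ² (X_γᵀX_γ)⁻¹).

Integrating (α, β_γ, σ) gives the exact null-referenced log Bayes factor

    log B_γ = ((n−1−d)/2)·log(1+g) − ((n−1)/2)·log(1+g(1−R²_γ)),

with d = |γ| and R²_γ the OLS coefficient of determination. Every variant in
the package reduces to a choice about g:

| variant   | g                                   | notes |
|-----------|-------------------------------------|-------|
| fixed_g   | √n, n (UIP), 1, max(n, p²), or any positive number | finite BF even at R² = 1 (information-paradox ceiling ((n−1−d)/2)·log(1+g)) |
| hyper_g   | π(g) ∝ (1+g)^(−a/2), a > 2          | closed form ((a−2)/(d+a−2))·₂F₁((n−1)/2, 1; (d+a)/2; R²); diverges as R² → 1 |
| eb_local  | ĝ = max(F−1, 0) per model           | F is the model's overall F statistic; plug-in into the fixed-g form |
| jzs       | g ~ InvGamma(1/2, n/2)              | Zellner–Siow Cauchy on β; 1-D quadrature |
| bic / aic | approximate weights                 | −(n·log(1−R²) + pen)/2 with pen = d·log n or 2d |

The hyper-g hyperparameter defaults to a = 3, the value its originators
recommend; it is configurable because nothing in the comparison pins it
down.

Model-space prior: beta-binomial(1,1) by default (uniform on size, uniform
within size); for p > n a truncated variant assigns zero mass to models
with more than n−2 variables and renormalizes. Rank-deficient or saturated
submodels are treated as zero-prior-mass rather than errors, mirroring the
truncation's intent.

## Numerical choices

- **JZS integral.** Evaluated on u = g/(1+g) ∈ (0,1) to tame the heavy
  tail; the log-integrand is exponentiated about its grid-located maximum
  and integrated by adaptive quadrature (relative tolerance 1e-10, warning
  above 1e-8). Results are cached per (R², n, d).
- **Hyper-g.** scipy's ₂F₁ is the fast path. It overflows float64 once
  log B exceeds ~709, which happens routinely for n in the thousands; the
  same quantity is then computed as the 1-D mixture integral of the
  fixed-g Bayes factor against π(g), in log space, by the same stabilized
  quadrature (agrees with 50-digit arithmetic to ≤1e-7 relative).
  High-precision arithmetic is retained for R² > 0.95 at small n, where
  the hypergeometric series suffers cancellation, and for the convergent
  R² = 1 boundary case.
- **OLS sufficient statistics.** Each dataset precomputes XᵀX, Xᵀy and the
  total sum of squares once; every submodel fit is a Cholesky solve of the
  relevant Gram submatrix. Cholesky failure, or a diagonal ratio below
  1e-8, flags rank deficiency.
- **Ties in MAP selection** break toward the smaller model, then the
  lexicographically smaller inclusion vector.

## Model search

Up to p = 25 the 2ᵖ models are enumerated and masses normalized by
log-sum-exp. Beyond that, MC3: a Metropolis–Hastings chain over inclusion
vectors whose proposal mixes, with probability ½ each, a uniform
single-coordinate add/delete flip and a random swap of one included for
one excluded variable (degenerate states fall back to add/delete). Both
proposals are symmetric, so acceptance uses the ratio of marginal × prior.
Posterior masses and inclusion probabilities are estimated by visit
frequencies over the full chain — the estimator recommended for MCMC model
search — with renormalized-marginal masses stored as a diagnostic. There
is no burn-in by default (configurable): the frequency estimator is
consistent from any start, and the null-model start is admissible under
every prior here.

## BMA and BMS inference

Conditional on (γ, g), the posterior is the standard conjugate one:
σ² | y ~ InvGamma((n−1)/2, SSR_g/2) with SSR_g = TSS·(1 − w·R²_γ) and
w = g/(1+g); β_γ | σ², y ~ N(w·β̂_γ, σ²·w·(X_γᵀX_γ)⁻¹); α | σ² ~ N(0, σ²/n).
Adaptive variants draw g per sample from its conditional posterior
p(g | γ, y) ∝ BF_fixed(g)·π(g) by inverse-CDF sampling on a 2048-point grid
in u = g/(1+g); EB-local uses its plug-in ĝ; the BIC and AIC weight
approximations use plug-in g = n and g = 1 respectively (the priors they
approximate). Posterior means are computed analytically as mass-weighted
mixtures of w·β̂_γ (with E[w] from the same grid for adaptive variants);
intervals are equal-tailed quantiles of 10,000 seeded mixture draws by
default, including the point mass at zero contributed by models that
exclude a variable. Equal-tailed (not HPD) intervals are used because the
interval score is defined through bounds (l, u). Predictive draws add
intercept and noise uncertainty.

BMS (Bayesian model selection) runs the identical machinery on a posterior
degenerate at the MAP model.

Intervals for variables with inclusion probability 0 are the degenerate
[0, 0]; for partially included variables the mixture quantiles may or may
not span zero — this convention (rather than forcing [0, 0] for excluded
coordinates of each draw separately) is what the interval score then
evaluates.

## Penalized baselines

Lasso (CV-min and 1-SE) and elastic net minimize
‖y − Xb‖²/(2n) + λ·penalty(b) over a fixed grid of 100 log-spaced λ values
from λ_max = max_j |x_jᵀy|/n down to 1e-4·λ_max, with 5-fold
cross-validation by default. The 1-SE rule takes the sparsest λ whose CV
risk is within one standard error of the minimum. The elastic net tunes
its convex mixing weight over {0.25, 0.5, 0.75} (the comparison it comes
from does not state a value). The coordinate-descent solver is
scikit-learn's; the grid/fold/rule contract is fixed here so results are
solver-portable.

## Generating models and the parametric bootstrap

To ground simulations in a dataset, the pipeline (1) screens to 30
variables when p > 30 — sure independence screening by univariate R², with
an iterative variant that spends half the budget marginally, refits, and
re-ranks the remainder against the residual to recover signals masked by
correlated decoys; (2) finds the best subset of each size by
branch-and-bound all-subsets regression using the monotone RSS bound
(variables pre-ordered by univariate R² to tighten pruning); (3) selects
the largest size whose best model has every coefficient significant at the
0.05 level by two-sided t-test, falling back to the best single-variable
model with a warning when nothing qualifies. The significance filter scans
only the best-R² model of each size (the natural reading of a
leaps-then-filter workflow; scanning all models of a size is the
alternative). The chosen support is refit by OLS to give the generating
coefficients and residual SD; responses are then re-simulated as
y* = α + Xβ + N(0, σ²) with the design fixed. Train–test splits use
ceil(0.75·n) training rows.

## Synthetic benchmark suite

Four presets cover the corners of the (n, p) plane seen in real
variable-selection benchmarks: tall_small (500×15), tall_large (2000×30),
square (150×100), wide (60×300, p > n). All use AR(1) predictor
correlation ρ = 0.5, sparse supports (5, 8, 5, 5), generating R² of 0.7,
0.8, 0.7, 0.8, and coefficient magnitudes decaying geometrically (base
0.5; decay 0.60–0.72 by preset). The decay rates implement the structural
property of generating models derived from data by the
all-coefficients-significant-at-0.05 rule: no hopeless effects. With
these rates the weakest coefficient has |t| ≈ 2.9–3.3 on the source fit —
significant on essentially every source design and most bootstrap
replicates, yet far from certain recovery, so the support-recovery metric
stays informative. (A sharper calibration putting the weakest effect
exactly at the |t| ≈ 2.2 boundary on average was evaluated and rejected:
averaged calibration leaves the weakest coefficient non-significant on
roughly half the design seeds, violating the very rule it emulates.) At
these sample sizes and R² values the leading coefficients are necessarily
strong (t in the tens); only the tail is marginal, as in real generating
models. Designs are Gaussian; discrete,
skewed, or heavy-tailed covariates found in real tables are not emulated,
so passing benchmarks here says nothing about robustness to those
features. The noise SD is solved analytically from the target R² under
the empirical predictor covariance, and generation is fully determined by
a single seed.

## Benchmark harness and scoring

Per dataset replicate, the full-data fit yields coefficient RMSE
(PointEst), mean interval score of the coefficient intervals (IntEst,
α = 0.05), 1 − AUPRC of support recovery (Inference; inclusion-probability
ranking for Bayesian methods, path-entry sweep for penalized ones), and
the model size (expected size Σ inclusion probabilities for BMA — the MAP
size is reported for BMS rows); random 75–25 splits yield out-of-sample
R²_test and the predictive mean interval score, averaged over splits
within a replicate, then over replicates. AUPRC uses step-function
(average-precision) integration with tie groups as single thresholds,
avoiding optimistic interpolation.

Relative tables divide each per-dataset method mean by the reference
method's (JZS) matched value and average across datasets with equal
weight. Because Score averaging needs a common lower-is-better
orientation, the Prediction column enters as the relative prediction RMSE
√(1−R²_test) ratio — the shared baseline denominator cancels, so this is
exactly the ratio of test RMSEs. Score is the mean of the five relative
metrics; interval-free methods get PartScore over the remaining three and
are interleaved into the ranking as highly as possible without disturbing
the Score order.

## Scaled problem sizes

The shipped benchmark configuration used by the test suite runs 25
bootstrap replicates per preset, 2 train–test splits per replicate, 1500
MC3 iterations and 2000 posterior draws — deliberately smaller than the
reference configuration of 100 replicates, 100 splits and 10,000
iterations, which the config defaults preserve. MC3↔enumeration agreement
is verified separately at 10,000 and 100,000 iterations, and the
qualitative comparisons (method ranking direction, BMA vs BMS direction)
are stable at the scaled sizes.

## Known limitations

- Gaussian designs only; no discrete covariates, outliers, or
  heteroscedasticity.
- EB-global, nonlocal priors, horseshoe, spike-and-slab, EMVS, SS-LASSO,
  SCAD and MCP are out of scope.
- The MC3 estimator's visit-frequency masses are biased for models never
  visited; inclusion probabilities inherit ordinary MCMC error.
- Branch-and-bound all-subsets is exhaustive but can be slow beyond
  p ≈ 20 on strongly correlated designs.
- CPU time is not a benchmark metric (hardware- and implementation-bound).
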