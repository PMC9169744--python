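"""Orchestration: methods x replicates x splits, and relative score tables.

For each dataset replicate the full-data fit yields the estimation metrics
(PointEst, IntEst, Inference, N vars); random 75-25 train-test splits
yield the prediction metrics (Prediction, IntPred), averaged over splits
within a replicate and then over replicates. Per-method metrics are
averaged within each dataset, divided by the dataset-matched value of the
reference method (JZS by default), and averaged across datasets with equal
weight. ``Score`` is the mean of the five relative metrics; methods
without interval metrics get the ``PartScore`` over the remaining three.
Lower is better throughout: the Prediction column enters the relative
table as relative test-set prediction RMSE, i.e. sqrt(1 - R^2_test) ratios,
so that all five columns share the lower-is-better orientation.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import RegressionData, standardize
from .generating import train_test_split
from .gprior import GPriorSpec, ModelPriorSpec
from .inference import bma_coefficients, bma_predict, bms_infer
from .metrics import (
    MetricRecord,
    auprc,
    mean_interval_score,
    path_entry_scores,
    r2_test,
    rmse_coefficients,
)
from .penalized import fit_penalized
from .search import enumerate_posterior, map_model, mc3_sample
from .synthetic import SyntheticDataset

logger = logging.getLogger("bmabench")

__all__ = ["BenchmarkConfig", "BAYES_METHODS", "PENALIZED_METHODS",
           "run_benchmark", "relative_score_table", "compare_bma_bms"]

BAYES_METHODS: dict[str, GPriorSpec] = {
    "g-sqrt-n": GPriorSpec("fixed_g", "sqrt_n"),
    "UIP": GPriorSpec("fixed_g", "n"),
    "g-1": GPriorSpec("fixed_g", "one"),
    "benchmark": GPriorSpec("fixed_g", "benchmark"),
    "hyper-g": GPriorSpec("hyper_g"),
    "EB-local": GPriorSpec("eb_local"),
    "JZS": GPriorSpec("jzs"),
    "BIC": GPriorSpec("bic"),
    "AIC": GPriorSpec("aic"),
}

PENALIZED_METHODS: dict[str, str] = {
    "LASSO": "lasso",
    "LASSO-1se": "lasso_1se",
    "ElasticNet": "elastic_net",
}

INTERVAL_FREE = set(PENALIZED_METHODS)


@dataclass
class BenchmarkConfig:
    methods: list[str] = field(default_factory=lambda: ["JZS", "g-sqrt-n", "LASSO"])
    n_bootstrap: int = 100
    n_splits: int = 100
    train_fraction: float = 0.75
    alpha: float = 0.05
    mcmc_iterations: int = 10_000
    n_draws: int = 10_000
    enumeration_max_p: int = 12
    n_cv_folds: int = 5
    reference_method: str = "JZS"
    seed: int = 0

    def __post_init__(self):
        known = set(BAYES_METHODS) | set(PENALIZED_METHODS)
        unknown = [m for m in self.methods if m not in known]
        if unknown:
            raise ValueError(f"unregistered method label(s): {unknown}")
        if self.reference_method not in self.methods:
            raise ValueError("reference_method must be among methods")
        if min(self.n_bootstrap, self.n_splits) < 1:
            raise ValueError("counts must be >= 1")


def _derive_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2 ** 31))


def _stable_hash(name: str) -> int:
    # str.hash is salted per process; use CRC32 so seeds reproduce across runs
    return zlib.crc32(name.encode()) % 997


def _model_prior_for(data: RegressionData) -> ModelPriorSpec:
    kind = "truncated_beta_binomial_11" if data.p > data.n else "beta_binomial_11"
    return ModelPriorSpec(kind=kind)


def _posterior(data: RegressionData, gspec: GPriorSpec, config: BenchmarkConfig,
               seed: int):
    mprior = _model_prior_for(data)
    if data.p <= config.enumeration_max_p:
        return enumerate_posterior(data, gspec, mprior)
    return mc3_sample(data, gspec, mprior, n_iter=config.mcmc_iterations, seed=seed)


def _split_data(ds: SyntheticDataset, y: np.ndarray, train_idx, test_idx):
    """Re-standardize the training block and map the test block onto it."""
    train = standardize(ds.design.X[train_idx], y[train_idx])
    X_test = train.standardizer.transform_X(ds.design.X[test_idx])
    y_test_c = y[test_idx] - train.standardizer.y_mean
    return train, X_test, y_test_c


def _eval_bayes(ds: SyntheticDataset, rep: int, label: str, gspec: GPriorSpec,
                config: BenchmarkConfig, with_bms: bool = False):
    """Metric records for one Bayesian method on one replicate.

    Returns (bma_record, bms_record or None); BMS shares the BMA posterior
    and conditions on the MAP model.
    """
    mi = sorted(BAYES_METHODS).index(label)
    data = ds.replicate_data(rep)
    truth = ds.truth
    seed0 = _derive_seed(config.seed, _stable_hash(ds.name), rep, mi)
    post = _posterior(data, gspec, config, seed0)

    rec = MetricRecord(dataset=ds.name, method=label, replicate=rep)
    coefs = bma_coefficients(data, post, gspec, config.alpha,
                             n_draws=config.n_draws, seed=seed0 + 1)
    rec.point_est_rmse = rmse_coefficients(truth.beta_DG, coefs.posterior_mean)
    rec.int_est_mis = mean_interval_score(coefs.interval_lower, coefs.interval_upper,
                                          truth.beta_DG, config.alpha)
    rec.inference_one_minus_auprc = 1.0 - auprc(truth.support, coefs.inclusion_prob)
    rec.n_vars = post.expected_model_size()

    brec = None
    if with_bms:
        brec = MetricRecord(dataset=ds.name, method=label + " (BMS)", replicate=rep)
        bcoefs, _ = bms_infer(data, post, gspec, None, config.alpha,
                              n_draws=config.n_draws, seed=seed0 + 2)
        brec.point_est_rmse = rmse_coefficients(truth.beta_DG, bcoefs.posterior_mean)
        brec.int_est_mis = mean_interval_score(bcoefs.interval_lower,
                                               bcoefs.interval_upper,
                                               truth.beta_DG, config.alpha)
        brec.inference_one_minus_auprc = 1.0 - auprc(truth.support,
                                                     bcoefs.inclusion_prob)
        brec.n_vars = float(map_model(post).sum())

    y = ds.replicates[rep]
    splits = train_test_split(ds.design.n, config.train_fraction,
                              config.n_splits, seed=seed0 + 3)
    r2s, mips, br2s, bmips = [], [], [], []
    for si, (tr, te) in enumerate(splits):
        train, X_test, y_test_c = _split_data(ds, y, tr, te)
        post_tr = _posterior(train, gspec, config, seed0 + 10 + si)
        pred = bma_predict(train, post_tr, gspec, X_test, config.alpha,
                           n_draws=config.n_draws, seed=seed0 + 100 + si)
        r2s.append(r2_test(y_test_c, pred.point, 0.0))
        mips.append(mean_interval_score(pred.pred_lower, pred.pred_upper,
                                        y_test_c, config.alpha))
        if with_bms:
            _, bpred = bms_infer(train, post_tr, gspec, X_test, config.alpha,
                                 n_draws=config.n_draws, seed=seed0 + 200 + si)
            br2s.append(r2_test(y_test_c, bpred.point, 0.0))
            bmips.append(mean_interval_score(bpred.pred_lower, bpred.pred_upper,
                                             y_test_c, config.alpha))
    rec.prediction_r2test = float(np.mean(r2s))
    rec.int_pred_mis = float(np.mean(mips))
    if with_bms:
        brec.prediction_r2test = float(np.mean(br2s))
        brec.int_pred_mis = float(np.mean(bmips))
    return rec, brec


def _eval_penalized(ds: SyntheticDataset, rep: int, label: str,
                    config: BenchmarkConfig) -> MetricRecord:
    method = PENALIZED_METHODS[label]
    data = ds.replicate_data(rep)
    truth = ds.truth
    mi = sorted(PENALIZED_METHODS).index(label)
    seed0 = _derive_seed(config.seed, _stable_hash(ds.name), rep, 100 + mi)

    rec = MetricRecord(dataset=ds.name, method=label, replicate=rep)
    fit = fit_penalized(data, method, n_folds=config.n_cv_folds, seed=seed0)
    rec.point_est_rmse = rmse_coefficients(truth.beta_DG, fit.coefficients)
    rec.inference_one_minus_auprc = 1.0 - auprc(
        truth.support, path_entry_scores(fit.path, data.p))
    rec.n_vars = float(fit.support_size)

    y = ds.replicates[rep]
    splits = train_test_split(ds.design.n, config.train_fraction,
                              config.n_splits, seed=seed0 + 3)
    r2s = []
    for tr, te in splits:
        train, X_test, y_test_c = _split_data(ds, y, tr, te)
        f = fit_penalized(train, method, n_folds=config.n_cv_folds, seed=seed0 + 7)
        r2s.append(r2_test(y_test_c, f.predict(X_test), 0.0))
    rec.prediction_r2test = float(np.mean(r2s))
    return rec


def run_benchmark(config: BenchmarkConfig,
                  suites: list[SyntheticDataset]) -> pd.DataFrame:
    """All methods on all suite replicates; one row per (dataset, method,
    replicate). A failure of one method on one replicate is recorded as
    NaN metrics, not fatal."""
    records = []
    for ds in suites:
        n_reps = min(config.n_bootstrap, ds.replicates.shape[0])
        for rep in range(n_reps):
            for label in config.methods:
                try:
                    if label in BAYES_METHODS:
                        rec, _ = _eval_bayes(ds, rep, label, BAYES_METHODS[label],
                                             config)
                    else:
                        rec = _eval_penalized(ds, rep, label, config)
                except Exception:
                    logger.exception("method %s failed on %s replicate %d",
                                     label, ds.name, rep)
                    rec = MetricRecord(dataset=ds.name, method=label, replicate=rep)
                records.append(rec.as_dict())
    return pd.DataFrame.from_records(records)


_REL_COLS = ["point_est_rmse", "int_est_mis", "inference_one_minus_auprc",
             "prediction_rmse", "int_pred_mis"]
_PART_COLS = ["point_est_rmse", "inference_one_minus_auprc", "prediction_rmse"]


def relative_score_table(records: pd.DataFrame,
                         reference: str = "JZS") -> pd.DataFrame:
    """Per-method metrics relative to the reference, with Score / PartScore.

    Metrics are averaged over replicates within each dataset, divided by
    the reference's dataset-matched value, and averaged across datasets.
    Prediction R^2_test is converted to the relative prediction RMSE
    sqrt((1 - R^2) / (1 - R^2_ref)) so lower is better everywhere. Methods
    are ranked by Score; interval-free methods are interleaved by
    PartScore as highly as possible without changing the Score order.
    """
    if reference not in set(records["method"]):
        raise ValueError(f"reference {reference!r} not among the records")
    per_ds = (records
              .groupby(["dataset", "method"], sort=False)
              .mean(numeric_only=True)
              .reset_index())
    per_ds["prediction_rmse"] = np.sqrt(np.clip(1.0 - per_ds["prediction_r2test"],
                                                0.0, None))
    rel_rows = []
    for ds, grp in per_ds.groupby("dataset", sort=False):
        ref = grp[grp["method"] == reference]
        if len(ref) != 1:
            raise ValueError(f"reference missing for dataset {ds!r}")
        ref = ref.iloc[0]
        for _, row in grp.iterrows():
            out = {"dataset": ds, "method": row["method"]}
            for c in _REL_COLS:
                denom = ref[c]
                if pd.isna(denom) or denom == 0:
                    raise ValueError(f"reference metric {c} unusable on {ds!r}")
                out[c] = row[c] / denom
            rel_rows.append(out)
    rel = (pd.DataFrame(rel_rows)
           .groupby("method", sort=False)
           .mean(numeric_only=True))
    rel["Score"] = rel[_REL_COLS].mean(axis=1, skipna=False)
    rel["PartScore"] = rel[_PART_COLS].mean(axis=1, skipna=False)

    scored = rel[rel["Score"].notna()].sort_values("Score")
    unscored = rel[rel["Score"].isna()].sort_values("PartScore")
    order = list(scored.index)
    for m in unscored.index:
        ps = rel.loc[m, "PartScore"]
        pos = len(order)
        for i, s in enumerate(order):
            sps = rel.loc[s, "PartScore"]
            if pd.notna(sps) and pd.notna(ps) and ps < sps:
                pos = i
                break
        order.insert(pos, m)
    rel = rel.loc[order]
    rel["rank"] = np.arange(1, len(rel) + 1)
    return rel


def compare_bma_bms(config: BenchmarkConfig, suites: list[SyntheticDataset],
                    methods: tuple[str, ...] = ("g-sqrt-n", "hyper-g", "EB-local")
                    ) -> pd.DataFrame:
    """Paired BMA / BMS relative metrics for the top adaptive methods.

    Each method's posterior is computed once per replicate; the BMS row
    conditions the same posterior on its MAP model. Metrics are relative
    to BMA under the reference prior. The ``bma_minus_bms`` sign summary
    is negative wherever model averaging beats selection (lower is
    better on every metric).
    """
    for m in methods:
        if m not in BAYES_METHODS:
            raise ValueError(f"unknown Bayesian method {m!r}")
    records = []
    for ds in suites:
        n_reps = min(config.n_bootstrap, ds.replicates.shape[0])
        for rep in range(n_reps):
            ref_rec, _ = _eval_bayes(ds, rep, config.reference_method,
                                     BAYES_METHODS[config.reference_method], config)
            records.append(ref_rec.as_dict())
            for label in sorted(methods):
                rec, brec = _eval_bayes(ds, rep, label, BAYES_METHODS[label],
                                        config, with_bms=True)
                records.append(rec.as_dict())
                records.append(brec.as_dict())
    df = pd.DataFrame.from_records(records)
    rel = relative_score_table(df, reference=config.reference_method)
    pairs = []
    for label in sorted(methods):
        a = rel.loc[label, _REL_COLS]
        b = rel.loc[label + " (BMS)", _REL_COLS]
        row = {"method": label}
        for c in _REL_COLS:
            row[f"bma_{c}"] = a[c]
            row[f"bms_{c}"] = b[c]
            row[f"bma_minus_bms_{c}"] = a[c] - b[c]
        pairs.append(row)
    return pd.DataFrame(pairs).set_index("method")
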