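"""The five evaluation metrics plus model-size accounting.

PointEst — root mean squared error of coefficient estimates against the
generating coefficients, RMSE = sqrt((1/p) sum_i (beta_i,DG - beta_hat_i)^2).

IntEst / IntPred — mean interval score at level 1 - alpha,
IS(l, u, z) = (u - l) + (2/alpha)(l - z) 1{z < l} + (2/alpha)(z - u) 1{u < z},
a proper score balancing narrowness against coverage; lower is better.

Inference — 1 minus the area under the precision-recall curve for
recovering the true support, from inclusion-probability rankings (Bayesian
methods) or the regularization-path support sweep (penalized methods).

Prediction — out-of-sample R^2_test = 1 - SS_res / SS_base with the
training mean as baseline; can go negative.

N vars — expected model size (sum of inclusion probabilities) for BMA,
nonzero-coefficient count for penalized fits.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .penalized import PenalizedFit
from .search import PosteriorOverModels

__all__ = [
    "MetricRecord",
    "rmse_coefficients",
    "interval_score",
    "mean_interval_score",
    "auprc",
    "path_entry_scores",
    "r2_test",
    "average_model_size",
]


@dataclass
class MetricRecord:
    """Per-(dataset, method, replicate) metric values; NaN where undefined."""

    dataset: str
    method: str
    replicate: int
    point_est_rmse: float = np.nan
    int_est_mis: float = np.nan
    inference_one_minus_auprc: float = np.nan
    prediction_r2test: float = np.nan
    int_pred_mis: float = np.nan
    n_vars: float = np.nan

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def rmse_coefficients(beta_DG: np.ndarray, beta_hat: np.ndarray) -> float:
    beta_DG = np.asarray(beta_DG, dtype=float)
    beta_hat = np.asarray(beta_hat, dtype=float)
    if beta_DG.shape != beta_hat.shape:
        raise ValueError("coefficient vectors must have equal length")
    return float(np.sqrt(np.mean((beta_DG - beta_hat) ** 2)))


def interval_score(l: float, u: float, z: float, alpha: float = 0.05) -> float:
    if l > u:
        raise ValueError("need l <= u")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    score = u - l
    if z < l:
        score += (2.0 / alpha) * (l - z)
    elif z > u:
        score += (2.0 / alpha) * (z - u)
    return float(score)


def mean_interval_score(lower, upper, targets, alpha: float = 0.05) -> float:
    """Arithmetic mean of the interval score across (l, u, z) triples."""
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if not (len(lower) == len(upper) == len(targets)):
        raise ValueError("lower, upper, targets must have equal length")
    if len(lower) == 0:
        raise ValueError("empty input")
    if np.any(lower > upper):
        raise ValueError("need l <= u elementwise")
    w = upper - lower
    w = w + (2.0 / alpha) * np.where(targets < lower, lower - targets, 0.0)
    w = w + (2.0 / alpha) * np.where(targets > upper, targets - upper, 0.0)
    return float(np.mean(w))


def auprc(true_support, scores) -> float:
    """Area under the precision-recall curve by step (average-precision)
    integration, with tie groups processed as single thresholds.

    ``scores`` rank the variables (higher = more likely included); they are
    typically posterior inclusion probabilities or path entry penalties.
    Invariant to strictly monotone transforms of the scores. With constant
    scores the curve has the single point (recall 1, precision prevalence),
    so the area equals the prevalence.
    """
    t = np.asarray(true_support, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if t.shape != s.shape:
        raise ValueError("support and scores must have equal length")
    n_pos = int(t.sum())
    if n_pos == 0:
        raise ValueError("true support has no positives; recall undefined")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    t_sorted = t[order]
    area = 0.0
    tp = 0
    seen = 0
    prev_recall = 0.0
    i = 0
    p = len(s)
    while i < p:
        j = i
        while j < p and s_sorted[j] == s_sorted[i]:
            j += 1
        tp += int(t_sorted[i:j].sum())
        seen += j - i
        recall = tp / n_pos
        precision = tp / seen
        area += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return float(area)


def path_entry_scores(path: list[tuple[float, np.ndarray]], p: int) -> np.ndarray:
    """Convert a regularization path to per-variable entry scores.

    Each variable is scored by the largest penalty at which it is active
    (0 if it never enters), so sweeping a threshold over the scores
    reproduces the sequence of selected supports along the path from
    lambda_max down.
    """
    scores = np.zeros(p)
    for lam, coef in path:
        active = np.asarray(coef) != 0
        scores[active] = np.maximum(scores[active], lam)
    return scores


def r2_test(y_test, y_pred, train_mean: float) -> float:
    y_test = np.asarray(y_test, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_test.shape != y_pred.shape:
        raise ValueError("y_test and y_pred must have equal length")
    denom = float(np.sum((y_test - train_mean) ** 2))
    if denom == 0:
        raise ValueError("test responses constant at the training mean")
    return 1.0 - float(np.sum((y_test - y_pred) ** 2)) / denom


def average_model_size(fits_or_posteriors) -> float:
    """Average model size across replicates.

    A posterior contributes its expected size (sum of inclusion
    probabilities); a penalized fit contributes its nonzero-coefficient
    count.
    """
    items = list(fits_or_posteriors)
    if not items:
        raise ValueError("empty input")
    sizes = []
    for it in items:
        if isinstance(it, PosteriorOverModels):
            sizes.append(it.expected_model_size())
        elif isinstance(it, PenalizedFit):
            sizes.append(float(it.support_size))
        else:
            raise TypeError(f"unsupported item {type(it)!r}")
    return float(np.mean(sizes))
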