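"""Threshold classification metrics and DeLong's AUC confidence interval.

The ROC AUC of a score vector equals the normalised Mann–Whitney statistic
of the scores (ties count 1/2), so AUC here is computed from mid-ranks and
coincides exactly with U / (n_pos * n_neg) from :mod:`ctratio.exact_stats`.
Its sampling variance uses DeLong's structural components: per-observation
placement values V10 (each case's fraction of controls it beats) and V01,
with Var(AUC) = S10/n_pos + S01/n_neg and a Wald interval clipped to
[0, 1].  AUC is deliberately not floored at 1/2: below-chance score vectors
report below-chance AUC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

from .errors import ValidationError


@dataclass(frozen=True)
class PerformanceReport:
    """LOOCV prediction quality for one comparison / model."""

    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    auc_variance: float
    n_pos: int
    n_neg: int
    ci_clipped: bool = False


def _split(scores, y):
    scores = np.asarray(scores, float).ravel()
    y = np.asarray(y).ravel()
    pos = scores[y == 1]
    neg = scores[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError("both classes must be present")
    return scores, y, pos, neg


def threshold_metrics(scores, y, threshold: float = 0.5) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) at a probability threshold.

    A sample is called positive iff its score is >= threshold (ties resolve
    toward the positive call).  Sensitivity is the fraction of true
    positives called positive; specificity the fraction of true negatives
    called negative.
    """
    _, y, pos, neg = _split(scores, y)
    tp = int((pos >= threshold).sum())
    tn = int((neg < threshold).sum())
    sens = tp / len(pos)
    spec = tn / len(neg)
    acc = (tp + tn) / (len(pos) + len(neg))
    return acc, sens, spec


def delong_auc_ci(scores, y, level: float = 0.95
                  ) -> tuple[float, float, float, float]:
    """(auc, ci_low, ci_high, variance) by DeLong's method.

    Placement values are computed with the mid-rank identity: for case i,
    V10_i = (pooled_rank_i - within_case_rank_i) / n_neg.  Degenerate
    variance (perfect or constant scores) yields a zero-width interval at
    the point estimate.
    """
    scores, y, pos, neg = _split(scores, y)
    m, n = len(pos), len(neg)
    r_all = rankdata(scores)
    r_pos = rankdata(pos)
    r_neg = rankdata(neg)
    v10 = (r_all[y == 1] - r_pos) / n
    v01 = 1.0 - (r_all[y == 0] - r_neg) / m
    auc = float(v10.mean())
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    variance = s10 / m + s01 / n
    if variance <= 0.0:
        return auc, auc, auc, 0.0
    z = norm.ppf(0.5 * (1.0 + level))
    half = z * np.sqrt(variance)
    lo = max(0.0, auc - half)
    hi = min(1.0, auc + half)
    return auc, float(lo), float(hi), float(variance)


def evaluate_predictions(scores, y, threshold: float = 0.5,
                         level: float = 0.95) -> PerformanceReport:
    """Bundle threshold metrics and the DeLong interval into one report."""
    scores = np.asarray(scores, float).ravel()
    y = np.asarray(y).ravel()
    acc, sens, spec = threshold_metrics(scores, y, threshold)
    auc, lo, hi, var = delong_auc_ci(scores, y, level)
    z = norm.ppf(0.5 * (1.0 + level))
    half = z * np.sqrt(var)
    clipped = bool(var > 0 and (auc - half < 0.0 or auc + half > 1.0))
    return PerformanceReport(
        accuracy=acc, sensitivity=sens, specificity=spec,
        auc=auc, auc_ci_low=lo, auc_ci_high=hi, auc_variance=var,
        n_pos=int((y == 1).sum()), n_neg=int((y == 0).sum()),
        ci_clipped=clipped)
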