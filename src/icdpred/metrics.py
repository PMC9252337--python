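"""Evaluation metrics and the DeLong test for correlated ROC AUCs.

ROC AUC is computed with midranks (ties get half credit), which is exactly
P(score_pos > score_neg) + 0.5 P(tie) and is the same placement-value
machinery the DeLong covariance estimator is built on.  Average precision
and the 2x2-table metrics delegate to scikit-learn; classification uses the
strict ``score > threshold`` convention at the default threshold 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata
from sklearn.metrics import average_precision_score


class UndefinedMetricError(ValueError):
    """The metric is undefined for this label configuration."""


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty input")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    return labels.astype(int)


def roc_auc(labels, scores) -> float:
    """Midrank ROC AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("ROC AUC needs both classes present")
    ranks = rankdata(scores)  # midranks
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def average_precision(labels, scores) -> float:
    """Recall-increment-weighted mean of precisions (no interpolation)."""
    labels = _check_binary(labels)
    if labels.sum() == 0:
        raise UndefinedMetricError("average precision needs at least one positive")
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def confusion_metrics(labels, scores, threshold: float = 0.5):
    """(accuracy, balanced_accuracy, sensitivity, specificity) at a threshold.

    Predicted class is 1 iff score is strictly greater than the threshold.
    """
    labels = _check_binary(labels)
    pred = (np.asarray(scores, dtype=float) > threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    n_pos, n_neg = tp + fn, tn + fp
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("balanced metrics need both classes present")
    sens = tp / n_pos
    spec = tn / n_neg
    acc = (tp + tn) / len(labels)
    return acc, (sens + spec) / 2, sens, spec


@dataclass(frozen=True)
class MetricReport:
    """All reported metrics for one model on one evaluation set."""

    roc_auc: float
    average_precision: float
    accuracy: float
    balanced_accuracy: float
    sensitivity: float
    specificity: float
    threshold: float
    n_obs: int
    prevalence: float

    def as_dict(self) -> dict:
        return {
            "roc_auc": self.roc_auc,
            "average_precision": self.average_precision,
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "threshold": self.threshold,
            "n_obs": self.n_obs,
            "prevalence": self.prevalence,
        }


def metric_report(labels, scores, threshold: float = 0.5) -> MetricReport:
    labels = _check_binary(labels)
    acc, ba, sens, spec = confusion_metrics(labels, scores, threshold)
    return MetricReport(
        roc_auc=roc_auc(labels, scores),
        average_precision=average_precision(labels, scores),
        accuracy=acc,
        balanced_accuracy=ba,
        sensitivity=sens,
        specificity=spec,
        threshold=threshold,
        n_obs=len(labels),
        prevalence=float(np.mean(labels)),
    )


# -------------------------------------------------------------- DeLong test


def _placements(labels: np.ndarray, scores: np.ndarray):
    """Structural components (placement values) of the AUC.

    V10[i] for positive i is the fraction of negatives it outranks (ties
    half); V01[j] the symmetric quantity for negatives.  Computed with
    midranks in O(n log n).
    """
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    all_scores = np.concatenate([pos, neg])
    ranks_all = rankdata(all_scores)
    ranks_pos = rankdata(pos)
    ranks_neg = rankdata(neg)
    v10 = (ranks_all[:m] - ranks_pos) / n
    v01 = 1.0 - (ranks_all[m:] - ranks_neg) / m
    return v10, v01


@dataclass(frozen=True)
class DeLongResult:
    """Paired comparison of two correlated ROC AUCs on the same labels."""

    auc_a: float
    auc_b: float
    diff: float
    var_diff: float
    z: float
    p_value: float
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    degenerate: bool = False


def delong_variance(labels, scores) -> float:
    """DeLong variance of a single AUC estimate."""
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=float)
    v10, v01 = _placements(labels, scores)
    m, n = len(v10), len(v01)
    return float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n)


def delong_test(labels, scores_a, scores_b, alpha: float = 0.05) -> DeLongResult:
    """DeLong test for the difference of two correlated ROC AUCs.

    Uses the structural-component estimator of the 2x2 covariance matrix of
    (AUC_A, AUC_B); the statistic z = (AUC_A - AUC_B)/sqrt(var(diff)) is
    compared to a standard normal (two-sided).  Per-model confidence
    intervals come from each AUC's own asymptotic normal distribution.

    If the two score vectors induce an exactly zero-variance difference
    (e.g. identical scores), a degenerate result with diff 0 and p = 1 is
    returned and flagged.
    """
    labels = _check_binary(labels)
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if not (len(labels) == len(scores_a) == len(scores_b)):
        raise ValueError("paired design requires equal-length inputs")

    v10a, v01a = _placements(labels, scores_a)
    v10b, v01b = _placements(labels, scores_b)
    m, n = len(v10a), len(v01a)
    auc_a = float(np.mean(v10a))
    auc_b = float(np.mean(v10b))

    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    cov = s10 / m + s01 / n
    var_a, var_b = cov[0, 0], cov[1, 1]
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]

    zq = norm.ppf(1 - alpha / 2)
    ci_a = (auc_a - zq * np.sqrt(max(var_a, 0)), auc_a + zq * np.sqrt(max(var_a, 0)))
    ci_b = (auc_b - zq * np.sqrt(max(var_b, 0)), auc_b + zq * np.sqrt(max(var_b, 0)))

    if var_diff <= 0:
        return DeLongResult(
            auc_a, auc_b, 0.0, 0.0, 0.0, 1.0, ci_a, ci_b, degenerate=True
        )
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = float(2 * norm.sf(abs(z)))
    return DeLongResult(auc_a, auc_b, auc_a - auc_b, float(var_diff), float(z), p,
                        ci_a, ci_b)


def bonferroni(pvals, m: int) -> np.ndarray:
    """Bonferroni adjustment: p -> min(1, m * p); ordering preserved."""
    pvals = np.asarray(pvals, dtype=float)
    if ((pvals < 0) | (pvals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if m < len(pvals):
        raise ValueError("m must be at least the number of p-values")
    return np.minimum(1.0, m * pvals)


def significance_stars(p: float) -> str:
    """Star convention: p <= 0.05 (*), <= 0.01 (**), <= 0.001 (***)."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""
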