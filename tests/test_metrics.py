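"""Metric implementations against independent oracles: brute-force pair
counting for ROC AUC, hand enumeration for average precision, an external
reference implementation and a bootstrap for the DeLong test."""

import shutil
import subprocess

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from icdpred import (
    average_precision,
    bonferroni,
    confusion_metrics,
    delong_test,
    metric_report,
    roc_auc,
)
from icdpred.metrics import UndefinedMetricError, significance_stars


def brute_force_auc(labels, scores):
    """Exhaustive pair counting: concordant + half credit for ties."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def step_average_precision(labels, scores):
    """AP by direct enumeration down the ranked score list."""
    order = np.argsort(-scores, kind="stable")
    labels = labels[order]
    scores = scores[order]
    ap = 0.0
    prev_recall = 0.0
    n_pos = labels.sum()
    # thresholds at distinct score values
    i = 0
    tp = fp = 0
    while i < len(labels):
        j = i
        while j < len(labels) and scores[j] == scores[i]:
            tp += labels[j]
            fp += 1 - labels[j]
            j += 1
        recall = tp / n_pos
        precision = tp / (tp + fp)
        ap += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return ap


class TestRocAuc:
    def test_worked_example(self):
        assert roc_auc([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1]) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_all_ties(self):
        assert roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            roc_auc([1, 1, 1], [0.1, 0.2, 0.3])

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(5, 120)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            scores = rng.choice(np.round(rng.normal(size=6), 2), size=n)
            assert roc_auc(labels, scores) == pytest.approx(
                brute_force_auc(labels, scores), abs=1e-12
            )

    def test_matches_sklearn(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, 300)
        scores = rng.normal(size=300)
        assert roc_auc(labels, scores) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )


class TestAveragePrecision:
    def test_worked_example(self):
        assert average_precision([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1]) == \
            pytest.approx(5 / 6)

    def test_perfect_ranking(self):
        assert average_precision([0, 1, 1], [0.1, 0.8, 0.9]) == 1.0

    def test_constant_scores_equal_prevalence(self):
        labels = np.array([1, 0, 0, 0, 1])
        assert average_precision(labels, np.full(5, 0.3)) == pytest.approx(0.4)

    def test_no_positives_rejected(self):
        with pytest.raises(UndefinedMetricError):
            average_precision([0, 0], [0.1, 0.2])

    def test_matches_hand_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = rng.integers(4, 100)
            labels = rng.integers(0, 2, n)
            if labels.sum() == 0:
                continue
            scores = rng.normal(size=n).round(1)
            assert average_precision(labels, scores) == pytest.approx(
                step_average_precision(labels, scores), abs=1e-12
            )


class TestConfusionMetrics:
    def test_worked_table(self):
        acc, ba, sens, spec = confusion_metrics(
            [1, 1, 0, 0], [0.9, 0.4, 0.6, 0.2]
        )
        assert (acc, ba, sens, spec) == (0.5, 0.5, 0.5, 0.5)

    def test_strict_threshold_convention(self):
        acc, ba, sens, spec = confusion_metrics([1, 0], [0.5, 0.5])
        assert sens == 0.0 and spec == 1.0

    def test_balanced_accuracy_identity(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 2, 200)
        scores = rng.random(200)
        _, ba, sens, spec = confusion_metrics(labels, scores)
        assert ba == pytest.approx((sens + spec) / 2)

    def test_report_consistency(self):
        rng = np.random.default_rng(4)
        labels = rng.integers(0, 2, 150)
        scores = rng.random(150)
        rep = metric_report(labels, scores)
        assert rep.n_obs == 150
        assert rep.prevalence == pytest.approx(labels.mean())
        assert rep.balanced_accuracy == pytest.approx(
            (rep.sensitivity + rep.specificity) / 2
        )


class TestDeLong:
    def test_identical_scores_degenerate(self):
        labels = np.array([1, 0, 1, 0, 1])
        s = np.array([0.9, 0.2, 0.8, 0.3, 0.7])
        res = delong_test(labels, s, s)
        assert res.degenerate
        assert res.diff == 0.0 and res.p_value == 1.0

    def test_ci_contains_point_estimate(self):
        rng = np.random.default_rng(5)
        labels = rng.integers(0, 2, 100)
        a, b = rng.normal(size=100), rng.normal(size=100)
        res = delong_test(labels, a, b)
        assert res.ci_a[0] <= res.auc_a <= res.ci_a[1]
        assert res.ci_b[0] <= res.auc_b <= res.ci_b[1]
        assert 0 <= res.p_value <= 1

    def test_variance_close_to_stratified_bootstrap(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=30)
        y = np.array([1] * 12 + [0] * 18)
        a = x + y * 0.8 + rng.normal(size=30) * 0.5
        b = x + y * 0.8 + rng.normal(size=30) * 0.5
        res = delong_test(y, a, b)
        pos, neg = np.where(y == 1)[0], np.where(y == 0)[0]
        diffs = np.empty(4000)
        for k in range(len(diffs)):
            idx = np.concatenate(
                [rng.choice(pos, len(pos)), rng.choice(neg, len(neg))]
            )
            diffs[k] = roc_auc(y[idx], a[idx]) - roc_auc(y[idx], b[idx])
        boot_var = diffs.var(ddof=1)
        assert res.var_diff == pytest.approx(boot_var, rel=0.15)

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript not on PATH")
    def test_matches_reference_implementation(self, tmp_path):
        """z and p agree with pROC's DeLong test on the same data."""
        rng = np.random.default_rng(42)
        n = 80
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-x))).astype(int)
        a = x + rng.normal(size=n)
        b = 0.5 * x + rng.normal(size=n)
        res = delong_test(y, a, b)
        csv = tmp_path / "scores.csv"
        np.savetxt(csv, np.column_stack([y, a, b]), delimiter=",",
                   header="y,a,b", comments="")
        script = (
            "suppressMessages(library(pROC));"
            f"d <- read.csv('{csv}');"
            "ra <- roc(d$y, d$a, quiet=TRUE); rb <- roc(d$y, d$b, quiet=TRUE);"
            "t <- roc.test(ra, rb, method='delong');"
            "cat(t$statistic, t$p.value)"
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        z_ref, p_ref = map(float, out.stdout.split())
        assert res.z == pytest.approx(z_ref, abs=1e-6)
        assert res.p_value == pytest.approx(p_ref, abs=1e-6)


class TestBonferroni:
    def test_scaling_and_cap(self):
        assert bonferroni([0.01], 4).tolist() == [0.04]
        assert bonferroni([0.5], 4).tolist() == [1.0]

    def test_order_preserved(self):
        p = np.array([0.001, 0.01, 0.02, 0.2])
        adj = bonferroni(p, 4)
        assert (np.diff(adj) >= 0).all()

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni([1.2], 2)
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2], 1)

    def test_star_convention(self):
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.009) == "**"
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.2) == ""
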