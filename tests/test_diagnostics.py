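"""ROC/Youden, confusion metrics, kappa and regression comparison."""

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score, roc_auc_score

from acidmap.diagnostics import (
    ConfusionMatrix,
    confusion,
    mann_whitney_auc,
    metric_report,
    reconstruct_confusion,
    regression_compare,
    roc_curve,
    youden_threshold,
)


def random_dataset(rng, n_max=40, decimals=None):
    n = int(rng.integers(6, n_max))
    labels = rng.integers(0, 2, n)
    while labels.sum() in (0, n):
        labels = rng.integers(0, 2, n)
    scores = rng.normal(6.5, 0.8, n)
    if decimals is not None:
        scores = np.round(scores, decimals)
    return labels, scores


class TestRocCurve:
    def test_perfect_separation_gives_auc_one(self):
        roc = roc_curve([0, 0, 1, 1], [5.0, 5.5, 7.0, 7.5])
        assert roc.auc == 1.0

    def test_mirrored_labels_give_half(self):
        # balanced toy set where score distributions are identical per class
        labels = [0, 1, 0, 1]
        scores = [5.0, 5.0, 7.0, 7.0]
        assert roc_curve(labels, scores).auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_curve([1, 1, 1], [1.0, 2.0, 3.0])

    def test_trapezoid_equals_mann_whitney_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            labels, scores = random_dataset(rng, decimals=int(rng.integers(0, 3)))
            roc = roc_curve(labels, scores)
            assert roc.auc == pytest.approx(
                mann_whitney_auc(labels, scores), abs=1e-10
            )
            assert roc.auc == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-10
            )

    def test_two_normal_simulation_matches_binormal_closed_form(self):
        """Tumor N(7.056, 0.4138) vs para N(6.046, 0.8352): the mean
        empirical AUC matches Phi(delta / sigma_pooled) ~ 0.861."""
        from scipy.stats import norm

        expected = norm.cdf(
            (7.056 - 6.046) / np.hypot(0.4138, 0.8352)
        )
        rng = np.random.default_rng(1)
        aucs = []
        for _ in range(60):
            tumor = rng.normal(7.056, 0.4138, 575)
            para = rng.normal(6.046, 0.8352, 941)
            labels = np.r_[np.ones(575, int), np.zeros(941, int)]
            aucs.append(roc_curve(labels, np.r_[tumor, para]).auc)
        se = np.std(aucs) / np.sqrt(len(aucs))
        assert np.mean(aucs) == pytest.approx(expected, abs=3 * se + 1e-4)


class TestYouden:
    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            labels, scores = random_dataset(rng, decimals=1)
            roc = roc_curve(labels, scores)
            thr, j = youden_threshold(roc)
            pos, neg = scores[labels == 1], scores[labels == 0]
            candidates = np.r_[scores, np.inf]
            best_j = max(
                np.mean(pos >= t) - np.mean(neg >= t) for t in candidates
            )
            assert j == pytest.approx(best_j, abs=1e-12)
            # the returned midpoint must achieve the same J
            j_at_thr = np.mean(pos >= thr) - np.mean(neg >= thr)
            assert j_at_thr == pytest.approx(best_j, abs=1e-12)

    def test_separated_classes_return_gap_midpoint(self):
        roc = roc_curve([0, 0, 1, 1], [5.0, 6.0, 7.0, 8.0])
        thr, j = youden_threshold(roc)
        assert thr == pytest.approx(6.5)
        assert j == 1.0


class TestConfusion:
    def test_all_correct(self):
        labels = [1] * 4 + [0] * 6
        cm = confusion(labels, labels)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (4, 6, 0, 0)

    def test_negated_predictions(self):
        labels = np.array([0, 1, 0, 1])
        cm = confusion(labels, 1 - labels)
        assert cm.tp == 0 and cm.tn == 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion([0, 1], [1])

    def test_reconstruction_from_printed_sensitivity_specificity(self):
        cm = reconstruct_confusion(127, 262, 0.8504, 0.8779)
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (108, 19, 230, 32)


class TestMetricReport:
    def test_printed_external_validation_metrics(self):
        """The reconstructed 389-point external validation matrix yields
        the printed accuracy, PPV, NPV and kappa."""
        cm = ConfusionMatrix(tp=108, fp=32, tn=230, fn=19)
        rep = metric_report(cm)
        assert rep.accuracy == pytest.approx(338 / 389)
        assert round(100 * rep.accuracy, 2) == 86.89
        assert round(100 * rep.ppv, 2) == 77.14
        assert round(100 * rep.npv, 2) == 92.37
        assert round(rep.kappa, 2) == 0.71

    def test_perfect_matrix_all_ones(self):
        rep = metric_report(ConfusionMatrix(tp=5, fp=0, tn=5, fn=0))
        assert rep.sensitivity == rep.specificity == rep.accuracy == 1.0
        assert rep.kappa == 1.0

    def test_kappa_matches_sklearn(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            labels = rng.integers(0, 2, 50)
            preds = rng.integers(0, 2, 50)
            cm = confusion(labels, preds)
            rep = metric_report(cm)
            expected = cohen_kappa_score(labels, preds)
            if rep.kappa is None:
                assert np.isnan(expected) or expected == 0.0
            else:
                assert rep.kappa == pytest.approx(expected, abs=1e-12)

    def test_zero_denominator_reported_absent(self):
        rep = metric_report(ConfusionMatrix(tp=0, fp=0, tn=5, fn=0))
        assert rep.sensitivity is None
        assert rep.ppv is None
        assert rep.accuracy == 1.0

    def test_clopper_pearson_interval_covers_estimate(self):
        rep = metric_report(ConfusionMatrix(tp=108, fp=32, tn=230, fn=19))
        lo, hi = rep.ci_95["sensitivity"]
        assert lo < rep.sensitivity < hi
        # cross-check the exact interval for 108/127 against statsmodels
        from statsmodels.stats.proportion import proportion_confint

        ref_lo, ref_hi = proportion_confint(108, 127, method="beta")
        assert lo == pytest.approx(ref_lo, abs=1e-10)
        assert hi == pytest.approx(ref_hi, abs=1e-10)


class TestRegressionCompare:
    def test_identity_prediction(self):
        ref = np.array([2.0, 5.0, 8.0])
        r2, sse = regression_compare(ref, ref)
        assert (r2, sse) == (1.0, 0.0)

    def test_constant_prediction_scores_zero(self):
        ref = np.array([2.0, 5.0, 8.0])
        r2, sse = regression_compare(np.full(3, ref.mean()), ref)
        assert r2 == pytest.approx(0.0)

    def test_constant_offset_sse_closed_form(self):
        """A 0.43 pH systematic offset over 389 points gives SSE ~ 71.9 —
        the scale of error corresponding to the published model-fit SSE."""
        rng = np.random.default_rng(4)
        ref = rng.uniform(5, 8, 389)
        r2, sse = regression_compare(ref + 0.43, ref)
        assert sse == pytest.approx(389 * 0.43**2, rel=1e-12)

    def test_zero_reference_variance_r2_absent(self):
        r2, sse = regression_compare(np.array([1.0, 2.0]), np.array([3.0, 3.0]))
        assert r2 is None
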