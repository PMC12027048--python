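"""Metric operations against independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from swecaf.metrics import (
    ConfusionMatrix,
    PredictionRecord,
    UndefinedMetricError,
    accuracy,
    auc,
    confusion_counts,
    metrics_report,
    sensitivity,
    specificity,
    vote_tumor,
)


def _recs(ys, ps, cutoff=0.5):
    return [
        PredictionRecord.from_probability(f"T{i}", 0, y, p, cutoff) for i, (y, p) in enumerate(zip(ys, ps))
    ]


def brute_force_auc(y, p):
    """Exhaustive positive-negative pair counting, ties worth one half."""
    wins = halves = 0
    pos = [pi for yi, pi in zip(y, p) if yi == 1]
    neg = [pi for yi, pi in zip(y, p) if yi == 0]
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1
            elif a == b:
                halves += 1
    return 100.0 * (wins + 0.5 * halves) / (len(pos) * len(neg))


def trapezoid_auc(y, p):
    """Trapezoidal ROC integration at every distinct score threshold."""
    y, p = np.asarray(y), np.asarray(p)
    thresholds = np.concatenate([[np.inf], np.sort(np.unique(p))[::-1]])
    tpr = [(p[y == 1] >= t).mean() for t in thresholds]
    fpr = [(p[y == 0] >= t).mean() for t in thresholds]
    return 100.0 * float(np.trapezoid(tpr, fpr))


class TestConfusionAndRates:
    def test_all_correct_has_no_errors(self):
        cm = confusion_counts(_recs([1, 0, 1], [0.9, 0.1, 0.8]))
        assert (cm.fp, cm.fn) == (0, 0)

    def test_one_of_each_cell(self):
        cm = confusion_counts(_recs([1, 1, 0, 0], [0.9, 0.1, 0.2, 0.8]))
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (1, 1, 1, 1)

    def test_counts_match_exhaustive_tally_on_random_sets(self, rng):
        for _ in range(200):
            n = rng.integers(4, 60)
            y = rng.integers(0, 2, n)
            p = rng.random(n)
            cm = confusion_counts(_recs(y, p))
            yh = (p > 0.5).astype(int)
            assert cm.tp == int(((y == 1) & (yh == 1)).sum())
            assert cm.tn == int(((y == 0) & (yh == 0)).sum())
            assert cm.fp == int(((y == 0) & (yh == 1)).sum())
            assert cm.fn == int(((y == 1) & (yh == 0)).sum())

    def test_tumor_level_worked_example(self):
        """A 21-unit test set with 9 TP / 1 FN / 8 TN / 3 FP reproduces the
        canonical 90.00% sensitivity, 72.73% specificity, 80.95% accuracy."""
        cm = ConfusionMatrix(tp=9, fn=1, tn=8, fp=3)
        assert round(sensitivity(cm), 2) == 90.00
        assert round(specificity(cm), 2) == 72.73
        assert round(accuracy(cm), 2) == 80.95

    def test_undefined_metrics_raise_not_zero(self):
        with pytest.raises(UndefinedMetricError):
            sensitivity(ConfusionMatrix(tn=5, fp=2))
        with pytest.raises(UndefinedMetricError):
            specificity(ConfusionMatrix(tp=5, fn=2))

    def test_accuracy_is_prevalence_weighted_average(self, rng):
        for _ in range(50):
            y = rng.integers(0, 2, 30)
            if len(np.unique(y)) < 2:
                continue
            p = rng.random(30)
            cm = confusion_counts(_recs(y, p))
            pos, neg = cm.tp + cm.fn, cm.tn + cm.fp
            blended = (sensitivity(cm) * pos + specificity(cm) * neg) / (pos + neg)
            assert accuracy(cm) == pytest.approx(blended)


class TestAUC:
    def test_perfect_separation_and_all_ties(self):
        assert auc(_recs([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1])) == 100.0
        assert auc(_recs([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5])) == 50.0

    def test_printed_pair_counting_example(self):
        assert auc(_recs([1, 0, 1, 0], [0.9, 0.8, 0.4, 0.2])) == pytest.approx(75.0)

    def test_matches_brute_force_and_trapezoid_on_random_sets(self, rng):
        for i in range(200):
            n = int(rng.integers(4, 50))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            # quantized scores force ties on some sets
            p = np.round(rng.random(n), 1 if i % 2 else 3)
            recs = _recs(y, p)
            expected = brute_force_auc(y, p)
            assert auc(recs) == pytest.approx(expected, abs=1e-9)
            assert auc(recs) == pytest.approx(trapezoid_auc(y, p), abs=1e-9)

    def test_matches_reference_implementation(self, rng):
        from sklearn.metrics import roc_auc_score

        y = rng.integers(0, 2, 100)
        p = rng.random(100)
        assert auc(_recs(y, p)) == pytest.approx(100.0 * roc_auc_score(y, p))

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            auc(_recs([1, 1], [0.5, 0.6]))


class TestVoting:
    @staticmethod
    def _tumor(tumor_id, y, probs, cutoff=0.5):
        return [
            PredictionRecord.from_probability(tumor_id, k, y, p, cutoff) for k, p in enumerate(probs)
        ]

    def test_strict_majority(self):
        out = vote_tumor(self._tumor("A", 1, [0.9, 0.8, 0.2]))
        assert out[0].y_hat == 1

    def test_even_vote_broken_by_mean_probability(self):
        out = vote_tumor(self._tumor("A", 1, [0.9, 0.2]))
        assert out[0].p == pytest.approx(0.55)
        assert out[0].y_hat == 1
        out = vote_tumor(self._tumor("B", 0, [0.6, 0.1]))
        assert out[0].y_hat == 0  # mean 0.35 <= cutoff

    def test_matches_independent_majority_tally(self, rng):
        records = []
        expected = {}
        for t in range(100):
            tid = f"T{t:03d}"
            y = int(rng.integers(0, 2))
            probs = rng.random(int(rng.integers(1, 8)))
            records.extend(self._tumor(tid, y, probs))
            votes = (probs > 0.5).astype(int)
            n_high, n_low = votes.sum(), len(votes) - votes.sum()
            if n_high != n_low:
                expected[tid] = int(n_high > n_low)
            else:
                expected[tid] = int(probs.mean() > 0.5)
        for rec in vote_tumor(records):
            assert rec.y_hat == expected[rec.tumor_id], rec.tumor_id

    def test_unanimous_votes_collapse_confusion_matrices(self, rng):
        """When every image of a tumor votes the same way, the tumor-level
        confusion matrix is the image-level one collapsed by tumor."""
        records = []
        for t in range(40):
            y = int(rng.integers(0, 2))
            vote = int(rng.integers(0, 2))
            p = 0.8 if vote else 0.2
            records.extend(self._tumor(f"T{t}", y, [p] * int(rng.integers(1, 5))))
        img_cm = confusion_counts(records)
        tum_cm = confusion_counts(vote_tumor(records))
        by_tumor = {}
        for r in records:
            by_tumor.setdefault(r.tumor_id, r)
        collapsed = confusion_counts(list(by_tumor.values()))
        assert (tum_cm.tp, tum_cm.tn, tum_cm.fp, tum_cm.fn) == (
            collapsed.tp,
            collapsed.tn,
            collapsed.fp,
            collapsed.fn,
        )
        assert img_cm.total >= tum_cm.total

    def test_inconsistent_truth_rejected(self):
        records = self._tumor("A", 1, [0.9]) + self._tumor("A", 0, [0.1])
        with pytest.raises(ValueError, match="inconsistent"):
            vote_tumor(records)

    def test_vote_fraction_scoring_option(self):
        out = vote_tumor(self._tumor("A", 1, [0.9, 0.9, 0.1]), score="vote_fraction")
        assert out[0].p == pytest.approx(2 / 3)


class TestThresholdMonotonicity:
    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_raising_cutoff_never_raises_sensitivity(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, 40)
        if len(np.unique(y)) < 2:
            return
        p = rng.random(40)
        prev_sens, prev_spec = 100.0, 0.0
        for cutoff in np.linspace(0.05, 0.95, 10):
            cm = confusion_counts(_recs(y, p, cutoff))
            s, sp = sensitivity(cm), specificity(cm)
            assert s <= prev_sens + 1e-9
            assert sp >= prev_spec - 1e-9
            prev_sens, prev_spec = s, sp


def test_report_flags_undefined_metrics():
    report = metrics_report(_recs([1, 1], [0.9, 0.2]), level="image")
    assert np.isnan(report.auc) and np.isnan(report.specificity)
    assert report.flags and report.n_units == 2
    assert report.accuracy == pytest.approx(50.0)
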