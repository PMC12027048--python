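"""Classification metrics at image and tumor level.

The image level scores every B-mode/elastography pair independently; the
tumor level aggregates a tumor's image-level predictions by majority vote
(hard label) and mean probability (ranking score for AUC), mirroring how a
per-tumor call would be made from repeated acquisitions.

All four headline metrics — AUC, accuracy, sensitivity, specificity — are
reported as percentages.  ``high`` is the positive class (label 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "PredictionRecord",
    "ConfusionMatrix",
    "MetricsReport",
    "UndefinedMetricError",
    "confusion_counts",
    "accuracy",
    "sensitivity",
    "specificity",
    "auc",
    "vote_tumor",
    "metrics_report",
]

DEFAULT_CUTOFF = 0.5


class UndefinedMetricError(ValueError):
    """A metric's denominator is zero (e.g. no positives for sensitivity)."""


@dataclass
class PredictionRecord:
    """One evaluated unit: an image pair, or a tumor after voting."""

    tumor_id: str
    pair_index: int  # -1 for tumor-level records
    y: int  # true label, 1 = high
    p: float  # predicted probability of high
    y_hat: int  # hard prediction at the decision cutoff

    @classmethod
    def from_probability(cls, tumor_id, pair_index, y, p, cutoff=DEFAULT_CUTOFF):
        return cls(tumor_id=tumor_id, pair_index=pair_index, y=int(y), p=float(p), y_hat=int(p > cutoff))


@dataclass
class ConfusionMatrix:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    """The four headline metrics (percent) at one evaluation level."""

    level: str  # {"image", "tumor"}
    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    confusion: ConfusionMatrix
    n_units: int
    flags: list[str] = field(default_factory=list)

    @property
    def selection_score(self) -> float:
        """Sum of the four metrics, the validation model-selection score."""
        return self.auc + self.accuracy + self.sensitivity + self.specificity

    def to_dict(self) -> dict:
        d = asdict(self)
        d["selection_score"] = self.selection_score
        return d


def confusion_counts(records: list[PredictionRecord]) -> ConfusionMatrix:
    """Cross-tabulate true labels against hard predictions."""
    if not records:
        raise ValueError("cannot tabulate an empty record list")
    cm = ConfusionMatrix()
    for r in records:
        if r.y == 1:
            if r.y_hat == 1:
                cm.tp += 1
            else:
                cm.fn += 1
        else:
            if r.y_hat == 1:
                cm.fp += 1
            else:
                cm.tn += 1
    return cm


def accuracy(cm: ConfusionMatrix) -> float:
    """(TP+TN)/(TP+TN+FP+FN), percent."""
    if cm.total == 0:
        raise UndefinedMetricError("accuracy undefined: no evaluated units")
    return 100.0 * (cm.tp + cm.tn) / cm.total


def sensitivity(cm: ConfusionMatrix) -> float:
    """TP/(TP+FN), percent — the true-positive rate."""
    if cm.tp + cm.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no actual positives")
    return 100.0 * cm.tp / (cm.tp + cm.fn)


def specificity(cm: ConfusionMatrix) -> float:
    """TN/(TN+FP), percent — the true-negative rate."""
    if cm.tn + cm.fp == 0:
        raise UndefinedMetricError("specificity undefined: no actual negatives")
    return 100.0 * cm.tn / (cm.tn + cm.fp)


def auc(records: list[PredictionRecord]) -> float:
    """Rank-based ROC AUC, percent.

    Equals the probability that a uniformly random positive receives a
    higher score than a uniformly random negative, with ties counted half —
    and therefore also equals the trapezoidal area under the ROC curve.
    """
    y = np.array([r.y for r in records])
    p = np.array([r.p for r in records])
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC undefined: both classes must be present")
    ranks = rankdata(p)  # average ranks handle ties as half-wins
    auc01 = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return 100.0 * float(auc01)


def vote_tumor(
    records: list[PredictionRecord],
    cutoff: float = DEFAULT_CUTOFF,
    score: str = "mean_probability",
) -> list[PredictionRecord]:
    """Aggregate image-level records into one record per tumor.

    The tumor's hard label is the majority of its image-level hard labels;
    an even vote is broken by comparing the tumor score to the cutoff.  The
    tumor score is the mean image probability by default (``score=
    "vote_fraction"`` uses the fraction of high votes instead).
    """
    if score not in ("mean_probability", "vote_fraction"):
        raise ValueError(f"unknown tumor score {score!r}")
    by_tumor: dict[str, list[PredictionRecord]] = {}
    for r in records:
        by_tumor.setdefault(r.tumor_id, []).append(r)
    out = []
    for tumor_id, recs in by_tumor.items():
        votes = [r.y_hat for r in recs]
        mean_p = float(np.mean([r.p for r in recs]))
        tumor_score = mean_p if score == "mean_probability" else float(np.mean(votes))
        n_high = sum(votes)
        n_low = len(votes) - n_high
        if n_high > n_low:
            y_hat = 1
        elif n_high < n_low:
            y_hat = 0
        else:
            y_hat = int(tumor_score > cutoff)
        ys = {r.y for r in recs}
        if len(ys) != 1:
            raise ValueError(f"tumor {tumor_id} has inconsistent true labels across images")
        out.append(
            PredictionRecord(tumor_id=tumor_id, pair_index=-1, y=ys.pop(), p=tumor_score, y_hat=y_hat)
        )
    return out


def metrics_report(records: list[PredictionRecord], level: str) -> MetricsReport:
    """Compute the four metrics, flagging (not zeroing) undefined ones."""
    cm = confusion_counts(records)
    values = {}
    flags = []
    for name, fn, arg in (
        ("auc", auc, records),
        ("accuracy", accuracy, cm),
        ("sensitivity", sensitivity, cm),
        ("specificity", specificity, cm),
    ):
        try:
            values[name] = fn(arg)
        except UndefinedMetricError as exc:
            values[name] = float("nan")
            flags.append(str(exc))
    return MetricsReport(
        level=level,
        auc=values["auc"],
        accuracy=values["accuracy"],
        sensitivity=values["sensitivity"],
        specificity=values["specificity"],
        confusion=cm,
        n_units=len(records),
        flags=flags,
    )
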