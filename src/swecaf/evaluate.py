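"""End-to-end evaluation: both-level reports, ablation, cross-validation.

``evaluate`` scores a trained model on one split at the image level and,
after majority voting, at the tumor level.  ``ablation`` trains the
bimodal model and both unimodal arms under one shared protocol and tables
the results.  ``cross_validate`` runs tumor-grouped k-fold CV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import PairDataset
from .metrics import DEFAULT_CUTOFF, MetricsReport, metrics_report, vote_tumor
from .model import BimodalNet, ModelSpec, build_model
from .train import TrainConfig, predict_records, train

__all__ = ["EvaluationResult", "evaluate", "ablation", "cross_validate", "grouped_stratified_folds"]

METRIC_NAMES = ("auc", "accuracy", "sensitivity", "specificity")


@dataclass
class EvaluationResult:
    image: MetricsReport
    tumor: MetricsReport
    image_records: list
    tumor_records: list

    def to_dict(self) -> dict:
        return {"image": self.image.to_dict(), "tumor": self.tumor.to_dict()}

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def evaluate(
    model: BimodalNet,
    dataset: PairDataset,
    cutoff: float = DEFAULT_CUTOFF,
    tumor_score: str = "mean_probability",
) -> EvaluationResult:
    """Image-level then voted tumor-level metrics for one split."""
    if len(dataset) == 0:
        raise ValueError("cannot evaluate an empty split")
    image_records = predict_records(model, dataset, cutoff=cutoff)
    tumor_records = vote_tumor(image_records, cutoff=cutoff, score=tumor_score)
    return EvaluationResult(
        image=metrics_report(image_records, level="image"),
        tumor=metrics_report(tumor_records, level="tumor"),
        image_records=image_records,
        tumor_records=tumor_records,
    )


def ablation(
    spec: ModelSpec,
    train_set: PairDataset,
    val_set: PairDataset | None,
    test_set: PairDataset,
    config: TrainConfig,
    modes: tuple[str, ...] = ("bimodal", "grayscale_only", "elastography_only"),
) -> pd.DataFrame:
    """Train and evaluate each arm on identical splits and seeds.

    Returns one row per (arm, level); a failed arm is recorded as a row
    with an ``error`` column while the other arms proceed.
    """
    rows = []
    for mode in modes:
        try:
            model = build_model(spec, mode=mode, seed=config.seed)
            train(model, train_set, val_set, config)
            result = evaluate(model, test_set)
            for level, report in (("image", result.image), ("tumor", result.tumor)):
                row = {"mode": mode, "level": level, "n_units": report.n_units}
                row.update({m: getattr(report, m) for m in METRIC_NAMES})
                rows.append(row)
        except Exception as exc:  # arm isolation: one failure must not sink the table
            rows.append({"mode": mode, "level": "error", "error": str(exc)})
    return pd.DataFrame(rows)


def grouped_stratified_folds(
    tumor_ids: list[str], labels: list[str], k: int, seed: int
) -> list[list[str]]:
    """Partition tumors into k folds, stratified by label.

    Tumors (the grouping unit — all of a tumor's images follow it) are
    shuffled within each class and dealt round-robin, so fold sizes and
    class balance differ by at most one tumor.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    folds: list[list[str]] = [[] for _ in range(k)]
    cursor = 0  # rolling across classes keeps fold sizes within one overall
    for cls in sorted(set(labels)):
        ids = [t for t, l in zip(tumor_ids, labels) if l == cls]
        ids = [ids[i] for i in rng.permutation(len(ids))]
        for tid in ids:
            folds[cursor % k].append(tid)
            cursor += 1
    return folds


@dataclass
class CrossValResult:
    fold_reports: list[dict]  # per fold: {"image": MetricsReport, "tumor": MetricsReport}
    summary: pd.DataFrame  # mean and sd per metric and level
    flagged_folds: list[int] = field(default_factory=list)


def cross_validate(
    spec: ModelSpec,
    dataset: PairDataset,
    tumor_labels: dict[str, str],
    config: TrainConfig,
    k: int = 5,
) -> CrossValResult:
    """Tumor-grouped stratified k-fold cross-validation.

    Each fold's model trains on the other k-1 folds for the configured
    number of epochs (final-epoch weights; no inner validation split, so
    the held-out fold never influences selection) and is evaluated on the
    held-out fold at both levels.  Folds missing a class are flagged.
    """
    tumor_ids = sorted(set(dataset.tumor_ids.tolist()))
    labels = [tumor_labels[t] for t in tumor_ids]
    folds = grouped_stratified_folds(tumor_ids, labels, k, config.seed)
    fold_reports = []
    flagged = []
    rows = []
    for f, held_out in enumerate(folds):
        held = set(held_out)
        test_idx = np.array([t in held for t in dataset.tumor_ids])
        train_ds = dataset.subset(~test_idx)
        test_ds = dataset.subset(test_idx)
        if len(np.unique(test_ds.y)) < 2:
            flagged.append(f)
        model = build_model(spec, mode="bimodal", seed=config.seed + f)
        train(model, train_ds, None, config)
        result = evaluate(model, test_ds)
        fold_reports.append({"image": result.image, "tumor": result.tumor})
        for level, report in (("image", result.image), ("tumor", result.tumor)):
            for m in METRIC_NAMES:
                rows.append({"fold": f, "level": level, "metric": m, "value": getattr(report, m)})
    df = pd.DataFrame(rows)
    summary = (
        df.groupby(["level", "metric"])["value"].agg(["mean", "std"]).reset_index()
    )
    return CrossValResult(fold_reports=fold_reports, summary=summary, flagged_folds=flagged)
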