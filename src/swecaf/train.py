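"""Training protocol: mini-batch momentum SGD on cross-entropy with
paired flip augmentation, validation-based model selection, and grid search.

The protocol mirrors the emulated study: SGD with momentum 0.95, 200
epochs at full scale, learning rate and batch size chosen by grid search
over {1e-2 … 1e-6} x {2, 4, 8, 16, 32, 64, 128}, selecting the cell whose
validation sum of AUC + accuracy + sensitivity + specificity (image level)
is highest.  Desk-scale runs shrink epochs and the grid, not the protocol.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import PairDataset, augment_pair
from .metrics import DEFAULT_CUTOFF, MetricsReport, PredictionRecord, metrics_report
from .model import BimodalNet
from .nn import SGD, cross_entropy_with_logits
from .nn.losses import binary_cross_entropy  # noqa: F401  (re-exported spec op)

__all__ = ["TrainConfig", "TrainHistory", "train", "grid_search", "predict_records", "binary_cross_entropy"]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 32
    epochs: int = 200
    momentum: float = 0.95
    lr_grid: tuple[float, ...] = (1e-2, 1e-3, 1e-4, 1e-5, 1e-6)
    batch_grid: tuple[int, ...] = (2, 4, 8, 16, 32, 64, 128)
    augment_flip_p: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0.0 <= self.augment_flip_p <= 1.0:
            raise ValueError("augment_flip_p must be in [0,1]")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_reports: list[MetricsReport | None] = field(default_factory=list)
    selected_epoch: int = -1
    selected_hyperparams: tuple[float, int] | None = None

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)


def _batch_inputs(model: BimodalNet, gray, elast):
    kwargs = {}
    if "grayscale" in model.branches:
        kwargs["grayscale"] = gray
    if "elastography" in model.branches:
        kwargs["elastography"] = elast
    return kwargs


def predict_records(
    model: BimodalNet, dataset: PairDataset, batch_size: int = 64, cutoff: float = DEFAULT_CUTOFF
) -> list[PredictionRecord]:
    """Run inference over a dataset, one record per image pair."""
    records = []
    for start in range(0, len(dataset), batch_size):
        sl = slice(start, start + batch_size)
        out = model.forward(
            **_batch_inputs(model, dataset.grayscale[sl], dataset.elastography[sl]), train=False
        )
        for i, p in enumerate(out.prob_high):
            j = start + i
            records.append(
                PredictionRecord.from_probability(
                    dataset.tumor_ids[j], int(dataset.pair_indices[j]), int(dataset.y[j]), p, cutoff
                )
            )
    return records


def train(
    model: BimodalNet,
    train_set: PairDataset,
    val_set: PairDataset | None,
    config: TrainConfig,
) -> TrainHistory:
    """Train in place; returns the per-epoch history.

    After each epoch the image-level validation metrics are computed and the
    parameters of the epoch with the highest selection score (sum of AUC,
    accuracy, sensitivity, specificity) are retained; ties go to the
    earliest epoch.  With ``val_set=None`` the final-epoch weights stand.
    """
    config.validate()
    if len(np.unique(train_set.y)) < 2:
        raise ValueError("training split must contain both classes")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    model.set_dropout_rng(np.random.default_rng(np.random.SeedSequence([config.seed, 202])))
    opt = SGD(model.parameters(), config.learning_rate, config.momentum)
    history = TrainHistory()
    best_score, best_state = -np.inf, None
    n = len(train_set)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            gray = train_set.grayscale[idx]
            elast = train_set.elastography[idx]
            if config.augment_flip_p > 0:
                gray = gray.copy()
                elast = elast.copy()
                for b in range(len(idx)):
                    gray[b], elast[b] = augment_pair(gray[b], elast[b], config.augment_flip_p, rng)
            out = model.forward(**_batch_inputs(model, gray, elast), train=True)
            loss, dlogits = cross_entropy_with_logits(out.logits, train_set.y[idx])
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged at epoch {epoch}: loss={loss}")
            losses.append(loss * len(idx))
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
        history.train_loss.append(float(np.sum(losses) / n))
        if val_set is not None:
            report = metrics_report(predict_records(model, val_set), level="image")
            history.val_reports.append(report)
            score = report.selection_score
            if np.isfinite(score) and score > best_score:
                best_score, best_state = score, model.copy_params()
                history.selected_epoch = epoch
        else:
            history.val_reports.append(None)
            history.selected_epoch = epoch
    if best_state is not None:
        model.load_state_dict(best_state)
    history.selected_hyperparams = (config.learning_rate, config.batch_size)
    return history


def grid_search(
    build_model_fn,
    train_set: PairDataset,
    val_set: PairDataset,
    base_config: TrainConfig,
    epochs_override: int | None = None,
) -> tuple[tuple[float, int], pd.DataFrame]:
    """Train one model per (learning rate, batch size) grid cell and return
    the argmax of the validation selection score plus the full score table.

    ``build_model_fn(seed)`` must return a fresh, identically initialized
    model for every cell.  Ties break deterministically toward the first
    cell in row-major (learning-rate-major) grid order.
    """
    if not base_config.lr_grid or not base_config.batch_grid:
        raise ValueError("grids must be non-empty")
    rows = []
    best_key, best_score = None, -np.inf
    epochs = epochs_override or base_config.epochs
    for lr, bs in itertools.product(base_config.lr_grid, base_config.batch_grid):
        cfg = replace(base_config, learning_rate=lr, batch_size=bs, epochs=epochs)
        model = build_model_fn(base_config.seed)
        hist = train(model, train_set, val_set, cfg)
        reports = [r for r in hist.val_reports if r is not None]
        score = max((r.selection_score for r in reports if np.isfinite(r.selection_score)), default=float("nan"))
        rows.append({"learning_rate": lr, "batch_size": bs, "selection_score": score})
        if np.isfinite(score) and score > best_score:  # strict > keeps the first maximum
            best_key, best_score = (lr, bs), score
    table = pd.DataFrame(rows)
    if best_key is None:
        raise RuntimeError("no grid cell produced a finite selection score")
    return best_key, table
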