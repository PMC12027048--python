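"""One-command orchestration: simulate -> label -> train -> evaluate -> ....

An :class:`ExperimentConfig` bundles every stage's configuration plus an
ordered stage subset and a single global seed.  The global seed fans out to
per-stage seeds through a fixed counter scheme
(``SeedSequence([global_seed, stage_index])``), so any stage can be re-run
in isolation and reproduce its part of a full run.

All artifacts land under ``out_dir``: the cohort images and CSV manifest,
the labeled manifest with its threshold sidecar, checkpoints, per-stage
JSON/CSV reports, Grad-CAM overlays, and a ``provenance.json`` recording
the fully resolved configuration and seeds.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import dataset_from_cohort
from .evaluate import ablation, cross_validate, evaluate
from .labeling import LabelingConfig, label_and_split, apply_to_manifest
from .model import ModelSpec, build_model, save_checkpoint, load_checkpoint
from .saliency import gradcam, overlay
from .synthetic import CohortConfig, generate_cohort, save_cohort
from .train import TrainConfig, grid_search, train

__all__ = ["ExperimentConfig", "run_experiment", "desk_preset", "stage_seed"]

STAGE_ORDER = ("simulate", "label", "gridsearch", "train", "evaluate", "ablation", "crossval", "gradcam")
STAGE_DEPS = {
    "simulate": (),
    "label": ("simulate",),
    "gridsearch": ("label",),
    "train": ("label",),
    "evaluate": ("train",),
    "ablation": ("label",),
    "crossval": ("label",),
    "gradcam": ("train",),
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    idx = STAGE_ORDER.index(stage)
    return int(np.random.SeedSequence([global_seed, idx]).generate_state(1)[0] % (2**31))


@dataclass
class ExperimentConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    labeling: LabelingConfig = field(default_factory=LabelingConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    model: ModelSpec = field(default_factory=ModelSpec)
    stages: tuple[str, ...] = ("simulate", "label", "train", "evaluate")
    out_dir: str = "runs/experiment"
    global_seed: int = 0
    crossval_k: int = 5
    gradcam_n_pairs: int = 4

    def validate(self) -> None:
        seen = set()
        order = {s: i for i, s in enumerate(STAGE_ORDER)}
        last = -1
        for s in self.stages:
            if s not in order:
                raise ValueError(f"unknown stage {s!r}")
            if order[s] <= last:
                raise ValueError(f"stages out of dependency order at {s!r}")
            for dep in STAGE_DEPS[s]:
                if dep not in seen:
                    raise ValueError(f"stage {s!r} requires {dep!r} to run first")
            seen.add(s)
            last = order[s]
        if self.cohort.image_size_px != self.model.input_hw:
            # allowed: images are resized at preprocessing; just validate specs
            pass
        self.cohort.validate()
        self.labeling.validate()
        self.training.validate()
        self.model.validate()

    # -- YAML round trip ---------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        kwargs = dict(d)
        if "cohort" in kwargs:
            kwargs["cohort"] = CohortConfig(**kwargs["cohort"])
        if "labeling" in kwargs:
            lab = dict(kwargs["labeling"])
            if "split_ratios" in lab:
                lab["split_ratios"] = tuple(lab["split_ratios"])
            kwargs["labeling"] = LabelingConfig(**lab)
        if "training" in kwargs:
            tr = dict(kwargs["training"])
            for key in ("lr_grid", "batch_grid"):
                if key in tr:
                    tr[key] = tuple(tr[key])
            kwargs["training"] = TrainConfig(**tr)
        if "model" in kwargs:
            mo = dict(kwargs["model"])
            for key in ("channels", "classifier_sizes"):
                if key in mo:
                    mo[key] = tuple(mo[key])
            kwargs["model"] = ModelSpec(**mo)
        if "stages" in kwargs:
            kwargs["stages"] = tuple(kwargs["stages"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def desk_preset(seed: int = 0, out_dir: str = "runs/desk") -> ExperimentConfig:
    """Small-footprint profile: 20 tumors, 64x64 images, channels [8, 16],
    10 epochs, no grid search — runs end to end in minutes on one CPU."""
    from .synthetic import desk_config

    return ExperimentConfig(
        cohort=desk_config(n_tumors=20, image_size_px=64, seed=seed),
        labeling=LabelingConfig(seed=seed),
        training=TrainConfig(learning_rate=1e-2, batch_size=8, epochs=10, seed=seed),
        model=ModelSpec(n_blocks=2, channels=(8, 16), input_hw=64),
        stages=("simulate", "label", "train", "evaluate"),
        out_dir=out_dir,
        global_seed=seed,
    )


def run_experiment(config: ExperimentConfig) -> Path:
    """Execute the requested stages in order; returns the run directory.

    A stage failure halts the run with the failed stage named; artifacts of
    earlier stages are preserved.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = {
        "config": config.to_dict(),
        "stage_seeds": {s: stage_seed(config.global_seed, s) for s in config.stages},
        "swecaf_version": __version__,
        "numpy_version": np.__version__,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, default=str))

    state: dict = {}
    for stage in config.stages:
        try:
            _run_stage(stage, config, out, state)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    return out


def _datasets(config, state):
    cohort, manifest = state["cohort"], state["split"]
    hw = config.model.input_hw
    return {s: dataset_from_cohort(cohort, manifest, s, hw) for s in ("train", "val", "test")}


def _run_stage(stage: str, config: ExperimentConfig, out: Path, state: dict) -> None:
    seed = stage_seed(config.global_seed, stage)
    if stage == "simulate":
        cohort = generate_cohort(replace(config.cohort, seed=seed))
        state["cohort"] = cohort
        state["manifest_df"] = save_cohort(cohort, out / "cohort")
    elif stage == "label":
        manifest = label_and_split(state["cohort"].records, replace(config.labeling, seed=seed))
        state["split"] = manifest
        labeled = apply_to_manifest(state["manifest_df"], manifest, out / "threshold.json")
        labeled.to_csv(out / "labeled_manifest.csv", index=False)
        state["datasets"] = _datasets(config, state)
    elif stage == "gridsearch":
        ds = state["datasets"]
        best, table = grid_search(
            lambda s: build_model(config.model, "bimodal", seed=s),
            ds["train"],
            ds["val"],
            replace(config.training, seed=seed),
        )
        table.to_csv(out / "gridsearch.csv", index=False)
        state["best_hyperparams"] = best
        config.training = replace(config.training, learning_rate=best[0], batch_size=best[1])
    elif stage == "train":
        ds = state["datasets"]
        model = build_model(config.model, "bimodal", seed=seed)
        history = train(model, ds["train"], ds["val"], replace(config.training, seed=seed))
        state["model"] = model
        save_checkpoint(model, out / "checkpoint.npz")
        (out / "history.json").write_text(
            json.dumps(
                {
                    "train_loss": history.train_loss,
                    "selected_epoch": history.selected_epoch,
                    "selected_hyperparams": history.selected_hyperparams,
                },
                indent=2,
            )
        )
    elif stage == "evaluate":
        result = evaluate(state["model"], state["datasets"]["test"])
        result.save(out / "test_metrics.json")
        pd.DataFrame([dataclasses.asdict(r) for r in result.image_records]).to_csv(
            out / "test_predictions.csv", index=False
        )
        state["evaluation"] = result
    elif stage == "ablation":
        ds = state["datasets"]
        table = ablation(config.model, ds["train"], ds["val"], ds["test"], replace(config.training, seed=seed))
        table.to_csv(out / "ablation.csv", index=False)
        state["ablation"] = table
    elif stage == "crossval":
        ds = state["datasets"]
        full = _concat_datasets(ds)
        labels = {r.tumor_id: r.label for r in state["split"].records}
        cv = cross_validate(config.model, full, labels, replace(config.training, seed=seed), k=config.crossval_k)
        cv.summary.to_csv(out / "crossval.csv", index=False)
        state["crossval"] = cv
    elif stage == "gradcam":
        _run_gradcam(config, out, state)


def _concat_datasets(ds: dict):
    from .data import PairDataset

    return PairDataset(
        np.concatenate([ds[s].grayscale for s in ("train", "val", "test")]),
        np.concatenate([ds[s].elastography for s in ("train", "val", "test")]),
        np.concatenate([ds[s].y for s in ("train", "val", "test")]),
        np.concatenate([ds[s].tumor_ids for s in ("train", "val", "test")]),
        np.concatenate([ds[s].pair_indices for s in ("train", "val", "test")]),
    )


def _run_gradcam(config: ExperimentConfig, out: Path, state: dict) -> None:
    model = state["model"]
    test = state["datasets"]["test"]
    cam_dir = out / "gradcam"
    cam_dir.mkdir(exist_ok=True)
    n_done = 0
    for i in range(len(test)):
        if n_done >= config.gradcam_n_pairs:
            break
        gray, elast = test.grayscale[i], test.elastography[i]
        cls = "high" if test.y[i] == 1 else "low"
        for modality in model.branch_order:
            smap = gradcam(model, gray, elast, target_class=cls, modality=modality)
            stem = f"{test.tumor_ids[i]}_{test.pair_indices[i]:02d}_{modality}"
            np.save(cam_dir / f"{stem}.npy", smap.heatmap)
            base = (gray[0] * 255).astype(np.uint8) if modality == "grayscale" else (
                (elast.transpose(1, 2, 0) * 255).astype(np.uint8)
            )
            overlay(smap, base, out_path=cam_dir / f"{stem}.png")
        n_done += 1
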