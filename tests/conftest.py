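"""Shared fixtures: session-scoped trained models so expensive training runs
once and is reused by the training, saliency, and acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

import swecaf


@pytest.fixture(scope="session")
def separable_run():
    """Near-separable 60-tumor cohort (64x64, channels [8, 16]) trained for
    30 epochs — the standard desk-scale learning experiment."""
    cfg = swecaf.separable_cohort_config(n_tumors=60, image_size_px=64, seed=7)
    cohort = swecaf.generate_cohort(cfg)
    manifest = swecaf.label_and_split(cohort.records, swecaf.LabelingConfig(seed=0))
    sets = {s: swecaf.dataset_from_cohort(cohort, manifest, s, 64) for s in ("train", "val", "test")}
    spec = swecaf.ModelSpec(n_blocks=2, channels=(8, 16), input_hw=64)
    model = swecaf.build_model(spec, "bimodal", seed=0)
    history = swecaf.train(
        model,
        sets["train"],
        sets["val"],
        swecaf.TrainConfig(learning_rate=1e-2, batch_size=16, epochs=30, seed=0),
    )
    result = swecaf.evaluate(model, sets["test"])
    return {
        "cohort": cohort,
        "manifest": manifest,
        "sets": sets,
        "spec": spec,
        "model": model,
        "history": history,
        "result": result,
    }


@pytest.fixture(scope="session")
def toy_sets():
    """Noise-free toy cohort with extreme stiffness separation: 20 tumors,
    48x48 images, constant fields, no speckle."""
    cfg = swecaf.CohortConfig(
        n_tumors=20,
        pairs_per_tumor_mean=6,
        image_size_px=48,
        vtn_low_mean=0.05,
        vtn_high_mean=0.9,
        vtn_sd=0.01,
        stiffness_slope=90.0,
        stiffness_intercept=5.0,
        stiffness_noise_sd=0.0,
        field_texture_sd=0.0,
        speckle_scale=0.0,
        seed=3,
    )
    cohort = swecaf.generate_cohort(cfg)
    manifest = swecaf.label_and_split(cohort.records, swecaf.LabelingConfig(seed=1))
    return {
        "cohort": cohort,
        "sets": {s: swecaf.dataset_from_cohort(cohort, manifest, s, 48) for s in ("train", "val", "test")},
        "spec": swecaf.ModelSpec(n_blocks=2, channels=(8, 16), input_hw=48),
    }


@pytest.fixture(scope="session")
def tiny_cohort():
    """Smallest useful cohort for plumbing tests (8 tumors, 32x32)."""
    cfg = swecaf.CohortConfig(n_tumors=8, pairs_per_tumor_mean=3, image_size_px=32, seed=5)
    cohort = swecaf.generate_cohort(cfg)
    manifest = swecaf.label_and_split(cohort.records, swecaf.LabelingConfig(seed=5))
    return cohort, manifest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
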