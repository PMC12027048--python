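"""Loss closed forms, preprocessing, augmentation, and the training loop."""

from __future__ import annotations

import math

import numpy as np
import pytest

import swecaf
from swecaf.data import augment_pair, preprocess
from swecaf.model import ModelSpec, build_model
from swecaf.synthetic import ImagePair
from swecaf.train import TrainConfig, binary_cross_entropy, grid_search, train


class TestBinaryCrossEntropy:
    def test_perfect_predictions_cost_nothing(self):
        assert binary_cross_entropy(1, 1.0) == pytest.approx(0.0, abs=1e-6)
        assert binary_cross_entropy(0, 0.0) == pytest.approx(0.0, abs=1e-6)

    def test_coin_flip_costs_ln2(self):
        assert binary_cross_entropy(1, 0.5) == pytest.approx(math.log(2), rel=1e-9)

    def test_batch_mean_matches_hand_loop(self, rng):
        y = rng.integers(0, 2, 20)
        p = rng.uniform(0.01, 0.99, 20)
        hand = sum(-(yi * math.log(pi) + (1 - yi) * math.log(1 - pi)) for yi, pi in zip(y, p)) / 20
        assert binary_cross_entropy(y, p) == pytest.approx(hand, rel=1e-12)

    def test_invalid_labels_rejected(self):
        with pytest.raises(ValueError):
            binary_cross_entropy(2, 0.5)


class TestPreprocess:
    def test_resizes_any_geometry_to_target(self, rng):
        pair = ImagePair(
            grayscale=rng.integers(0, 256, (180, 300), dtype=np.uint8).astype(np.uint8),
            elastography=rng.integers(0, 256, (180, 300, 3), dtype=np.uint8).astype(np.uint8),
            tumor_id="T0",
            pair_index=0,
        )
        gray, elast = preprocess(pair, 224)
        assert gray.shape == (1, 224, 224)
        assert elast.shape == (3, 224, 224)
        assert gray.max() <= 1.0 and gray.min() >= 0.0
        assert elast.max() <= 1.0 and elast.min() >= 0.0

    def test_idempotent_after_first_application(self, rng):
        pair = ImagePair(
            grayscale=rng.integers(0, 256, (64, 64), dtype=np.uint8).astype(np.uint8),
            elastography=rng.integers(0, 256, (64, 64, 3), dtype=np.uint8).astype(np.uint8),
            tumor_id="T0",
            pair_index=0,
        )
        gray1, elast1 = preprocess(pair, 64)
        # re-wrapping the already-sized images and preprocessing again is a no-op
        pair2 = ImagePair(
            grayscale=(gray1[0] * 255).astype(np.uint8),
            elastography=(elast1.transpose(1, 2, 0) * 255).astype(np.uint8),
            tumor_id="T0",
            pair_index=0,
        )
        gray2, elast2 = preprocess(pair2, 64)
        np.testing.assert_allclose(gray2, gray1, atol=1 / 255)
        np.testing.assert_allclose(elast2, elast1, atol=1 / 255)


class TestAugmentation:
    def test_zero_probability_is_identity(self, rng):
        gray = rng.random((1, 8, 8))
        elast = rng.random((3, 8, 8))
        g, e = augment_pair(gray, elast, 0.0, rng)
        np.testing.assert_array_equal(g, gray)
        np.testing.assert_array_equal(e, elast)

    def test_certain_flips_are_involutive(self, rng):
        gray = rng.random((1, 8, 8))
        elast = rng.random((3, 8, 8))
        g1, e1 = augment_pair(gray, elast, 1.0, rng)
        assert not np.array_equal(g1, gray)
        g2, e2 = augment_pair(g1, e1, 1.0, rng)
        np.testing.assert_array_equal(g2, gray)
        np.testing.assert_array_equal(e2, elast)

    def test_flip_frequency_matches_probability(self):
        rng = np.random.default_rng(77)
        gray = np.arange(16, dtype=float).reshape(1, 4, 4)
        elast = np.arange(48, dtype=float).reshape(3, 4, 4)
        variants = {
            "none": gray,
            "h": gray[..., ::-1],
            "v": gray[..., ::-1, :],
            "hv": gray[..., ::-1, :][..., ::-1],
        }
        h_flips = v_flips = 0
        n = 1000
        for _ in range(n):
            g, e = augment_pair(gray, elast, 0.3, rng)
            kind = next(k for k, v in variants.items() if np.array_equal(g, v))
            if "h" in kind:
                h_flips += 1
                # co-registration: the same flip hit the elastography image
                assert np.array_equal(e[..., -1], elast[..., 0] if kind == "h" else elast[..., ::-1, :][..., 0])
            if "v" in kind:
                v_flips += 1
        # each axis flips Binomial(1000, 0.3): 3 sigma ~ 43
        assert abs(h_flips - 300) < 45
        assert abs(v_flips - 300) < 45


class TestTrainLoop:
    def test_single_epoch_smoke(self, toy_sets):
        model = build_model(toy_sets["spec"], "bimodal", seed=0)
        hist = train(model, toy_sets["sets"]["train"], toy_sets["sets"]["val"], TrainConfig(learning_rate=1e-3, batch_size=8, epochs=1, seed=0))
        assert hist.n_epochs == 1
        assert hist.selected_epoch == 0

    def test_zero_learning_rate_leaves_parameters_unchanged(self, toy_sets):
        model = build_model(toy_sets["spec"], "bimodal", seed=1)
        before = model.copy_params()
        train(model, toy_sets["sets"]["train"], None, TrainConfig(learning_rate=0.0, batch_size=8, epochs=1, seed=0))
        after = model.state_dict()
        for key, value in before.items():
            if "running" in key:  # batch-norm statistics still update
                continue
            np.testing.assert_array_equal(after[key], value, err_msg=key)

    def test_separable_toy_learns_cleanly(self, toy_sets):
        """On a noise-free, extreme-separation cohort the loss decreases
        strictly over the first five epochs and validation AUC is high."""
        model = build_model(toy_sets["spec"], "bimodal", seed=2)
        hist = train(
            model,
            toy_sets["sets"]["train"],
            toy_sets["sets"]["val"],
            TrainConfig(learning_rate=1e-4, batch_size=8, epochs=10, seed=2),
        )
        first5 = hist.train_loss[:5]
        assert all(b < a for a, b in zip(first5, first5[1:]))
        assert max(r.auc for r in hist.val_reports) >= 95.0

    def test_single_class_training_split_rejected(self, toy_sets):
        ds = toy_sets["sets"]["train"]
        only_high = ds.subset(ds.y == 1)
        model = build_model(toy_sets["spec"], "bimodal", seed=0)
        with pytest.raises(ValueError, match="both classes"):
            train(model, only_high, None, TrainConfig(epochs=1))

    def test_seeded_training_is_reproducible(self, toy_sets):
        def run():
            model = build_model(toy_sets["spec"], "bimodal", seed=3)
            hist = train(
                model,
                toy_sets["sets"]["train"],
                toy_sets["sets"]["val"],
                TrainConfig(learning_rate=1e-3, batch_size=8, epochs=2, seed=3),
            )
            return hist.train_loss, hist.selected_epoch

        assert run() == run()


class TestGridSearch:
    def test_singleton_grids_return_that_cell(self, toy_sets):
        cfg = TrainConfig(lr_grid=(1e-3,), batch_grid=(8,), epochs=1, seed=0)
        best, table = grid_search(
            lambda s: build_model(toy_sets["spec"], "bimodal", seed=s),
            toy_sets["sets"]["train"],
            toy_sets["sets"]["val"],
            cfg,
        )
        assert best == (1e-3, 8)
        assert len(table) == 1

    def test_argmax_matches_bruteforce_scan_of_table(self, toy_sets):
        cfg = TrainConfig(lr_grid=(1e-3, 1e-4), batch_grid=(8, 16), epochs=1, seed=0)
        best, table = grid_search(
            lambda s: build_model(toy_sets["spec"], "bimodal", seed=s),
            toy_sets["sets"]["train"],
            toy_sets["sets"]["val"],
            cfg,
        )
        assert len(table) == 4
        # brute-force scan in row-major order, first strict maximum wins
        scan_best, scan_score = None, -np.inf
        for _, row in table.iterrows():
            if row.selection_score > scan_score:
                scan_best, scan_score = (row.learning_rate, row.batch_size), row.selection_score
        assert best == scan_best

    def test_empty_grid_rejected(self, toy_sets):
        with pytest.raises(ValueError):
            grid_search(
                lambda s: build_model(toy_sets["spec"], "bimodal", seed=s),
                toy_sets["sets"]["train"],
                toy_sets["sets"]["val"],
                TrainConfig(lr_grid=(), epochs=1),
            )


def test_default_protocol_constants():
    """The full-scale protocol: 5 x 7 hyperparameter grid, 200 epochs,
    momentum 0.95 — the configuration the analysis is defined with."""
    cfg = TrainConfig()
    assert len(cfg.lr_grid) * len(cfg.batch_grid) == 35
    assert cfg.epochs == 200
    assert cfg.momentum == 0.95
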