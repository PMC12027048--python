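"""Cohort generator: sampling statistics, stiffness fields, and rendering."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from swecaf.synthetic import (
    CohortConfig,
    ConfigurationError,
    TumorRecord,
    generate_cohort,
    render_elastography,
    render_grayscale,
    sample_cohort,
    save_cohort,
    stiffness_to_rgb,
    synth_stiffness_field,
)


class TestSampleCohort:
    def test_default_cohort_size_and_pair_budget(self):
        records = sample_cohort(CohortConfig(seed=42))
        assert len(records) == 105
        total_pairs = sum(r.n_pairs for r in records)
        # shifted Poisson, mean 10: sd of the total is 3*sqrt(105) ~ 31
        assert abs(total_pairs - 1050) < 150

    def test_same_seed_is_byte_identical(self):
        a = sample_cohort(CohortConfig(seed=9))
        b = sample_cohort(CohortConfig(seed=9))
        assert a == b
        c = sample_cohort(CohortConfig(seed=10))
        assert a != c

    def test_noise_free_stiffness_is_exact_linear_function(self):
        cfg = replace(CohortConfig(seed=3), stiffness_noise_sd=0.0)
        records = sample_cohort(cfg)
        for r in records:
            expected = np.clip(cfg.stiffness_intercept + cfg.stiffness_slope * r.vtn_fraction, 0, 100)
            assert r.mean_stiffness_kpa == pytest.approx(expected, abs=1e-9)
        # monotone coupling: stiffness strictly increases with VTN fraction
        srt = sorted(records, key=lambda r: r.vtn_fraction)
        stiff = [r.mean_stiffness_kpa for r in srt]
        assert all(b > a for a, b in zip(stiff, stiff[1:]))

    @pytest.mark.parametrize(
        "bad",
        [
            {"n_tumors": 1},
            {"pairs_per_tumor_mean": 0.5},
            {"image_size_px": 16},
            {"vtn_low_mean": 0.6, "vtn_high_mean": 0.5},
            {"vtn_high_mean": 1.2},
            {"stiffness_slope": -1.0},
        ],
    )
    def test_invalid_config_raises(self, bad):
        with pytest.raises(ConfigurationError):
            sample_cohort(replace(CohortConfig(), **bad))

    def test_group_separation_mirrors_cohort_design(self):
        """Tumors above the cohort median VTN are stiffer on average."""
        records = sample_cohort(CohortConfig(n_tumors=60, seed=21))
        vtn = np.array([r.vtn_fraction for r in records])
        stiff = np.array([r.mean_stiffness_kpa for r in records])
        thr = np.median(vtn)
        assert stiff[vtn > thr].mean() > stiff[vtn <= thr].mean()


class TestStiffnessField:
    record = TumorRecord(tumor_id="T0", vtn_fraction=0.4, mean_stiffness_kpa=30.0, n_pairs=1)

    def test_zero_texture_gives_constant_roi(self):
        fld = synth_stiffness_field(self.record, 64, seed=0, texture_sd=0.0)
        np.testing.assert_allclose(fld.grid[fld.roi_mask], 30.0)
        np.testing.assert_allclose(fld.grid[~fld.roi_mask], 5.0)

    def test_roi_mean_matches_target_over_many_seeds(self):
        devs = []
        for seed in range(100):
            fld = synth_stiffness_field(self.record, 64, seed=seed)
            devs.append(abs(fld.grid[fld.roi_mask].mean() - 30.0))
        assert np.mean(devs) < 0.5  # kPa; exact pre-clip, clip rarely binds at 30 kPa

    def test_values_clipped_to_machine_range(self):
        hot = TumorRecord(tumor_id="T1", vtn_fraction=0.9, mean_stiffness_kpa=99.0, n_pairs=1)
        for seed in range(10):
            fld = synth_stiffness_field(hot, 64, seed=seed)
            assert fld.grid.min() >= 0.0 and fld.grid.max() <= 100.0

    def test_too_small_size_raises(self):
        with pytest.raises(ValueError):
            synth_stiffness_field(self.record, 8, seed=0)


class TestRendering:
    def test_colormap_endpoints_blue_and_red(self):
        assert tuple(stiffness_to_rgb(np.array(0.0))) == (0, 0, 255)
        assert tuple(stiffness_to_rgb(np.array(100.0))) == (255, 0, 0)

    def test_out_of_range_stiffness_rejected(self):
        with pytest.raises(ValueError):
            stiffness_to_rgb(np.array([50.0, 101.0]))

    def test_elastography_rendering_deterministic(self):
        fld = synth_stiffness_field(TestStiffnessField.record, 48, seed=4)
        np.testing.assert_array_equal(render_elastography(fld), render_elastography(fld))

    def test_grayscale_noise_free_limit_is_two_level(self):
        fld = synth_stiffness_field(TestStiffnessField.record, 48, seed=4, texture_sd=0.0)
        img = render_grayscale(fld, seed=1, speckle_scale=0.0)
        assert len(np.unique(img)) == 2
        assert img[fld.roi_mask].mean() > img[~fld.roi_mask].mean()

    def test_grayscale_contrast_survives_speckle(self):
        """ROI stays brighter than background on average across seeds."""
        fld = synth_stiffness_field(TestStiffnessField.record, 48, seed=4)
        diffs = []
        for seed in range(50):
            img = render_grayscale(fld, seed=seed, bg_level=0.25, roi_level=0.45, speckle_scale=0.5)
            diffs.append(img[fld.roi_mask].mean() - img[~fld.roi_mask].mean())
        assert np.mean(diffs) > 10  # 8-bit intensity units

    def test_grayscale_seeded_determinism(self):
        fld = synth_stiffness_field(TestStiffnessField.record, 48, seed=4)
        np.testing.assert_array_equal(render_grayscale(fld, seed=7), render_grayscale(fld, seed=7))
        assert (render_grayscale(fld, seed=7) != render_grayscale(fld, seed=8)).any()


class TestGenerateCohort:
    def test_cohort_is_pure_function_of_config(self):
        cfg = CohortConfig(n_tumors=4, pairs_per_tumor_mean=2, image_size_px=32, seed=6)
        a, b = generate_cohort(cfg), generate_cohort(cfg)
        assert a.records == b.records
        for pa, pb in zip(a.pairs, b.pairs):
            np.testing.assert_array_equal(pa.grayscale, pb.grayscale)
            np.testing.assert_array_equal(pa.elastography, pb.elastography)

    def test_pairs_are_coregistered_and_masked(self):
        cohort = generate_cohort(CohortConfig(n_tumors=3, pairs_per_tumor_mean=2, image_size_px=32, seed=2))
        for p in cohort.pairs:
            assert p.grayscale.shape == p.elastography.shape[:2]
            assert (p.tumor_id, p.pair_index) in cohort.roi_masks

    def test_save_cohort_roundtrip(self, tmp_path):
        from PIL import Image

        cohort = generate_cohort(CohortConfig(n_tumors=3, pairs_per_tumor_mean=2, image_size_px=32, seed=2))
        manifest = save_cohort(cohort, tmp_path)
        assert len(manifest) == len(cohort.pairs)
        row = manifest.iloc[0]
        gray = np.asarray(Image.open(row.grayscale_path))
        np.testing.assert_array_equal(gray, cohort.pairs[0].grayscale)
        elast = np.asarray(Image.open(row.elastography_path))
        np.testing.assert_array_equal(elast, cohort.pairs[0].elastography)
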