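"""Synthetic shear-wave-elastography cohort generator.

Emulates a mouse-tumor imaging study in which each tumor carries

* a scalar VTN immunofluorescence fraction (the abundance of wound-healing
  cancer-associated fibroblasts, in [0, 1]),
* a mean tissue stiffness in kPa that increases with the VTN fraction, and
* ~10 co-registered image pairs: a grayscale B-mode image with speckle
  texture and a color elastography image mapping stiffness over 0-100 kPa
  from blue (soft) to red (hard).

The generator is a pure function of its :class:`CohortConfig`, including the
seed: the same configuration always yields byte-identical records and images.

VTN fractions are drawn from a two-component Gaussian mixture (low/high
abundance modes); stiffness couples to VTN linearly with Gaussian noise and
is clipped to the machine's 0-100 kPa range.  Tumor cross-sections are
ellipses with randomized axes and orientation; the in-ROI stiffness field is
the tumor mean plus smooth (Gaussian-filtered) texture.  B-mode speckle uses
the standard first-order model: multiplicative Rayleigh noise followed by
log compression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

__all__ = [
    "CohortConfig",
    "TumorRecord",
    "StiffnessField",
    "ImagePair",
    "Cohort",
    "sample_cohort",
    "synth_stiffness_field",
    "render_elastography",
    "render_grayscale",
    "generate_cohort",
    "save_cohort",
    "load_manifest",
    "stiffness_to_rgb",
    "separable_cohort_config",
    "complementary_cohort_config",
]


class ConfigurationError(ValueError):
    """A cohort configuration violates one of its invariants."""


# ---------------------------------------------------------------------------
# configuration and record types


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the emulated study: 105 tumors, on average 10 image
    pairs each, 224x224 pixels, stiffness range 0-100 kPa.
    """

    n_tumors: int = 105
    pairs_per_tumor_mean: float = 10.0
    image_size_px: int = 224
    # two-component VTN-fraction mixture (low mode / high mode)
    vtn_low_mean: float = 0.20
    vtn_high_mean: float = 0.50
    vtn_sd: float = 0.08
    high_fraction: float = 0.5
    # linear VTN -> stiffness coupling, kPa
    stiffness_slope: float = 45.0
    stiffness_intercept: float = 8.0
    stiffness_noise_sd: float = 4.0
    # in-ROI stiffness texture (kPa) and background tissue baseline (kPa)
    field_texture_sd: float = 3.0
    background_kpa: float = 5.0
    # B-mode appearance
    speckle_scale: float = 0.5
    gray_bg_level: float = 0.25
    gray_roi_contrast: float = 0.20
    gray_contrast_slope: float = 0.25
    # elliptical ROI area as a fraction of the image
    roi_area_frac_min: float = 0.20
    roi_area_frac_max: float = 0.60
    seed: int = 0

    def validate(self) -> None:
        if self.n_tumors < 2:
            raise ConfigurationError("n_tumors must be >= 2")
        if self.pairs_per_tumor_mean < 1:
            raise ConfigurationError("pairs_per_tumor_mean must be >= 1")
        if self.image_size_px < 32:
            raise ConfigurationError("image_size_px must be >= 32")
        if not (0.0 <= self.vtn_low_mean < self.vtn_high_mean <= 1.0):
            raise ConfigurationError("require 0 <= vtn_low_mean < vtn_high_mean <= 1")
        if self.stiffness_slope <= 0:
            raise ConfigurationError("stiffness_slope must be > 0 (high-VTN tumors are stiffer)")
        if not (0.0 < self.high_fraction < 1.0):
            raise ConfigurationError("high_fraction must be in (0,1)")
        if not (0.0 < self.roi_area_frac_min <= self.roi_area_frac_max < 1.0):
            raise ConfigurationError("roi area fractions must satisfy 0 < min <= max < 1")


@dataclass
class TumorRecord:
    """One tumor of the cohort."""

    tumor_id: str
    vtn_fraction: float
    mean_stiffness_kpa: float
    n_pairs: int
    label: str = "unassigned"  # {high, low, unassigned}
    split: str = "unassigned"  # {train, val, test, unassigned}

    def __post_init__(self):
        if not 0.0 <= self.vtn_fraction <= 1.0:
            raise ValueError("vtn_fraction must lie in [0,1]")
        if not 0.0 <= self.mean_stiffness_kpa <= 100.0:
            raise ValueError("mean_stiffness_kpa must lie in [0,100]")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")


@dataclass
class StiffnessField:
    """Stiffness map (kPa) over the image lattice plus the tumor ROI mask."""

    grid: np.ndarray  # (H, W) float, kPa in [0, 100]
    roi_mask: np.ndarray  # (H, W) bool

    def __post_init__(self):
        if self.grid.shape != self.roi_mask.shape:
            raise ValueError("grid and roi_mask shapes differ")
        if self.grid.min() < 0.0 or self.grid.max() > 100.0:
            raise ValueError("stiffness values must lie in [0,100] kPa")
        if not self.roi_mask.any():
            raise ValueError("roi_mask has no interior pixels")


@dataclass
class ImagePair:
    """Co-registered grayscale B-mode and color elastography images."""

    grayscale: np.ndarray  # (H, W) uint8
    elastography: np.ndarray  # (H, W, 3) uint8
    tumor_id: str
    pair_index: int

    def __post_init__(self):
        if self.grayscale.shape[:2] != self.elastography.shape[:2]:
            raise ValueError("image pair is not co-registered (shape mismatch)")


@dataclass
class Cohort:
    """A fully generated cohort held in memory.

    ``fields`` keeps the first stiffness field per tumor for inspection;
    ``roi_masks`` keeps the ROI mask of every pair, keyed by
    ``(tumor_id, pair_index)``, for localization analyses.
    """

    config: CohortConfig
    records: list[TumorRecord]
    pairs: list[ImagePair]
    fields: dict[str, StiffnessField] = field(default_factory=dict)
    roi_masks: dict[tuple[str, int], np.ndarray] = field(default_factory=dict)

    def pairs_of(self, tumor_id: str) -> list[ImagePair]:
        return [p for p in self.pairs if p.tumor_id == tumor_id]


# ---------------------------------------------------------------------------
# cohort-level sampling


def _rng_for(config_seed: int, *key: int) -> np.random.Generator:
    """Deterministic per-component generator: one stream per (seed, key...)."""
    return np.random.default_rng(np.random.SeedSequence([config_seed, *key]))


def sample_cohort(config: CohortConfig) -> list[TumorRecord]:
    """Draw the per-tumor scalars of a cohort (no images).

    VTN fractions come from the configured two-component mixture; mean
    stiffness is ``clip(intercept + slope * vtn + noise, 0, 100)``; the
    number of image pairs per tumor is shifted-Poisson with the configured
    mean and a minimum of one.
    """
    config.validate()
    rng = _rng_for(config.seed, 0)
    n = config.n_tumors
    is_high = rng.random(n) < config.high_fraction
    means = np.where(is_high, config.vtn_high_mean, config.vtn_low_mean)
    vtn = np.clip(rng.normal(means, config.vtn_sd), 0.0, 1.0)
    noise = rng.normal(0.0, config.stiffness_noise_sd, size=n) if config.stiffness_noise_sd > 0 else np.zeros(n)
    stiff = np.clip(config.stiffness_intercept + config.stiffness_slope * vtn + noise, 0.0, 100.0)
    # shifted Poisson: 1 + Poisson(mean - 1) keeps the configured mean with minimum 1
    n_pairs = 1 + rng.poisson(max(config.pairs_per_tumor_mean - 1.0, 0.0), size=n)
    width = len(str(n - 1))
    return [
        TumorRecord(
            tumor_id=f"T{i:0{width}d}",
            vtn_fraction=float(vtn[i]),
            mean_stiffness_kpa=float(stiff[i]),
            n_pairs=int(n_pairs[i]),
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# per-tumor stiffness field and rendering


def _ellipse_mask(size: int, rng: np.random.Generator, area_frac: tuple[float, float]) -> np.ndarray:
    """Random ellipse covering the configured fraction of the image area."""
    target = rng.uniform(*area_frac)
    # semi-axes from target area pi*a*b = target*size^2, random aspect ratio
    aspect = rng.uniform(0.5, 1.0)
    ab = target * size * size / math.pi
    a = math.sqrt(ab / aspect)
    b = ab / a
    theta = rng.uniform(0.0, math.pi)
    cy = size / 2 + rng.uniform(-0.05, 0.05) * size
    cx = size / 2 + rng.uniform(-0.05, 0.05) * size
    yy, xx = np.mgrid[0:size, 0:size]
    y, x = yy - cy, xx - cx
    ct, st = math.cos(theta), math.sin(theta)
    u = x * ct + y * st
    v = -x * st + y * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def synth_stiffness_field(
    record: TumorRecord,
    size: int,
    seed: int,
    *,
    texture_sd: float = 3.0,
    background_kpa: float = 5.0,
    area_frac: tuple[float, float] = (0.20, 0.60),
) -> StiffnessField:
    """Generate a smooth stiffness field whose ROI mean equals the tumor's
    ``mean_stiffness_kpa``.

    Texture is Gaussian noise low-pass filtered at sigma = size/16, then
    re-centered inside the ROI so the ROI mean matches the target exactly
    before the final [0, 100] kPa clip.
    """
    if size < 32:
        raise ValueError("field size must be >= 32 pixels")
    rng = np.random.default_rng(seed)
    mask = _ellipse_mask(size, rng, area_frac)
    grid = np.full((size, size), float(background_kpa))
    if texture_sd > 0:
        texture = ndimage.gaussian_filter(rng.normal(0.0, 1.0, size=(size, size)), sigma=size / 16)
        sd = texture.std()
        texture = texture / sd * texture_sd if sd > 0 else texture * 0.0
    else:
        texture = np.zeros((size, size))
    roi_vals = record.mean_stiffness_kpa + texture[mask]
    roi_vals += record.mean_stiffness_kpa - roi_vals.mean()  # exact ROI mean pre-clip
    grid[mask] = roi_vals
    grid = np.clip(grid, 0.0, 100.0)
    return StiffnessField(grid=grid, roi_mask=mask)


# piecewise-linear blue -> cyan -> green -> yellow -> red colormap over 0-100 kPa
_CMAP_KPA = np.array([0.0, 25.0, 50.0, 75.0, 100.0])
_CMAP_RGB = np.array(
    [
        [0, 0, 255],  # 0 kPa: pure blue (soft)
        [0, 255, 255],
        [0, 255, 0],
        [255, 255, 0],
        [255, 0, 0],  # 100 kPa: pure red (hard)
    ],
    dtype=float,
)


def stiffness_to_rgb(kpa: np.ndarray) -> np.ndarray:
    """Map kPa values in [0,100] to uint8 RGB via the fixed blue-to-red map."""
    kpa = np.asarray(kpa, dtype=float)
    if kpa.min() < 0.0 or kpa.max() > 100.0:
        raise ValueError("stiffness values outside [0,100] kPa; clip upstream")
    channels = [np.interp(kpa, _CMAP_KPA, _CMAP_RGB[:, c]) for c in range(3)]
    return np.stack(channels, axis=-1).round().astype(np.uint8)


def render_elastography(field: StiffnessField) -> np.ndarray:
    """Render the machine-style color elastography display of a field.

    Bit-deterministic: the output is a pure function of the stiffness grid.
    """
    return stiffness_to_rgb(field.grid)


def render_grayscale(
    field: StiffnessField,
    seed: int,
    *,
    bg_level: float = 0.25,
    roi_level: float = 0.45,
    speckle_scale: float = 0.5,
) -> np.ndarray:
    """Render a B-mode-like grayscale image co-registered with the field.

    The echogenicity template is two-level (background vs tumor ROI).
    Speckle is multiplicative Rayleigh noise, blended by ``speckle_scale``
    (0 = noise-free), then log-compressed to 8 bits.  ``speckle_scale=0``
    therefore yields a piecewise-constant two-level image.
    """
    rng = np.random.default_rng(seed)
    template = np.where(field.roi_mask, roi_level, bg_level)
    if speckle_scale > 0:
        rayleigh = rng.rayleigh(scale=1.0, size=template.shape)
        rayleigh /= math.sqrt(math.pi / 2.0)  # unit mean
        template = template * ((1.0 - speckle_scale) + speckle_scale * rayleigh)
    # log compression, fixed dynamic-range constant
    a = 30.0
    img = np.log1p(a * template) / np.log1p(a)
    return np.clip(img * 255.0, 0, 255).round().astype(np.uint8)


# ---------------------------------------------------------------------------
# full cohort generation and I/O


def generate_cohort(config: CohortConfig) -> Cohort:
    """Sample records and render every image pair of the cohort in memory."""
    records = sample_cohort(config)
    pairs: list[ImagePair] = []
    fields: dict[str, StiffnessField] = {}
    roi_masks: dict[tuple[str, int], np.ndarray] = {}
    # grayscale ROI echogenicity couples weakly to VTN so B-mode carries
    # partial label signal, as a real B-mode appearance plausibly would
    vtn_mid = 0.5 * (config.vtn_low_mean + config.vtn_high_mean)
    for t_idx, rec in enumerate(records):
        roi_level = config.gray_bg_level + config.gray_roi_contrast + config.gray_contrast_slope * (
            rec.vtn_fraction - vtn_mid
        )
        roi_level = float(np.clip(roi_level, 0.05, 0.95))
        for k in range(rec.n_pairs):
            fseed = np.random.SeedSequence([config.seed, 1, t_idx, k]).generate_state(1)[0]
            fld = synth_stiffness_field(
                rec,
                config.image_size_px,
                int(fseed),
                texture_sd=config.field_texture_sd,
                background_kpa=config.background_kpa,
                area_frac=(config.roi_area_frac_min, config.roi_area_frac_max),
            )
            gseed = np.random.SeedSequence([config.seed, 2, t_idx, k]).generate_state(1)[0]
            gray = render_grayscale(
                fld,
                int(gseed),
                bg_level=config.gray_bg_level,
                roi_level=roi_level,
                speckle_scale=config.speckle_scale,
            )
            elast = render_elastography(fld)
            pairs.append(ImagePair(grayscale=gray, elastography=elast, tumor_id=rec.tumor_id, pair_index=k))
            roi_masks[(rec.tumor_id, k)] = fld.roi_mask
            if k == 0:
                fields[rec.tumor_id] = fld
    return Cohort(config=config, records=records, pairs=pairs, fields=fields, roi_masks=roi_masks)


def save_cohort(cohort: Cohort, out_dir: str | Path) -> pd.DataFrame:
    """Write PNGs and the CSV manifest; returns the manifest frame."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    by_id = {r.tumor_id: r for r in cohort.records}
    rows = []
    for p in cohort.pairs:
        gpath = out / "images" / f"{p.tumor_id}_{p.pair_index:02d}_gray.png"
        epath = out / "images" / f"{p.tumor_id}_{p.pair_index:02d}_elast.png"
        Image.fromarray(p.grayscale, mode="L").save(gpath)
        Image.fromarray(p.elastography, mode="RGB").save(epath)
        rec = by_id[p.tumor_id]
        rows.append(
            {
                "tumor_id": p.tumor_id,
                "pair_index": p.pair_index,
                "grayscale_path": str(gpath),
                "elastography_path": str(epath),
                "vtn_fraction": rec.vtn_fraction,
                "mean_stiffness_kpa": rec.mean_stiffness_kpa,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def load_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# study-condition presets


def separable_cohort_config(n_tumors: int = 60, image_size_px: int = 64, seed: int = 0) -> CohortConfig:
    """Near-separable desk-scale cohort: wide VTN modes, low stiffness noise.

    The elastography color alone determines the label almost perfectly;
    used for learning-sanity and saliency-localization experiments.
    """
    return CohortConfig(
        n_tumors=n_tumors,
        pairs_per_tumor_mean=10.0,
        image_size_px=image_size_px,
        vtn_low_mean=0.15,
        vtn_high_mean=0.55,
        vtn_sd=0.05,
        stiffness_slope=60.0,
        stiffness_intercept=5.0,
        stiffness_noise_sd=1.0,
        field_texture_sd=2.0,
        speckle_scale=0.5,
        gray_contrast_slope=0.25,
        seed=seed,
    )


def complementary_cohort_config(n_tumors: int = 40, image_size_px: int = 48, seed: int = 0) -> CohortConfig:
    """Cohort in which each modality carries partial, complementary signal.

    Stiffness couples to VTN with substantial noise (elastography alone is
    imperfect) while the B-mode ROI echogenicity also couples to VTN with
    its own independent noise via the speckle; fusing both modalities can
    recover more of the label than either alone.
    """
    return CohortConfig(
        n_tumors=n_tumors,
        pairs_per_tumor_mean=8.0,
        image_size_px=image_size_px,
        vtn_low_mean=0.20,
        vtn_high_mean=0.50,
        vtn_sd=0.08,
        stiffness_slope=40.0,
        stiffness_intercept=8.0,
        stiffness_noise_sd=6.0,
        field_texture_sd=3.0,
        speckle_scale=0.6,
        gray_roi_contrast=0.15,
        gray_contrast_slope=0.55,
        seed=seed,
    )


def desk_config(n_tumors: int = 20, image_size_px: int = 64, seed: int = 0) -> CohortConfig:
    """Small smoke-test cohort for quick end-to-end runs."""
    return replace(separable_cohort_config(n_tumors, image_size_px, seed), pairs_per_tumor_mean=6.0)
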