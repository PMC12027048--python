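"""Image preprocessing, paired augmentation, and dataset assembly.

Preprocessing resizes both modalities of a pair to the model's input size
(bilinear) and scales intensities to [0, 1].  Training-time augmentation
applies random horizontal and vertical flips, with the SAME flip decision
on both modalities so co-registration survives; validation and test data
are never augmented.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .synthetic import Cohort, ImagePair
from .labeling import SplitManifest

__all__ = ["PairDataset", "preprocess", "augment_pair", "dataset_from_cohort", "dataset_from_manifest"]


@dataclass
class PairDataset:
    """Model-ready arrays for one split."""

    grayscale: np.ndarray  # (N, 1, H, W) float in [0,1]
    elastography: np.ndarray  # (N, 3, H, W) float in [0,1]
    y: np.ndarray  # (N,) int, 1 = high
    tumor_ids: np.ndarray  # (N,) str
    pair_indices: np.ndarray  # (N,) int

    def __len__(self) -> int:
        return self.y.shape[0]

    def subset(self, idx) -> "PairDataset":
        return PairDataset(
            self.grayscale[idx],
            self.elastography[idx],
            self.y[idx],
            self.tumor_ids[idx],
            self.pair_indices[idx],
        )


def _resize(img: np.ndarray, hw: int) -> np.ndarray:
    if img.shape[0] == hw and img.shape[1] == hw:
        return img.astype(np.float32)
    mode = "L" if img.ndim == 2 else "RGB"
    pil = Image.fromarray(img.astype(np.uint8), mode=mode)
    return np.asarray(pil.resize((hw, hw), Image.BILINEAR), dtype=np.float32)


def preprocess(pair: ImagePair, input_hw: int) -> tuple[np.ndarray, np.ndarray]:
    """Resize both modalities to ``input_hw`` and scale to [0, 1].

    Returns ``(grayscale (1,H,W), elastography (3,H,W))``.  Idempotent once
    applied: re-running on the produced arrays changes nothing.
    """
    gray = (_resize(pair.grayscale, input_hw) / 255.0).astype(np.float32)
    elast = (_resize(pair.elastography, input_hw) / 255.0).astype(np.float32)
    return gray[None, :, :], elast.transpose(2, 0, 1)


def augment_pair(
    gray: np.ndarray, elast: np.ndarray, flip_p: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Random horizontal/vertical flips, identical across the two modalities.

    Each axis flips independently with probability ``flip_p``.
    """
    if not 0.0 <= flip_p <= 1.0:
        raise ValueError("flip_p must be a probability")
    if rng.random() < flip_p:  # horizontal
        gray, elast = gray[..., ::-1], elast[..., ::-1]
    if rng.random() < flip_p:  # vertical
        gray, elast = gray[..., ::-1, :], elast[..., ::-1, :]
    return np.ascontiguousarray(gray), np.ascontiguousarray(elast)


def _assemble(pairs, labels_by_id, input_hw) -> PairDataset:
    grays, elasts, ys, tids, pidx = [], [], [], [], []
    for pair in pairs:
        g, e = preprocess(pair, input_hw)
        grays.append(g)
        elasts.append(e)
        ys.append(1 if labels_by_id[pair.tumor_id] == "high" else 0)
        tids.append(pair.tumor_id)
        pidx.append(pair.pair_index)
    return PairDataset(
        np.stack(grays),
        np.stack(elasts),
        np.array(ys, dtype=int),
        np.array(tids),
        np.array(pidx, dtype=int),
    )


def dataset_from_cohort(cohort: Cohort, manifest: SplitManifest, split: str, input_hw: int) -> PairDataset:
    """Assemble one split's dataset from an in-memory cohort."""
    keep = {r.tumor_id: r.label for r in manifest.records if r.split == split}
    pairs = [p for p in cohort.pairs if p.tumor_id in keep]
    if not pairs:
        raise ValueError(f"split {split!r} contains no image pairs")
    return _assemble(pairs, keep, input_hw)


def dataset_from_manifest(manifest_df: pd.DataFrame, split: str, input_hw: int) -> PairDataset:
    """Assemble one split's dataset from a labeled CSV manifest on disk.

    Rows with missing image files are excluded with a warning listing them.
    """
    rows = manifest_df[manifest_df["split"] == split]
    if rows.empty:
        raise ValueError(f"split {split!r} has no manifest rows")
    pairs = []
    labels = {}
    missing = []
    for _, row in rows.iterrows():
        gpath, epath = Path(row["grayscale_path"]), Path(row["elastography_path"])
        if not gpath.exists() or not epath.exists():
            missing.append(row["tumor_id"])
            continue
        gray = np.asarray(Image.open(gpath).convert("L"))
        elast = np.asarray(Image.open(epath).convert("RGB"))
        pairs.append(
            ImagePair(grayscale=gray, elastography=elast, tumor_id=row["tumor_id"], pair_index=int(row["pair_index"]))
        )
        labels[row["tumor_id"]] = row["label"]
    if missing:
        import warnings

        warnings.warn(f"excluded {len(missing)} rows with missing images: {sorted(set(missing))}", stacklevel=2)
    if not pairs:
        raise ValueError(f"split {split!r} has no readable image pairs")
    return _assemble(pairs, labels, input_hw)
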