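"""Threshold-based labeling and tumor-grouped train/val/test splitting.

Tumors are labeled ``high`` when their VTN fraction strictly exceeds the
cohort threshold (mean or median of all per-tumor fractions) and ``low``
otherwise; ties at the threshold go to ``low``.  Splitting is done at the
tumor level so that a tumor's image pairs never straddle splits, with
largest-remainder rounding of the 3:1:1 ratios and optional stratification
by label.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import TumorRecord

__all__ = [
    "LabelingConfig",
    "SplitManifest",
    "compute_threshold",
    "assign_labels",
    "split_cohort",
    "largest_remainder",
    "apply_to_manifest",
]

SPLITS = ("train", "val", "test")


@dataclass(frozen=True)
class LabelingConfig:
    threshold_method: str = "median"  # {"mean", "median"}
    split_ratios: tuple[float, float, float] = (3.0, 1.0, 1.0)
    stratify: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.threshold_method not in ("mean", "median"):
            raise ValueError(f"unknown threshold_method {self.threshold_method!r}")
        if len(self.split_ratios) != 3 or any(r <= 0 for r in self.split_ratios):
            raise ValueError("split_ratios must be three positive numbers")


@dataclass
class SplitManifest:
    records: list[TumorRecord]
    threshold_value: float

    def counts(self) -> dict[str, dict[str, int]]:
        out: dict[str, dict[str, int]] = {s: {"high": 0, "low": 0} for s in SPLITS}
        for r in self.records:
            out[r.split][r.label] += 1
        return out

    def of_split(self, split: str) -> list[TumorRecord]:
        return [r for r in self.records if r.split == split]


def compute_threshold(values, method: str = "median") -> float:
    """Cohort labeling threshold: arithmetic mean or sample median.

    Even-length median is the midpoint of the two central order statistics.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot compute a threshold from an empty value list")
    if not np.all(np.isfinite(arr)):
        raise ValueError("threshold values must all be finite")
    if method == "mean":
        return float(arr.mean())
    if method == "median":
        return float(np.median(arr))
    raise ValueError(f"unknown threshold method {method!r}")


def assign_labels(records: list[TumorRecord], threshold: float) -> dict[str, int]:
    """Label each record in place: high iff vtn_fraction > threshold.

    Returns the class counts.  The boundary convention sends exact ties to
    ``low`` ("exceeding the threshold" means strictly greater).
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    counts = {"high": 0, "low": 0}
    for r in records:
        if r.vtn_fraction is None or not np.isfinite(r.vtn_fraction):
            raise ValueError(f"tumor {r.tumor_id} has no valid vtn_fraction")
        r.label = "high" if r.vtn_fraction > threshold else "low"
        counts[r.label] += 1
    return counts


def largest_remainder(n: int, ratios) -> list[int]:
    """Apportion ``n`` units to parts proportional to ``ratios``.

    Floors the exact quotas, then hands remaining units to the largest
    fractional parts; ties resolve in ratio order (train before val before
    test at the default ratios).
    """
    ratios = np.asarray(ratios, dtype=float)
    quotas = n * ratios / ratios.sum()
    base = np.floor(quotas).astype(int)
    rem = n - base.sum()
    if rem > 0:
        frac = quotas - base
        order = np.argsort(-frac, kind="stable")
        for i in order[:rem]:
            base[i] += 1
    return base.tolist()


def split_cohort(records: list[TumorRecord], config: LabelingConfig) -> SplitManifest:
    """Assign tumors (not images) to train/val/test.

    With ``stratify`` set, per-class quotas are floored and the remainders
    distributed by largest fractional part, constrained so the overall split
    sizes still equal the cohort-level largest-remainder apportionment:
    splits keep their exact global sizes while each stays class-balanced to
    within one tumor.  Reproducible for a fixed seed.
    """
    config.validate()
    if len(records) < 5:
        raise ValueError("need at least 5 tumors to split 3:1:1")
    labels = {r.label for r in records}
    if labels - {"high", "low"}:
        raise ValueError("all records must be labeled before splitting")
    if len(labels) < 2:
        raise ValueError("both classes must be present before splitting")
    rng = np.random.default_rng(config.seed)
    ratios = np.asarray(config.split_ratios, dtype=float)
    ratios = ratios / ratios.sum()

    def assign(group: list[TumorRecord], sizes: list[int]) -> None:
        idx = rng.permutation(len(group))
        bounds = np.cumsum([0] + list(sizes))
        for s, name in enumerate(SPLITS):
            for i in idx[bounds[s] : bounds[s + 1]]:
                group[i].split = name

    if config.stratify:
        global_sizes = largest_remainder(len(records), config.split_ratios)
        classes = ["high", "low"]
        groups = {c: [r for r in records if r.label == c] for c in classes}
        base = {c: np.floor(len(groups[c]) * ratios).astype(int) for c in classes}
        deficit = np.array(global_sizes) - sum(base.values())
        remaining = {c: len(groups[c]) - base[c].sum() for c in classes}
        # hand out per-class remainders by largest fractional part, without
        # overrunning any split's global size
        cells = sorted(
            ((c, s) for c in classes for s in range(3)),
            key=lambda cs: -(len(groups[cs[0]]) * ratios[cs[1]] - base[cs[0]][cs[1]]),
        )
        for c, s in cells:
            if remaining[c] > 0 and deficit[s] > 0:
                base[c][s] += 1
                remaining[c] -= 1
                deficit[s] -= 1
        for c in classes:  # safety net: any unplaced tumor goes where room remains
            while remaining[c] > 0:
                s = int(np.argmax(deficit))
                base[c][s] += 1
                remaining[c] -= 1
                deficit[s] -= 1
        for c in classes:
            assign(groups[c], base[c].tolist())
    else:
        assign(list(records), largest_remainder(len(records), config.split_ratios))

    manifest = SplitManifest(records=list(records), threshold_value=float("nan"))
    for split, cc in manifest.counts().items():
        if min(cc.values()) == 0:
            warnings.warn(
                f"split {split!r} is missing a class (counts {cc}); downstream "
                "metrics on that split may be undefined",
                stacklevel=2,
            )
    return manifest


def label_and_split(records: list[TumorRecord], config: LabelingConfig) -> SplitManifest:
    """Convenience: threshold -> labels -> split, returning the full manifest."""
    threshold = compute_threshold([r.vtn_fraction for r in records], config.threshold_method)
    assign_labels(records, threshold)
    manifest = split_cohort(records, config)
    manifest.threshold_value = threshold
    return manifest


def apply_to_manifest(
    manifest_df: pd.DataFrame, split: SplitManifest, sidecar_path: str | Path | None = None
) -> pd.DataFrame:
    """Join label/split columns onto the per-image CSV manifest.

    Optionally writes a JSON sidecar with the threshold and class counts.
    """
    by_id = {r.tumor_id: r for r in split.records}
    out = manifest_df.copy()
    out["label"] = out["tumor_id"].map(lambda t: by_id[t].label)
    out["split"] = out["tumor_id"].map(lambda t: by_id[t].split)
    if sidecar_path is not None:
        payload = {"threshold_value": split.threshold_value, "counts": split.counts()}
        Path(sidecar_path).write_text(json.dumps(payload, indent=2))
    return out
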