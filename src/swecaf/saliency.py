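"""Grad-CAM saliency over each modality branch.

Because the two branches fuse only after flattening, a joint map is
ill-defined; a map is computed per modality at the last convolutional
feature map of that branch (the final ReLU output before the last
max-pool).  Channel weights are the spatial means of the target-class
logit's gradients at that layer; the map is the rectified weighted sum of
activation channels, bilinearly upsampled to input resolution and
normalized to a maximum of 1 (identically-zero maps are flagged instead).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .model import BimodalNet
from .synthetic import stiffness_to_rgb

__all__ = ["SaliencyMap", "gradcam", "cam_from_activations", "overlay"]

CLASS_INDEX = {"low": 0, "high": 1}


@dataclass
class SaliencyMap:
    heatmap: np.ndarray  # (H, W) in [0, 1] at input resolution
    modality: str  # {"grayscale", "elastography"}
    target_class: str  # {"high", "low"}
    is_zero: bool = False  # gradients vanished everywhere


def _bilinear_resize(arr: np.ndarray, hw: int) -> np.ndarray:
    if arr.shape == (hw, hw):
        return arr
    img = Image.fromarray(arr.astype(np.float32), mode="F")
    return np.asarray(img.resize((hw, hw), Image.BILINEAR), dtype=np.float64)


def cam_from_activations(activations: np.ndarray, gradients: np.ndarray) -> np.ndarray:
    """Core Grad-CAM combination: rectified, gradient-weighted channel sum.

    ``activations`` and ``gradients`` are ``(C, h, w)`` arrays at the target
    layer; the channel weights are the spatial means of the gradients.  Not
    normalized or resized here.
    """
    if activations.shape != gradients.shape:
        raise ValueError("activations and gradients must share a shape")
    weights = gradients.mean(axis=(1, 2))
    return np.maximum((weights[:, None, None] * activations).sum(axis=0), 0.0)


def gradcam(
    model: BimodalNet,
    grayscale: np.ndarray | None,
    elastography: np.ndarray | None,
    target_class: str,
    modality: str,
) -> SaliencyMap:
    """Gradient-weighted class-activation map for one image pair.

    Inputs are single preprocessed pairs shaped ``(C, H, W)``; the target
    layer is the last ReLU of the chosen branch.
    """
    if modality not in model.branches:
        raise ValueError(f"model (mode {model.mode!r}) has no {modality!r} branch")
    if target_class not in CLASS_INDEX:
        raise ValueError(f"target_class must be 'high' or 'low', got {target_class!r}")
    gray = grayscale[None] if grayscale is not None else None
    elast = elastography[None] if elastography is not None else None
    kwargs = {}
    if "grayscale" in model.branches:
        kwargs["grayscale"] = gray
    if "elastography" in model.branches:
        kwargs["elastography"] = elast
    out = model.forward(**kwargs, train=False)

    dlogits = np.zeros_like(out.logits)
    dlogits[0, CLASS_INDEX[target_class]] = 1.0
    gfused = model.head.backward(dlogits)
    offset = 0
    gslice = None
    for name, flen in zip(model.branch_order, model._feature_lens):
        if name == modality:
            gslice = gfused[:, offset : offset + flen]
            break
        offset += flen
    branch = model.branches[modality]
    relu_idx = 4 * model.spec.n_blocks - 2  # last ReLU: blocks are [conv, bn, relu, pool]
    gact = branch.backward_from(gslice, start=relu_idx + 1)
    activations = branch.activation(relu_idx)  # (1, C, h, w)

    cam = cam_from_activations(activations[0], gact[0])
    cam = _bilinear_resize(cam, model.spec.input_hw)
    peak = cam.max()
    if peak <= 0.0:
        return SaliencyMap(heatmap=np.zeros_like(cam), modality=modality, target_class=target_class, is_zero=True)
    return SaliencyMap(heatmap=cam / peak, modality=modality, target_class=target_class)


def overlay(
    smap: SaliencyMap, image: np.ndarray, alpha: float = 0.5, out_path: str | Path | None = None
) -> np.ndarray:
    """Alpha-blend the heatmap (through the package colormap) onto an image.

    The per-pixel blend weight is ``alpha * heatmap``, so a zero map
    returns the base image unchanged and ``alpha=1`` paints the hottest
    pixel with the pure colormap color.  Deterministic.
    """
    base = np.asarray(image)
    if base.ndim == 2:
        base = np.repeat(base[:, :, None], 3, axis=2)
    if base.shape[:2] != smap.heatmap.shape:
        raise ValueError(f"image shape {base.shape[:2]} does not match heatmap {smap.heatmap.shape}")
    heat_rgb = stiffness_to_rgb(smap.heatmap * 100.0).astype(np.float64)
    w = (alpha * smap.heatmap)[:, :, None]
    blended = ((1.0 - w) * base.astype(np.float64) + w * heat_rgb).round().clip(0, 255).astype(np.uint8)
    if out_path is not None:
        Image.fromarray(blended, mode="RGB").save(out_path)
    return blended
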