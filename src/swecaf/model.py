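"""Two-branch convolutional fusion classifier.

Each modality (grayscale B-mode, color elastography) runs through its own
feature extractor — structurally identical stacks of
conv(3x3, stride 1, pad 1) -> batch-norm -> ReLU -> 2x2 max-pool blocks
ending in 7x7 adaptive average pooling — with independent parameters.
The flattened features are concatenated and classified by a three-layer
head (linear 256 -> ReLU -> dropout 0.2 -> linear 64 -> ReLU -> dropout 0.2
-> linear 2) producing two logits; the softmax probability of the ``high``
class is the model's p.

Unimodal variants (grayscale-only / elastography-only) keep one branch and
halve the head's input width; they are strict sub-models used for ablation.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn

__all__ = ["ModelSpec", "ModelOutput", "BimodalNet", "build_model", "save_checkpoint", "load_checkpoint"]

MODES = ("bimodal", "grayscale_only", "elastography_only")


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyperparameters.

    Defaults give four blocks at widths 16/32/64/128 so a 224x224 input is
    reduced to 14x14 before the 7x7 adaptive pool; desk-scale runs use two
    blocks [8, 16] on 64x64 inputs.
    """

    n_blocks: int = 4
    channels: tuple[int, ...] = (16, 32, 64, 128)
    adaptive_pool_hw: int = 7
    classifier_sizes: tuple[int, int, int] = (256, 64, 2)
    dropout_p: float = 0.2
    input_hw: int = 224
    grayscale_channels: int = 1
    elastography_channels: int = 3

    def validate(self) -> None:
        if len(self.channels) != self.n_blocks:
            raise ValueError("len(channels) must equal n_blocks")
        if any(c < 1 for c in self.channels):
            raise ValueError("all channel widths must be >= 1")
        if self.classifier_sizes[-1] != 2:
            raise ValueError("the classifier must end in two logits")
        if self.input_hw // (2**self.n_blocks) < self.adaptive_pool_hw:
            raise ValueError(
                f"input {self.input_hw} too small for {self.n_blocks} blocks "
                f"before a {self.adaptive_pool_hw}x{self.adaptive_pool_hw} adaptive pool"
            )

    @property
    def branch_feature_len(self) -> int:
        return self.channels[-1] * self.adaptive_pool_hw**2


@dataclass
class ModelOutput:
    logits: np.ndarray  # (N, 2)
    prob_high: np.ndarray  # (N,)


def _make_branch(spec: ModelSpec, in_channels: int, rng: np.random.Generator) -> nn.Sequential:
    layers: list[nn.Layer] = []
    c_in = in_channels
    for c_out in spec.channels:
        layers += [nn.Conv2d(c_in, c_out, rng), nn.BatchNorm2d(c_out), nn.ReLU(), nn.MaxPool2d()]
        c_in = c_out
    layers.append(nn.AdaptiveAvgPool2d(spec.adaptive_pool_hw))
    layers.append(nn.Flatten())
    return nn.Sequential(layers)


def _make_head(spec: ModelSpec, in_features: int, rng: np.random.Generator) -> nn.Sequential:
    h1, h2, out = spec.classifier_sizes
    return nn.Sequential(
        [
            nn.Linear(in_features, h1, rng),
            nn.ReLU(),
            nn.Dropout(spec.dropout_p),
            nn.Linear(h1, h2, rng),
            nn.ReLU(),
            nn.Dropout(spec.dropout_p),
            nn.Linear(h2, out, rng),
        ]
    )


class BimodalNet:
    """Fusion classifier over co-registered B-mode / elastography pairs.

    ``mode`` selects which branches exist; forward takes whichever inputs
    the mode requires and ignores ``None`` for the other.
    """

    def __init__(self, spec: ModelSpec, mode: str = "bimodal", seed: int = 0):
        spec.validate()
        if mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
        self.spec = spec
        self.mode = mode
        rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
        self.branches: dict[str, nn.Sequential] = {}
        if mode in ("bimodal", "grayscale_only"):
            self.branches["grayscale"] = _make_branch(spec, spec.grayscale_channels, rng)
        if mode in ("bimodal", "elastography_only"):
            self.branches["elastography"] = _make_branch(spec, spec.elastography_channels, rng)
        head_in = spec.branch_feature_len * len(self.branches)
        self.head = _make_head(spec, head_in, rng)
        self._feature_lens: list[int] | None = None

    # -- plumbing ----------------------------------------------------------

    @property
    def branch_order(self) -> list[str]:
        order = []
        if "grayscale" in self.branches:
            order.append("grayscale")
        if "elastography" in self.branches:
            order.append("elastography")
        return order

    def modules(self):
        for name in self.branch_order:
            yield self.branches[name]
        yield self.head

    def parameters(self):
        for module in self.modules():
            yield from module.parameters()

    def n_parameters(self) -> int:
        return sum(layer.params[name].size for layer, name in self.parameters())

    def set_dropout_rng(self, rng: np.random.Generator) -> None:
        for module in self.modules():
            for layer in module.layers:
                if isinstance(layer, nn.Dropout):
                    layer.rng = rng

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for m_idx, module in enumerate(self.modules()):
            for l_idx, layer in enumerate(module.layers):
                for pname, value in layer.params.items():
                    state[f"m{m_idx}.l{l_idx}.{pname}"] = value.copy()
                if isinstance(layer, nn.BatchNorm2d):
                    state[f"m{m_idx}.l{l_idx}.running_mean"] = layer.running_mean.copy()
                    state[f"m{m_idx}.l{l_idx}.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for m_idx, module in enumerate(self.modules()):
            for l_idx, layer in enumerate(module.layers):
                for pname in layer.params:
                    layer.params[pname][...] = state[f"m{m_idx}.l{l_idx}.{pname}"]
                if isinstance(layer, nn.BatchNorm2d):
                    layer.running_mean[...] = state[f"m{m_idx}.l{l_idx}.running_mean"]
                    layer.running_var[...] = state[f"m{m_idx}.l{l_idx}.running_var"]

    # -- forward / backward ------------------------------------------------

    def _check_input(self, name: str, x: np.ndarray | None, channels: int) -> np.ndarray:
        if x is None:
            raise ValueError(f"mode {self.mode!r} requires a {name} input")
        if x.ndim != 4 or x.shape[1] != channels or x.shape[2:] != (self.spec.input_hw, self.spec.input_hw):
            raise ValueError(
                f"{name} input must have shape (N, {channels}, {self.spec.input_hw}, "
                f"{self.spec.input_hw}); got {x.shape}"
            )
        return x

    def forward(
        self,
        grayscale: np.ndarray | None = None,
        elastography: np.ndarray | None = None,
        train: bool = False,
    ) -> ModelOutput:
        feats = []
        lens = []
        inputs = {"grayscale": grayscale, "elastography": elastography}
        chans = {
            "grayscale": self.spec.grayscale_channels,
            "elastography": self.spec.elastography_channels,
        }
        for name in self.branch_order:
            x = self._check_input(name, inputs[name], chans[name])
            f = self.branches[name].forward(x, train=train)
            feats.append(f)
            lens.append(f.shape[1])
        fused = np.concatenate(feats, axis=1) if len(feats) > 1 else feats[0]
        self._feature_lens = lens
        logits = self.head.forward(fused, train=train)
        return ModelOutput(logits=logits, prob_high=nn.softmax(logits)[:, 1])

    def backward(self, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        """Backprop through head and branches; returns input gradients."""
        gfused = self.head.backward(dlogits)
        grads = {}
        offset = 0
        for name, flen in zip(self.branch_order, self._feature_lens):
            grads[name] = self.branches[name].backward(gfused[:, offset : offset + flen])
            offset += flen
        return grads

    def copy_params(self) -> dict[str, np.ndarray]:
        return copy.deepcopy(self.state_dict())


def build_model(spec: ModelSpec, mode: str = "bimodal", seed: int = 0) -> BimodalNet:
    """Construct the fusion classifier (or a unimodal ablation arm)."""
    return BimodalNet(spec, mode=mode, seed=seed)


# ---------------------------------------------------------------------------
# checkpointing: parameters as .npz, the spec as a JSON sidecar


def save_checkpoint(model: BimodalNet, path: str | Path) -> None:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())
    header = {"spec": asdict(model.spec), "mode": model.mode}
    path.with_suffix(".json").write_text(json.dumps(header, indent=2))


def load_checkpoint(path: str | Path) -> BimodalNet:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    header = json.loads(path.with_suffix(".json").read_text())
    spec_d = header["spec"]
    spec_d["channels"] = tuple(spec_d["channels"])
    spec_d["classifier_sizes"] = tuple(spec_d["classifier_sizes"])
    model = BimodalNet(ModelSpec(**spec_d), mode=header["mode"])
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
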