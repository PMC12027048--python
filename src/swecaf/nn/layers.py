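"""Minimal NumPy neural-network layers with explicit forward/backward passes.

Every layer caches what its backward pass needs during ``forward`` and
releases the gradient of its input from ``backward``.  Parameters and their
gradients live in parallel dicts so an optimizer can walk them generically.

Conventions: activations and parameters are ``float32`` (``DTYPE``) arrays
shaped ``(N, C, H, W)`` for convolutional layers and ``(N, F)`` for linear
layers; float32 keeps desk-scale training fast without hurting stability at
these network sizes.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

#: working precision of the engine
DTYPE = np.float32


class Layer:
    """Base class: stateless by default, no parameters."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    """3x3 convolution, stride 1, padding 1 (spatial size preserved).

    Implemented as im2col + one matrix multiply; the backward pass scatters
    column gradients back with a 9-step loop over kernel offsets.
    """

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        fan_in = in_channels * 9
        # He initialization: suits the ReLU blocks this layer sits in.
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_channels, in_channels, 3, 3)).astype(DTYPE)
        self.params = {"w": w, "b": np.zeros(out_channels, dtype=DTYPE)}
        self.grads = {"w": np.zeros_like(w), "b": np.zeros(out_channels, dtype=DTYPE)}
        self._cache = None

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(f"Conv2d expected {self.in_channels} input channels, got {c}")
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (N, C, H, W, 3, 3)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * w, c * 9)
        wmat = self.params["w"].reshape(self.out_channels, c * 9)
        out = cols @ wmat.T + self.params["b"]
        out = out.reshape(n, h, w, self.out_channels).transpose(0, 3, 1, 2)
        self._cache = (cols, x.shape)
        return out

    def backward(self, gout):
        cols, (n, c, h, w) = self._cache
        gmat = gout.transpose(0, 2, 3, 1).reshape(n, h * w, self.out_channels)
        self.grads["w"][...] = np.tensordot(gmat, cols, axes=([0, 1], [0, 1])).reshape(
            self.params["w"].shape
        )
        self.grads["b"][...] = gout.sum(axis=(0, 2, 3))
        wmat = self.params["w"].reshape(self.out_channels, c * 9)
        gcols = (gmat @ wmat).reshape(n, h, w, c, 3, 3)
        gxp = np.zeros((n, c, h + 2, w + 2), dtype=gout.dtype)
        for i in range(3):
            for j in range(3):
                gxp[:, :, i : i + h, j : j + w] += gcols[..., i, j].transpose(0, 3, 1, 2)
        return gxp[:, :, 1 : 1 + h, 1 : 1 + w]


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics for inference."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.params = {"gamma": np.ones(channels, dtype=DTYPE), "beta": np.zeros(channels, dtype=DTYPE)}
        self.grads = {"gamma": np.zeros(channels, dtype=DTYPE), "beta": np.zeros(channels, dtype=DTYPE)}
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self._cache = None

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean
            self.running_var = (1 - m) * self.running_var + m * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std, train, x.shape)
        return self.params["gamma"][None, :, None, None] * xhat + self.params["beta"][None, :, None, None]

    def backward(self, gout):
        xhat, inv_std, train, shape = self._cache
        self.grads["gamma"][...] = (gout * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"][...] = gout.sum(axis=(0, 2, 3))
        g = self.params["gamma"][None, :, None, None]
        if not train:
            return gout * g * inv_std[None, :, None, None]
        n = shape[0] * shape[2] * shape[3]
        gxhat = gout * g
        # standard batch-norm backward through the batch statistics
        gx = (
            gxhat
            - gxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (gxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) * inv_std[None, :, None, None]
        return gx


class ReLU(Layer):
    def __init__(self):
        super().__init__()
        self._mask = None

    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gout):
        return gout * self._mask


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2. Odd trailing rows/columns are dropped.

    Gradient is split evenly among tied maxima within a window, which keeps
    the operator's numerical Jacobian well defined on plateaued inputs.
    """

    def __init__(self):
        super().__init__()
        self._cache = None

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        xc = x[:, :, : 2 * h2, : 2 * w2]
        x6 = xc.reshape(n, c, h2, 2, w2, 2)
        out = x6.max(axis=(3, 5))
        mask = x6 == out[:, :, :, None, :, None]
        mask = mask / mask.sum(axis=(3, 5), keepdims=True)
        self._cache = (mask, x.shape)
        return out

    def backward(self, gout):
        mask, (n, c, h, w) = self._cache
        gx6 = mask * gout[:, :, :, None, :, None]
        h2, w2 = h // 2, w // 2
        gx = np.zeros((n, c, h, w), dtype=gout.dtype)
        gx[:, :, : 2 * h2, : 2 * w2] = gx6.reshape(n, c, 2 * h2, 2 * w2)
        return gx


class AdaptiveAvgPool2d(Layer):
    """Average pooling onto a fixed output grid (default 7x7).

    Bin ``i`` of an axis of length ``h`` covers input rows
    ``[floor(i*h/out), ceil((i+1)*h/out))`` — overlapping bins when ``h`` is
    not a multiple of ``out``, matching the usual adaptive-pool convention.
    """

    def __init__(self, out_hw: int = 7):
        super().__init__()
        self.out_hw = out_hw
        self._cache = None

    @staticmethod
    def _bins(size: int, out: int) -> list[tuple[int, int]]:
        return [(int(np.floor(i * size / out)), int(np.ceil((i + 1) * size / out))) for i in range(out)]

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        o = self.out_hw
        if h < o or w < o:
            raise ValueError(f"AdaptiveAvgPool2d({o}) needs input at least {o}x{o}, got {h}x{w}")
        rb, cb = self._bins(h, o), self._bins(w, o)
        out = np.empty((n, c, o, o), dtype=x.dtype)
        for i, (r0, r1) in enumerate(rb):
            for j, (c0, c1) in enumerate(cb):
                out[:, :, i, j] = x[:, :, r0:r1, c0:c1].mean(axis=(2, 3))
        self._cache = (rb, cb, x.shape)
        return out

    def backward(self, gout):
        rb, cb, shape = self._cache
        gx = np.zeros(shape, dtype=gout.dtype)
        for i, (r0, r1) in enumerate(rb):
            for j, (c0, c1) in enumerate(cb):
                area = (r1 - r0) * (c1 - c0)
                gx[:, :, r0:r1, c0:c1] += gout[:, :, i, j, None, None] / area
        return gx


class Flatten(Layer):
    def __init__(self):
        super().__init__()
        self._shape = None

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gout):
        return gout.reshape(self._shape)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        w = rng.normal(0.0, np.sqrt(2.0 / in_features), size=(out_features, in_features)).astype(DTYPE)
        self.params = {"w": w, "b": np.zeros(out_features, dtype=DTYPE)}
        self.grads = {"w": np.zeros_like(w), "b": np.zeros(out_features, dtype=DTYPE)}
        self._x = None

    def forward(self, x, train=False):
        self._x = x
        return x @ self.params["w"].T + self.params["b"]

    def backward(self, gout):
        self.grads["w"][...] = gout.T @ self._x
        self.grads["b"][...] = gout.sum(axis=0)
        return gout @ self.params["w"]


class Dropout(Layer):
    """Inverted dropout; identity in inference mode.

    The mask is drawn from ``self.rng``, which the training loop re-seeds so
    runs are reproducible.
    """

    def __init__(self, p: float):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0,1), got {p}")
        self.p = p
        self.rng = np.random.default_rng(0)
        self._mask = None

    def forward(self, x, train=False):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = ((self.rng.random(x.shape) >= self.p) / (1.0 - self.p)).astype(x.dtype)
        return x * self._mask

    def backward(self, gout):
        if self._mask is None:
            return gout
        return gout * self._mask


class Sequential(Layer):
    """Ordered layer container supporting full and suffix-only backprop."""

    def __init__(self, layers: list[Layer]):
        super().__init__()
        self.layers = layers
        self._acts: list[np.ndarray] | None = None

    def forward(self, x, train=False):
        acts = []
        for layer in self.layers:
            x = layer.forward(x, train=train)
            acts.append(x)
        self._acts = acts
        return x

    def backward(self, gout):
        for layer in reversed(self.layers):
            gout = layer.backward(gout)
        return gout

    def backward_from(self, gout: np.ndarray, start: int) -> np.ndarray:
        """Backprop ``gout`` only through layers ``start..end``, returning the
        gradient at the output of layer ``start - 1`` (used by Grad-CAM)."""
        for layer in reversed(self.layers[start:]):
            gout = layer.backward(gout)
        return gout

    def activation(self, index: int) -> np.ndarray:
        if self._acts is None:
            raise RuntimeError("forward must run before activations are available")
        return self._acts[index]

    def parameters(self):
        for layer in self.layers:
            for name in layer.params:
                yield layer, name
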