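"""Momentum stochastic gradient descent over (layer, parameter-name) pairs."""

from __future__ import annotations

import numpy as np


class SGD:
    """Classical momentum update: v <- mu*v + g ; w <- w - lr*v."""

    def __init__(self, param_refs, learning_rate: float, momentum: float = 0.95):
        if learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        self.param_refs = list(param_refs)
        self.lr = learning_rate
        self.momentum = momentum
        self.velocity = [np.zeros_like(layer.params[name]) for layer, name in self.param_refs]

    def step(self) -> None:
        for v, (layer, name) in zip(self.velocity, self.param_refs):
            v *= self.momentum
            v += layer.grads[name]
            layer.params[name] -= self.lr * v

    def zero_grad(self) -> None:
        for layer, name in self.param_refs:
            layer.grads[name][...] = 0.0
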