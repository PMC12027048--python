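"""Loss functions: two-logit softmax cross-entropy and its scalar binary form."""

from __future__ import annotations

import numpy as np

#: probabilities are clamped to [EPS, 1-EPS] before any logarithm
EPS = 1e-7


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def binary_cross_entropy(y, p) -> float:
    """Mean binary cross-entropy  L = -[y log p + (1-y) log(1-p)].

    ``y`` is the true label (0 = low, 1 = high) and ``p`` the predicted
    probability of the high class.  Accepts scalars or arrays; arrays are
    averaged.  Probabilities are clamped by ``EPS`` so perfect predictions
    return exactly 0 after clamping rather than NaN.
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("labels must be 0 or 1")
    pc = np.clip(p, EPS, 1.0 - EPS)
    loss = -(y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc))
    return float(np.mean(loss))


def cross_entropy_with_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over a batch of two-logit rows, plus d(loss)/d(logits).

    With two logits and softmax, the loss reduces to the binary form with
    p = softmax probability of class 1.
    """
    n = logits.shape[0]
    probs = softmax(logits)
    p_true = np.clip(probs[np.arange(n), y], EPS, 1.0)
    loss = float(-np.log(p_true).mean())
    grad = probs.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n
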