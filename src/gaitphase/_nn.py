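"""Minimal numpy neural-network utilities shared by the SDA and the LSTM.

Everything runs in float32 on a single thread of BLAS; with fixed seeds the
training loops are bit-reproducible.
"""

from __future__ import annotations

import numpy as np


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Adam:
    """Adaptive-moment optimizer over a dict of named parameter arrays.

    Update: theta <- theta - lr * m_hat / (sqrt(v_hat) + eps), with
    bias-corrected first/second moment estimates (decays beta1, beta2).
    """

    def __init__(self, params: dict, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        if lr <= 0 or eps <= 0:
            raise ValueError("lr and eps must be positive")
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            m = self.m[k]
            v = self.v[k]
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * np.square(g)
            params[k] -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)


def check_finite(value: float, context: str) -> None:
    if not np.isfinite(value):
        raise RuntimeError(f"non-finite loss during {context}: {value!r}; training aborted")
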