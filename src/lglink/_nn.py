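"""Minimal numpy neural-net plumbing shared by the two graph models.

The models here are small dense-matrix networks, so parameters live in a
plain dict of arrays, gradients are hand-derived, and Adam does the
updates.  Everything is seeded through numpy Generators for bitwise
reproducibility.
"""

from __future__ import annotations

import numpy as np

__all__ = ["glorot", "Adam", "relu", "drelu"]


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def drelu(pre: np.ndarray) -> np.ndarray:
    return (pre > 0).astype(pre.dtype)


class Adam:
    """Adam optimizer over a dict of named parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            m_hat = self.m[k] / (1 - b1**self.t)
            v_hat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
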