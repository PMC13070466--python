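"""Minimal Adam optimizer (adaptive moment estimation) on flat vectors."""
from __future__ import annotations

import numpy as np


class Adam:
    def __init__(self, n: int, lr: float = 1e-2, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = np.zeros(n)
        self.v = np.zeros(n)
        self.t = 0

    def step(self, grad: np.ndarray) -> np.ndarray:
        """Return the parameter update (to be *added*) for this gradient."""
        self.t += 1
        self.m = self.beta1 * self.m + (1 - self.beta1) * grad
        self.v = self.beta2 * self.v + (1 - self.beta2) * grad**2
        mhat = self.m / (1 - self.beta1**self.t)
        vhat = self.v / (1 - self.beta2**self.t)
        return -self.lr * mhat / (np.sqrt(vhat) + self.eps)


def clip_norm(grad: np.ndarray, max_norm: float) -> np.ndarray:
    norm = float(np.linalg.norm(grad))
    if norm > max_norm > 0:
        return grad * (max_norm / norm)
    return grad
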