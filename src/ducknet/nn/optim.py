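"""RMS-propagation optimizer (centered=False, Keras-style update)."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["RMSprop"]


class RMSprop:
    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 rho: float = 0.9, eps: float = 1e-7):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = list(params)
        self.lr = lr
        self.rho = rho
        self.eps = eps
        self._acc = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, acc in zip(self.params, self._acc):
            if p.grad is None:
                continue
            g = p.grad
            acc *= self.rho
            acc += (1.0 - self.rho) * g * g
            p.data -= self.lr * g / (np.sqrt(acc) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
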