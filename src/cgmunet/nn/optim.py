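"""Optimizers for the autodiff engine."""

from __future__ import annotations

import math

import numpy as np

from .tensor import Parameter

__all__ = ["Adam", "cosine_lr"]


class Adam:
    """Adam with bias correction (Kingma & Ba); no weight decay by default."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float64, copy=False)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            upd = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p.data = (p.data - self.lr * upd).astype(p.data.dtype)


def cosine_lr(base_lr: float, step: int, total_steps: int,
              min_frac: float = 0.01) -> float:
    """Cosine decay from ``base_lr`` to ``min_frac * base_lr``."""
    if total_steps <= 1:
        return base_lr
    frac = min(step, total_steps - 1) / (total_steps - 1)
    return base_lr * (min_frac + (1 - min_frac) * 0.5 * (1 + math.cos(math.pi * frac)))
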