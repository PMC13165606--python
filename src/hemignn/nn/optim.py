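"""Adam optimizer and the cosine-annealing learning-rate schedule."""

from __future__ import annotations

import numpy as np

from .layers import Parameter

__all__ = ["Adam", "CosineAnnealingLR"]


class Adam:
    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        b1, b2 = self.betas
        self.t += 1
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p.data = p.data - self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class CosineAnnealingLR:
    """lr(e) = eta_min + (lr0 - eta_min) * (1 + cos(pi * e / T_max)) / 2."""

    def __init__(self, optimizer: Adam, t_max: int, eta_min: float = 1e-6):
        self.optimizer = optimizer
        self.t_max = t_max
        self.eta_min = eta_min
        self.base_lr = optimizer.lr
        self.epoch = 0

    def step(self) -> None:
        """Advance one epoch and update the optimizer's learning rate."""
        self.epoch += 1
        e = min(self.epoch, self.t_max)
        self.optimizer.lr = self.eta_min + (self.base_lr - self.eta_min) * (
            1.0 + np.cos(np.pi * e / self.t_max)
        ) / 2.0
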