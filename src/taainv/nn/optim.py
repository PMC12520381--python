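"""Adam optimizer and learning-rate schedules."""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor

__all__ = ["Adam", "make_schedule"]


def make_schedule(name: str, n_updates: int, gamma: float = 0.999):
    """Return a multiplier function step -> lr factor.

    ``constant``, ``cosine`` (annealing to 0 over the budget) or
    ``exponential`` (decay by ``gamma`` per step, normalized so the decay
    spans about three decades over the budget when gamma is left default).
    """
    if name == "constant":
        return lambda step: 1.0
    if name == "cosine":
        return lambda step: 0.5 * (1.0 + math.cos(math.pi * min(step, n_updates)
                                                  / max(n_updates, 1)))
    if name == "exponential":
        return lambda step: gamma ** step
    raise ValueError(f"unknown schedule {name!r}")


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, schedule=None):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.schedule = schedule or (lambda step: 1.0)
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        lr = self.lr * self.schedule(self.t - 1)
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
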