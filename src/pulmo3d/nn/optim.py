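"""Stochastic gradient descent with momentum and decoupled-style weight decay."""

from __future__ import annotations

import numpy as np


class SGD:
    def __init__(self, params, lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        for p, v in zip(self.params, self._velocity):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v -= self.lr * g
            p.data += v


class StepSchedule:
    """Multiply the learning rate by ``gamma`` at each listed epoch."""

    def __init__(self, base_lr: float, milestones, gamma: float):
        self.base_lr = base_lr
        self.milestones = sorted(milestones)
        self.gamma = gamma

    def lr_at(self, epoch: int) -> float:
        k = sum(1 for m in self.milestones if epoch >= m)
        return self.base_lr * (self.gamma ** k)
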