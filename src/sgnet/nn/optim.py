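"""Optimisers and learning-rate schedules."""

from __future__ import annotations

import numpy as np

from .layers import Parameter


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-2):
        self.params: list[Parameter] = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            if self.weight_decay:
                p.data = p.data * (1 - self.lr * self.weight_decay)
            p.data = p.data - self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class CosineAnnealingLR:
    """Cosine decay of the optimiser learning rate over ``t_max`` steps."""

    def __init__(self, optimizer: AdamW, t_max: int, eta_min: float = 1e-6):
        self.optimizer = optimizer
        self.base_lr = optimizer.lr
        self.t_max = max(1, int(t_max))
        self.eta_min = eta_min
        self.epoch = 0

    def step(self):
        self.epoch += 1
        frac = min(self.epoch, self.t_max) / self.t_max
        self.optimizer.lr = self.eta_min + 0.5 * (self.base_lr - self.eta_min) \
            * (1 + np.cos(np.pi * frac))
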