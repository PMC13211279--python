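"""Adam optimizer and reduce-on-plateau learning-rate schedule."""

from __future__ import annotations

import numpy as np


class Adam:
    def __init__(self, params, lr: float = 0.002, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad**2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class ReduceLROnPlateau:
    """Halve the learning rate when the monitored loss stops improving."""

    def __init__(self, optimizer: Adam, factor: float = 0.5, patience: int = 10,
                 min_lr: float = 1e-6):
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.best = np.inf
        self.num_bad = 0

    def step(self, metric: float) -> bool:
        """Feed one validation-loss value; returns True if the lr was reduced."""
        if metric < self.best - 1e-12:
            self.best = metric
            self.num_bad = 0
            return False
        self.num_bad += 1
        if self.num_bad > self.patience - 1:
            new_lr = max(self.optimizer.lr * self.factor, self.min_lr)
            reduced = new_lr < self.optimizer.lr
            self.optimizer.lr = new_lr
            self.num_bad = 0
            return reduced
        return False
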