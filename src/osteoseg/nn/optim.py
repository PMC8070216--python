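"""Optimizers and the validation-plateau learning-rate schedule."""

from __future__ import annotations

import numpy as np

__all__ = ["SGD", "Adam", "ReduceLROnPlateau"]


class SGD:
    """Plain stochastic gradient descent with optional momentum."""

    def __init__(self, params, lr: float = 0.0004, momentum: float = 0.9):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self._vel = [np.zeros_like(p.v) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self._vel):
            v *= self.momentum
            v -= self.lr * p.g
            p.v += v

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()


class Adam:
    """Adam with the standard bias correction (beta1=0.9, beta2=0.999)."""

    def __init__(self, params, lr: float = 0.001, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self._m = [np.zeros_like(p.v) for p in self.params]
        self._v = [np.zeros_like(p.v) for p in self.params]
        self._t = 0

    def step(self):
        self._t += 1
        b1c = 1.0 - self.beta1**self._t
        b2c = 1.0 - self.beta2**self._t
        for p, m, v in zip(self.params, self._m, self._v):
            m += (1 - self.beta1) * (p.g - m)
            v += (1 - self.beta2) * (p.g * p.g - v)
            p.v -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()


class ReduceLROnPlateau:
    """Halve (by `factor`) the optimizer lr when the monitored loss stalls."""

    def __init__(self, optimizer, factor: float = 0.5, patience: int = 5, min_lr: float = 1e-6):
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, value: float) -> bool:
        """Feed one epoch's monitored value; returns True if lr was reduced."""
        if value < self.best - 1e-9:
            self.best = value
            self.bad_epochs = 0
            return False
        self.bad_epochs += 1
        if self.bad_epochs > self.patience:
            self.bad_epochs = 0
            new_lr = max(self.min_lr, self.optimizer.lr * self.factor)
            reduced = new_lr < self.optimizer.lr
            self.optimizer.lr = new_lr
            return reduced
        return False
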