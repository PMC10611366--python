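"""Plain SGD and Adam optimizers."""

from __future__ import annotations

import numpy as np

from .layers import Param


class SGD:
    def __init__(self, params: list[Param], lr: float, momentum: float = 0.0):
        if lr <= 0:
            raise ValueError(f"learning rate must be positive, got {lr}")
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self._vel = [np.zeros_like(p.value) for p in params] if momentum else None

    def step(self):
        for i, p in enumerate(self.params):
            if self._vel is not None:
                self._vel[i] = self.momentum * self._vel[i] + p.grad
                p.value -= self.lr * self._vel[i]
            else:
                p.value -= self.lr * p.grad

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0


class Adam:
    def __init__(self, params: list[Param], lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
        if lr <= 0:
            raise ValueError(f"learning rate must be positive, got {lr}")
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * p.grad
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * p.grad ** 2
            p.value -= self.lr * (self._m[i] / b1t) / (np.sqrt(self._v[i] / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0
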