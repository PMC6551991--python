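"""Optimizers operating on flat lists of parameter arrays."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam", "Adadelta"]


class Adam:
    def __init__(self, params, lr=1e-5, beta1=0.9, beta2=0.999, eps=1e-8, decay=0.0):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps, self.decay = beta1, beta2, eps, decay
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        lr = self.lr / (1.0 + self.decay * self.t)
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class Adadelta:
    def __init__(self, params, rho=0.95, eps=1e-6, lr=1.0):
        self.params = params
        self.rho, self.eps, self.lr = rho, eps, lr
        self.eg = [np.zeros_like(p) for p in params]
        self.ex = [np.zeros_like(p) for p in params]

    def step(self, grads) -> None:
        for p, g, eg, ex in zip(self.params, grads, self.eg, self.ex):
            eg *= self.rho
            eg += (1 - self.rho) * g * g
            dx = -np.sqrt((ex + self.eps) / (eg + self.eps)) * g
            ex *= self.rho
            ex += (1 - self.rho) * dx * dx
            p += self.lr * dx
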