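"""First-order optimizers for :class:`~thermoseg.nn.Parameter` lists."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam", "SGD"]


class Adam:
    """ADAM with bias correction (Kingma & Ba)."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.98), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()


class SGD:
    """Plain SGD with classical momentum; fallback when ADAM is not wanted."""

    def __init__(self, params, lr: float = 1e-2, momentum: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.buf = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.buf[i] = self.momentum * self.buf[i] + p.grad
            p.data -= self.lr * self.buf[i]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
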