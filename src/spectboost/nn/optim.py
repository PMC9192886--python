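"""Adam optimizer (Kingma & Ba) for the tensor engine."""

from __future__ import annotations

import numpy as np


class Adam:
    def __init__(self, params, lr: float = 2e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1 ** self.t
        bias2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * (g * g)
            p.data -= (self.lr / bias1) * m / (np.sqrt(v / bias2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
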