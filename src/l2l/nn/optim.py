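"""Adam optimizer over the flat (name, param, grad) triples of l2l.nn.layers."""

from __future__ import annotations

import numpy as np


class Adam:
    def __init__(self, triples, lr: float = 2e-4, beta1: float = 0.5,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.triples = list(triples)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {n: np.zeros_like(p) for n, p, _ in self.triples}
        self.v = {n: np.zeros_like(p) for n, p, _ in self.triples}

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for name, p, g in self.triples:
            m = self.m[name]
            v = self.v[name]
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for _, _, g in self.triples:
            g[...] = 0.0
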