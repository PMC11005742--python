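"""Adam optimizer over one or more Sequential networks."""

from __future__ import annotations

import numpy as np


class Adam:
    def __init__(self, networks, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.networks = list(networks)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        for ni, net in enumerate(self.networks):
            for lname, params, _ in net.named_params():
                for k, p in params.items():
                    key = f"{ni}.{lname}.{k}"
                    self.m[key] = np.zeros_like(p)
                    self.v[key] = np.zeros_like(p)

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for ni, net in enumerate(self.networks):
            for lname, params, grads in net.named_params():
                for k, p in params.items():
                    key = f"{ni}.{lname}.{k}"
                    g = grads[k]
                    self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
                    self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
                    mhat = self.m[key] / bc1
                    vhat = self.v[key] / bc2
                    p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
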