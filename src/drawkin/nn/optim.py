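"""Adam optimizer over a flat list of (params, grads) dicts."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam"]


class Adam:
    """Adam with bias-corrected first/second moments.

    ``layers`` is any sequence of objects exposing ``params`` and ``grads``
    dicts (the nn layers); moments are keyed by (layer index, name).
    """

    def __init__(
        self,
        layers,
        lr: float = 0.001,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.layers = list(layers)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {
            (i, k): np.zeros_like(v)
            for i, layer in enumerate(self.layers)
            for k, v in layer.params.items()
        }
        self.v = {k: np.zeros_like(val) for k, val in self.m.items()}

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1**self.t
        corr2 = 1.0 - b2**self.t
        for i, layer in enumerate(self.layers):
            for k, p in layer.params.items():
                g = layer.grads[k]
                m = self.m[(i, k)]
                v = self.v[(i, k)]
                m *= b1
                m += (1.0 - b1) * g
                v *= b2
                v += (1.0 - b2) * g * g
                p -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)
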