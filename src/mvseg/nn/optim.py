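"""Adam optimizer (Kingma & Ba) for the float32 parameter set."""

from __future__ import annotations

import numpy as np

from .layers import F32, Param


class Adam:
    def __init__(
        self,
        params: list[Param],
        learning_rate: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr = learning_rate
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.value -= (
                self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            ).astype(F32)
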