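"""Adam optimizer with L2 weight decay (coupled, added to the gradient)."""

from __future__ import annotations

import numpy as np


class Adam:
    def __init__(
        self,
        params: list[np.ndarray],
        grads: list[np.ndarray],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ) -> None:
        self.params = params
        self.grads = grads
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p, dtype=np.float64) for p in params]
        self.v = [np.zeros_like(p, dtype=np.float64) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            grad = g.astype(np.float64)
            if self.weight_decay:
                grad = grad + self.weight_decay * p
            m *= self.b1
            m += (1.0 - self.b1) * grad
            v *= self.b2
            v += (1.0 - self.b2) * grad * grad
            update = self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            p -= update.astype(p.dtype)
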