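"""Nesterov-accelerated adaptive moment estimation (Nadam).

The update follows the Keras formulation: Adam moments with a Nesterov
look-ahead on the first moment,

    m_t = b1 m_{t-1} + (1 - b1) g
    v_t = b2 v_{t-1} + (1 - b2) g^2
    step = lr * (b1 m_t / (1 - b1^{t+1}) + (1 - b1) g / (1 - b1^t))
               / (sqrt(v_t / (1 - b2^t)) + eps)
"""

from __future__ import annotations

import numpy as np

from .layers import Param

__all__ = ["Nadam"]


class Nadam:
    def __init__(self, params: dict[str, Param], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self._v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc1_next = 1.0 - b1 ** (self.t + 1)
        bc2 = 1.0 - b2**self.t
        for k, p in self.params.items():
            g = p.grad
            m = self._m[k]
            v = self._v[k]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            m_bar = b1 * m / bc1_next + (1 - b1) * g / bc1
            p.data -= self.lr * m_bar / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()
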