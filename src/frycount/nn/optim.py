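"""Stochastic gradient descent with classical momentum and L2 weight decay.

Update rule (the convention used by mainstream deep-learning frameworks):

    v <- momentum * v + (grad + weight_decay * w)
    w <- w - lr * v
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["SGD"]


class SGD:
    def __init__(
        self,
        params,
        lr: float,
        momentum: float = 0.0,
        weight_decay: float = 0.0,
    ):
        self.params: list[Tensor] = list(params)
        if not self.params:
            raise ValueError("no parameters to optimize")
        self.lr = float(lr)
        self.momentum = float(momentum)
        self.weight_decay = float(weight_decay)
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad.astype(p.data.dtype, copy=False)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data = p.data - self.lr * v
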