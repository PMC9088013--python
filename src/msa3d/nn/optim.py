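"""Stochastic gradient descent with decoupled-by-flag weight decay.

Weight decay is applied only to parameters whose ``decay`` attribute is
true (convolution and linear weight matrices); biases, batch-norm affine
parameters and attention gates are exempt.
"""

from __future__ import annotations

import numpy as np

from .autograd import Parameter

__all__ = ["SGD"]


class SGD:
    def __init__(self, params, lr: float = 0.01, weight_decay: float = 0.0,
                 momentum: float = 0.0):
        self.params: list[Parameter] = list(params)
        self.lr = lr
        self.weight_decay = weight_decay
        self.momentum = momentum
        self._velocity = [np.zeros_like(p.data) for p in self.params] \
            if momentum else None

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.astype(p.data.dtype, copy=False)
            if self.weight_decay and getattr(p, "decay", False):
                g = g + self.weight_decay * p.data
            if self._velocity is not None:
                v = self._velocity[i]
                v *= self.momentum
                v += g
                g = v
            p.data = p.data - self.lr * g
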