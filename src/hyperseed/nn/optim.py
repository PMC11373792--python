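"""Stochastic gradient descent with classical momentum and L2 weight decay.

Matches the common deep-learning formulation: the decay term is added
to the raw gradient, the velocity is ``v = mu * v + g``, and the update
is ``p -= lr * v``.
"""

from __future__ import annotations

import numpy as np

from .core import Parameter

__all__ = ["SGD"]


class SGD:
    def __init__(
        self,
        params: list[Parameter],
        lr: float = 0.001,
        momentum: float = 0.9,
        weight_decay: float = 0.01,
    ) -> None:
        if lr <= 0:
            raise ValueError("learning rate must be > 0")
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
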