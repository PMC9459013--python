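"""Adam optimizer and loss functions (value + gradient pairs)."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam", "mse_loss", "rmse_loss"]


class Adam:
    """Adaptive moment estimation with bias correction.

    ``lr`` is mutable so training loops can decay it on plateaus.
    """

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def mse_loss(pred, target):
    """Mean squared error over all entries; returns (value, grad)."""
    diff = pred - target
    n = diff.size
    return float((diff**2).mean()), (2.0 / n) * diff


def rmse_loss(pred, target):
    """Root-mean-square error over all entries; returns (value, grad)."""
    mse, dmse = mse_loss(pred, target)
    rmse = float(np.sqrt(mse))
    if rmse == 0.0:
        return 0.0, np.zeros_like(pred)
    return rmse, dmse / (2.0 * rmse)
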