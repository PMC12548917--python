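"""Adam optimizer with L2 weight decay and max-norm re-projection."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tensor import Tensor


@dataclass
class MaxNormConstraint:
    """Clip the norm of `param` computed over `axes` to at most `max_norm`.

    With axes=(1,) on a (in, out) linear weight this bounds each output
    unit's incoming weight vector; with axes=(1, 2) on a (out, in, k)
    convolution kernel it bounds each filter.
    """

    param: Tensor
    max_norm: float
    axes: tuple

    def apply(self):
        w = self.param.data
        norms = np.sqrt((w * w).sum(axis=self.axes, keepdims=True))
        scale = np.minimum(1.0, self.max_norm / np.maximum(norms, 1e-12))
        self.param.data = w * scale

    def satisfied(self, tol: float = 1e-5) -> bool:
        w = self.param.data
        norms = np.sqrt((w * w).sum(axis=self.axes))
        return bool(np.all(norms <= self.max_norm + tol))


class Adam:
    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.99, eps: float = 1e-8,
                 weight_decay: float = 0.0, constraints=()):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.constraints = list(constraints)
        self.t = 0
        self.m = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]
        self.v = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float64)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / bias1
            vhat = self.v[i] / bias2
            p.data = (p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                p.data.dtype
            )
        for c in self.constraints:
            c.apply()
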