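"""Parameterised layers and the Adam optimiser for the NumPy backend."""

from __future__ import annotations

import numpy as np

from .autograd import Var, conv2d, relu

__all__ = ["Conv2d", "ConvRelu", "Adam", "he_uniform"]


def he_uniform(rng: np.random.Generator, ci: int, co: int, kh: int, kw: int):
    """He/Kaiming uniform initialisation for a ReLU convolution."""
    fan_in = ci * kh * kw
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=(co, ci, kh, kw)).astype(np.float32)


class Conv2d:
    """Bias-free stride-1 'same' convolution.

    Biases are deliberately absent: the analytical parameter/flop
    accounting in :mod:`mbffnet.complexity` counts convolution weights and
    multiplies only, and the network matches that accounting exactly.
    """

    def __init__(self, ci, co, k, rng, name=""):
        self.ci, self.co, self.k = ci, co, k
        self.weight = Var(he_uniform(rng, ci, co, k, k), requires_grad=True)
        self.weight.name = name

    def __call__(self, x: Var) -> Var:
        return conv2d(x, self.weight)

    def parameters(self):
        return [self.weight]


class ConvRelu(Conv2d):
    def __call__(self, x: Var) -> Var:
        return relu(conv2d(x, self.weight))


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
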