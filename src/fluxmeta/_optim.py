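"""Flat-vector optimizers for the training loops."""

from __future__ import annotations

import numpy as np

from .errors import ConfigurationError


class SGD:
    """Plain gradient descent: ``theta <- theta - lr * grad``."""

    def __init__(self, lr: float):
        if lr <= 0:
            raise ConfigurationError("learning rate must be > 0")
        self.lr = lr

    def step(self, theta: np.ndarray, grad: np.ndarray) -> np.ndarray:
        return theta - self.lr * grad


class Adam:
    """Adaptive-moment estimation with bias correction."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        if lr <= 0:
            raise ConfigurationError("learning rate must be > 0")
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = None
        self.v = None
        self.t = 0

    def step(self, theta: np.ndarray, grad: np.ndarray) -> np.ndarray:
        if self.m is None:
            self.m = np.zeros_like(theta)
            self.v = np.zeros_like(theta)
        self.t += 1
        self.m = self.beta1 * self.m + (1 - self.beta1) * grad
        self.v = self.beta2 * self.v + (1 - self.beta2) * grad**2
        mhat = self.m / (1 - self.beta1**self.t)
        vhat = self.v / (1 - self.beta2**self.t)
        return theta - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def make_optimizer(name: str, lr: float):
    if name == "sgd":
        return SGD(lr)
    if name == "adam":
        return Adam(lr)
    raise ConfigurationError(f"unknown optimizer {name!r}")
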