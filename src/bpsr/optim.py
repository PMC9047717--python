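"""Plain-numpy parameter optimizers: SGD, Adam, AdamW.

Each optimizer keeps per-array state keyed by an identifier and applies an
in-place update ``param -= step``.  AdamW applies decoupled weight decay
(default 0 — the l1 synaptic regularizer already provides shrinkage).
"""

from __future__ import annotations

import numpy as np

__all__ = ["SGD", "Adam", "AdamW", "make_optimizer"]


class SGD:
    def __init__(self, lr: float = 1e-2, momentum: float = 0.0):
        self.lr = lr
        self.momentum = momentum
        self._v: dict[str, np.ndarray] = {}

    def step(self, key: str, param: np.ndarray, grad: np.ndarray) -> None:
        if self.momentum:
            v = self._v.setdefault(key, np.zeros_like(param))
            v *= self.momentum
            v += grad
            grad = v
        param -= self.lr * grad


class Adam:
    weight_decay = 0.0

    def __init__(self, lr: float = 1e-2, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}
        self._t: dict[str, int] = {}

    def step(self, key: str, param: np.ndarray, grad: np.ndarray) -> None:
        m = self._m.setdefault(key, np.zeros_like(param))
        v = self._v.setdefault(key, np.zeros_like(param))
        t = self._t.get(key, 0) + 1
        self._t[key] = t
        m *= self.beta1
        m += (1 - self.beta1) * grad
        v *= self.beta2
        v += (1 - self.beta2) * grad * grad
        m_hat = m / (1 - self.beta1**t)
        v_hat = v / (1 - self.beta2**t)
        if self.weight_decay:
            param -= self.lr * self.weight_decay * param
        param -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


class AdamW(Adam):
    def __init__(self, lr: float = 1e-2, weight_decay: float = 0.0, **kw):
        super().__init__(lr=lr, **kw)
        self.weight_decay = weight_decay


def make_optimizer(name: str, lr: float):
    name = name.lower()
    if name == "sgd":
        return SGD(lr=lr)
    if name == "adam":
        return Adam(lr=lr)
    if name == "adamw":
        return AdamW(lr=lr)
    raise ValueError(f"unknown optimizer {name!r}")
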