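"""Optimizers for the NumPy network engine.

Adadelta is the default for the classifier weights (with decoupled L2 weight
decay); plain SGD drives the GAN. Both operate in place on a list of
(parameter, gradient) array pairs collected from the model.
"""

from __future__ import annotations

import numpy as np


class Optimizer:
    def step(self, pairs: list[tuple[np.ndarray, np.ndarray]]) -> None:
        raise NotImplementedError


class SGD(Optimizer):
    def __init__(self, lr: float = 1e-4, weight_decay: float = 0.0) -> None:
        self.lr = lr
        self.weight_decay = weight_decay

    def step(self, pairs: list[tuple[np.ndarray, np.ndarray]]) -> None:
        for p, g in pairs:
            if self.weight_decay:
                g = g + self.weight_decay * p
            p -= self.lr * g


class Adadelta(Optimizer):
    """Adadelta: per-parameter step from the ratio of running RMS values.

    update = - lr * RMS[dx] / RMS[g] * g, with exponential accumulators for
    the squared gradients and squared updates (decay ``rho``). ``lr`` is the
    conventional global multiplier (1.0 recovers the original method).
    """

    def __init__(self, lr: float = 1.0, rho: float = 0.95, eps: float = 1e-6,
                 weight_decay: float = 0.0) -> None:
        self.lr = lr
        self.rho = rho
        self.eps = eps
        self.weight_decay = weight_decay
        self._eg2: list[np.ndarray] | None = None  # E[g^2]
        self._ed2: list[np.ndarray] | None = None  # E[dx^2]

    def step(self, pairs: list[tuple[np.ndarray, np.ndarray]]) -> None:
        if self._eg2 is None:
            self._eg2 = [np.zeros_like(p) for p, _ in pairs]
            self._ed2 = [np.zeros_like(p) for p, _ in pairs]
        if len(self._eg2) != len(pairs):
            raise ValueError("parameter list changed between steps")
        for i, (p, g) in enumerate(pairs):
            if self.weight_decay:
                g = g + self.weight_decay * p
            eg2, ed2 = self._eg2[i], self._ed2[i]
            eg2 *= self.rho
            eg2 += (1 - self.rho) * g * g
            dx = np.sqrt((ed2 + self.eps) / (eg2 + self.eps)) * g
            ed2 *= self.rho
            ed2 += (1 - self.rho) * dx * dx
            p -= self.lr * dx


def make_optimizer(name: str, **kwargs) -> Optimizer:
    name = name.lower()
    if name == "adadelta":
        return Adadelta(**kwargs)
    if name == "sgd":
        return SGD(**kwargs)
    raise ValueError(f"unknown optimizer {name!r}")
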