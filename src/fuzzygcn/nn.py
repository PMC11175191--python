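"""Minimal neural-network layers with explicit forward/backward passes.

Everything operates on NumPy arrays; each layer caches what its backward pass
needs, exposes learnable arrays in ``params`` with matching entries in
``grads``, and reports its learnable-scalar count. The Chebyshev graph
convolution is the workhorse: a spectral graph filter realized as a
polynomial in the rescaled Laplacian, evaluated by the three-term Chebyshev
recursion (no eigendecomposition at run time).
"""

from __future__ import annotations

import numpy as np

from . import fuzzy
from .graph import ChannelGraph


def chebyshev_basis(L_scaled: np.ndarray, n_terms: int) -> np.ndarray:
    """Stack T_0..T_{S-1} of the rescaled Laplacian: (S, N, N).

    T_0 = I, T_1 = L_scaled, T_s = 2 L_scaled T_{s-1} - T_{s-2}.
    """
    if n_terms < 1:
        raise ValueError("need at least one Chebyshev term")
    n = L_scaled.shape[0]
    T = [np.eye(n)]
    if n_terms > 1:
        T.append(L_scaled.copy())
    for _ in range(2, n_terms):
        T.append(2.0 * L_scaled @ T[-1] - T[-2])
    return np.stack(T[:n_terms])


class Layer:
    """Base layer: params/grads dicts plus forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def param_count(self) -> int:
        return int(sum(p.size for p in self.params.values()))


class ChebGraphConv(Layer):
    """Graph convolution Y = sum_s T_s(L_scaled) X Theta_s + bias.

    ``theta`` has shape (S, in_features, out_features); with S = 1 the layer
    degenerates to a per-node linear map (T_0 = I, no neighbor mixing), which
    is the configuration the reference architecture settles on; S >= 2 mixes
    information across graph neighborhoods.
    """

    def __init__(self, in_features: int, out_features: int, n_terms: int,
                 graph: ChannelGraph, rng: np.random.Generator,
                 dtype=np.float64) -> None:
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.n_terms = n_terms
        self.T = chebyshev_basis(graph.L_scaled, n_terms).astype(dtype)
        bound = 1.0 / np.sqrt(in_features)  # scaled-uniform fan-in init
        self.params["theta"] = rng.uniform(
            -bound, bound, size=(n_terms, in_features, out_features)
        ).astype(dtype)
        self.params["bias"] = np.zeros(out_features, dtype=dtype)
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._tx: list[np.ndarray] | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        # x: (batch, nodes, in_features)
        if x.shape[2] != self.in_features:
            raise ValueError(
                f"input has {x.shape[2]} features, layer expects "
                f"{self.in_features}")
        if x.shape[1] != self.T.shape[1]:
            raise ValueError("input node count does not match the graph")
        theta = self.params["theta"]
        tx = []
        y = None
        for s in range(self.n_terms):
            txs = x if s == 0 else self.T[s] @ x  # T_0 = I: skip the matmul
            tx.append(txs)
            term = txs @ theta[s]
            y = term if y is None else y + term
        self._tx = tx
        return y + self.params["bias"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        theta = self.params["theta"]
        assert self._tx is not None
        dx = np.zeros_like(self._tx[0])
        for s in range(self.n_terms):
            txs = self._tx[s]
            # (B,N,Fin)^T (B,N,Fout) summed over batch and nodes
            self.grads["theta"][s] = np.einsum("bnf,bng->fg", txs, dy)
            back = dy @ theta[s].T
            dx += back if s == 0 else self.T[s].T @ back
        self.grads["bias"][...] = dy.sum(axis=(0, 1))
        return dx


class BatchNorm(Layer):
    """Batch normalization over (batch, nodes) per feature."""

    def __init__(self, n_features: int, momentum: float = 0.1,
                 eps: float = 1e-5, dtype=np.float64) -> None:
        super().__init__()
        self.params["gamma"] = np.ones(n_features, dtype=dtype)
        self.params["beta"] = np.zeros(n_features, dtype=dtype)
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.running_mean = np.zeros(n_features, dtype=dtype)
        self.running_var = np.ones(n_features, dtype=dtype)
        self.momentum = momentum
        self.eps = eps
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))  # all but the feature axis
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean
            self.running_var = (1 - m) * self.running_var + m * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        self._cache = (xhat, inv_std, axes, x.shape)
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std, axes, shape = self._cache
        m = np.prod([shape[a] for a in axes])
        self.grads["gamma"][...] = np.sum(dy * xhat, axis=axes)
        self.grads["beta"][...] = np.sum(dy, axis=axes)
        g = self.params["gamma"]
        dxhat = dy * g
        # standard batchnorm backward, vectorized over the reduction axes
        dx = (dxhat - dxhat.mean(axis=axes)
              - xhat * np.mean(dxhat * xhat, axis=axes)) * inv_std
        return dx


class Dropout(Layer):
    """Inverted dropout; active only in training mode."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class TF2Activation(Layer):
    """Elementwise TF-2 activation; three learnable scalars per layer."""

    def __init__(self, params: fuzzy.TF2Params) -> None:
        super().__init__()
        self.tf2 = params
        self._x: np.ndarray | None = None
        # expose gamma as a (3,) array so the main optimizer can drive it
        self.params["gamma3"] = params.as_array()
        self.grads["gamma3"] = np.zeros(3)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self.sync_from_array()  # the exposed array is the source of truth
        self._x = x
        return fuzzy.tf2_forward(x, self.tf2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx, da, dp, dn = fuzzy.tf2_backward(self._x, self.tf2, dy)
        self.grads["gamma3"][...] = (da, dp, dn)
        return dx

    def sync_from_array(self) -> None:
        """Pull gamma from the optimizer-facing array view (re-clamps alpha)."""
        a, p, n = self.params["gamma3"]
        self.tf2.alpha = float(np.clip(a, self.tf2.clamp_eps,
                                       1 - self.tf2.clamp_eps))
        self.params["gamma3"][0] = self.tf2.alpha
        self.tf2.p = float(p)
        self.tf2.n = float(n)

    def apply_momentum_update(self) -> None:
        """Dedicated gamma update rule (momentum on the layer gradient)."""
        fuzzy.update_params(self.tf2, tuple(self.grads["gamma3"]))
        self.params["gamma3"][...] = self.tf2.as_array()


class ReLU(Layer):
    def __init__(self, slope: float = 0.0) -> None:
        super().__init__()
        self.slope = slope  # 0 -> ReLU, >0 -> Leaky-ReLU
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return np.where(x > 0, x, self.slope * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._x > 0, dy, self.slope * dy)


class Sigmoid(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._y: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._y * (1.0 - self._y)


class Flatten(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._shape: tuple | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, dtype=np.float64) -> None:
        super().__init__()
        bound = 1.0 / np.sqrt(in_features)
        self.params["w"] = rng.uniform(
            -bound, bound, size=(in_features, out_features)).astype(dtype)
        self.params["bias"] = np.zeros(out_features, dtype=dtype)
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return x @ self.params["w"] + self.params["bias"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["w"][...] = self._x.T @ dy
        self.grads["bias"][...] = dy.sum(axis=0)
        return dy @ self.params["w"].T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, labels: np.ndarray,
                  eps: float = 1e-12) -> float:
    n = len(labels)
    return float(-np.mean(np.log(probs[np.arange(n), labels] + eps)))


def softmax_xent_backward(probs: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Gradient of mean cross-entropy w.r.t. the logits."""
    n = len(labels)
    d = probs.copy()
    d[np.arange(n), labels] -= 1.0
    return d / n
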