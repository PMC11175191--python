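"""The six-layer Chebyshev graph-convolutional classifier.

Architecture (per the reference design): input dropout, then six blocks of
[graph convolution -> batch normalization -> activation], then flatten, a
two-unit fully connected head, and softmax. Each graph vertex is an EEG
channel; its feature vector is the trial's (normalized) time series, so layer
widths shrink the per-vertex feature dimension while the vertex count stays
fixed.

The activation is the learnable TF-2 unit by default; ReLU and Leaky-ReLU are
drop-in replacements for ablation runs. Parameter accounting per layer is
S_l * in * out + out for the convolutions (weight tensor (S_l, in, out) plus
bias) — exactly the bookkeeping of the reference architecture table.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .fuzzy import TF2Params
from .graph import ChannelGraph
from . import nn

#: per-vertex feature widths of the paper-scale architecture
PAPER_DIMS = (10_000, 10_000, 5_000, 2_500, 1_250, 625, 312)
#: desk-scale widths for a 1000-sample (2 s @ 500 Hz) trial
DESK_DIMS = (1_000, 64, 48, 32, 24, 16, 8)


@dataclass
class ModelConfig:
    """Architecture + activation hyperparameters.

    ``dims`` chains the per-vertex feature widths: dims[0] is the input
    width (samples per trial), each subsequent entry is a conv layer's output
    width. ``cheb_orders[l]`` is the number of Chebyshev *terms* S_l of layer
    l (S = 1: per-node linear map; S >= 2: neighborhood mixing).
    """

    dims: tuple[int, ...] = DESK_DIMS
    cheb_orders: tuple[int, ...] | None = None  # default: all ones
    n_nodes: int = 5
    n_classes: int = 2
    dropout_rate: float = 0.1
    batchnorm: bool = True
    activation: str = "tf2"            # tf2 | relu | leaky_relu
    leaky_slope: float = 0.01
    act_before_bn: bool = False        # swap conv->bn->act to conv->act->bn
    tf2_alpha_init: float = 0.5
    tf2_p_init: float = 1.0
    tf2_n_init: float = 0.1
    tf2_rho: float = 0.9
    tf2_xi: float = 0.01
    tf2_via_main_optimizer: bool = False
    dtype: str = "float64"

    def __post_init__(self) -> None:
        if len(self.dims) < 2:
            raise ValueError("dims must chain at least one layer")
        if self.cheb_orders is None:
            self.cheb_orders = tuple(1 for _ in range(self.n_layers))
        self.cheb_orders = tuple(self.cheb_orders)
        if len(self.cheb_orders) != self.n_layers:
            raise ValueError("need one Chebyshev order per conv layer")
        if any(s < 1 for s in self.cheb_orders):
            raise ValueError("Chebyshev term counts must be >= 1")
        if self.activation not in ("tf2", "relu", "leaky_relu"):
            raise ValueError(f"unknown activation {self.activation!r}")

    @property
    def n_layers(self) -> int:
        return len(self.dims) - 1

    @property
    def flatten_size(self) -> int:
        return self.n_nodes * self.dims[-1]

    def conv_parameter_counts(self) -> list[int]:
        """Closed-form S_l*in*out + out per conv layer (weights + bias)."""
        return [s * din * dout + dout
                for s, din, dout in zip(self.cheb_orders, self.dims[:-1],
                                        self.dims[1:])]

    def head_parameter_count(self) -> int:
        return self.flatten_size * self.n_classes + self.n_classes

    @classmethod
    def paper_scale(cls, **overrides) -> "ModelConfig":
        return cls(dims=PAPER_DIMS, **overrides)

    @classmethod
    def desk(cls, input_dim: int = 1000, **overrides) -> "ModelConfig":
        if input_dim == DESK_DIMS[0]:
            dims = DESK_DIMS
        else:
            dims = (input_dim,) + DESK_DIMS[1:]
        return cls(dims=dims, **overrides)

    def to_dict(self) -> dict:
        return asdict(self)


class GCNModel:
    """A built network: ordered layer stack with explicit backprop."""

    def __init__(self, cfg: ModelConfig, graph: ChannelGraph,
                 seed: int = 0) -> None:
        if graph.n_nodes != cfg.n_nodes:
            raise ValueError(
                f"graph has {graph.n_nodes} nodes, config expects "
                f"{cfg.n_nodes}")
        self.cfg = cfg
        self.graph = graph
        self.rng = np.random.default_rng(seed)
        dtype = np.dtype(cfg.dtype).type
        self.layers: list[nn.Layer] = []
        self._conv_layers: list[nn.ChebGraphConv] = []
        self._tf2_layers: list[nn.TF2Activation] = []

        self.layers.append(nn.Dropout(cfg.dropout_rate, self.rng))
        for l in range(cfg.n_layers):
            conv = nn.ChebGraphConv(cfg.dims[l], cfg.dims[l + 1],
                                    cfg.cheb_orders[l], graph, self.rng,
                                    dtype=dtype)
            self._conv_layers.append(conv)
            block: list[nn.Layer] = [conv]
            act = self._make_activation()
            if cfg.batchnorm:
                bn = nn.BatchNorm(cfg.dims[l + 1], dtype=dtype)
                block += [act, bn] if cfg.act_before_bn else [bn, act]
            else:
                block.append(act)
            self.layers.extend(block)
        self.layers.append(nn.Flatten())
        self.layers.append(nn.Dense(cfg.flatten_size, cfg.n_classes, self.rng,
                                    dtype=dtype))
        self._n_feature_layers = len(self.layers) - 2  # up to (excl.) flatten

    def _make_activation(self) -> nn.Layer:
        cfg = self.cfg
        if cfg.activation == "tf2":
            layer = nn.TF2Activation(TF2Params(
                alpha=cfg.tf2_alpha_init, p=cfg.tf2_p_init, n=cfg.tf2_n_init,
                rho=cfg.tf2_rho, xi=cfg.tf2_xi))
            self._tf2_layers.append(layer)
            return layer
        if cfg.activation == "relu":
            return nn.ReLU(0.0)
        return nn.ReLU(cfg.leaky_slope)

    # ------------------------------------------------------------------
    # passes
    # ------------------------------------------------------------------

    def features(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Per-vertex representation after the conv blocks (pre-flatten)."""
        h = np.asarray(x)
        for layer in self.layers[:self._n_feature_layers]:
            h = layer.forward(h, training)
        return h

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Class probabilities, shape (batch, n_classes)."""
        h = np.asarray(x)
        if h.ndim != 3:
            raise ValueError("input must be (trials, nodes, features)")
        if h.shape[1] != self.cfg.n_nodes or h.shape[2] != self.cfg.dims[0]:
            raise ValueError(
                f"input shape {h.shape[1:]} does not match "
                f"({self.cfg.n_nodes}, {self.cfg.dims[0]})")
        for layer in self.layers:
            h = layer.forward(h, training)
        return nn.softmax(h)

    def loss_and_grads(self, x: np.ndarray, labels: np.ndarray
                       ) -> tuple[float, np.ndarray]:
        """Training-mode forward + full backward; returns (loss, probs)."""
        probs = self.forward(x, training=True)
        loss = nn.cross_entropy(probs, labels)
        d = nn.softmax_xent_backward(probs, labels)
        for layer in reversed(self.layers):
            d = layer.backward(d)
        return loss, probs

    def predict(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Predicted labels in eval mode (dropout off, BN running stats)."""
        return np.argmax(self.predict_proba(x, batch_size), axis=1)

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        out = [self.forward(x[i:i + batch_size], training=False)
               for i in range(0, len(x), batch_size)]
        return np.concatenate(out, axis=0)

    # ------------------------------------------------------------------
    # parameters
    # ------------------------------------------------------------------

    def weight_pairs(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """(param, grad) pairs for the main optimizer.

        TF-2 triples are included only when the config routes them through
        the main optimizer; by default they follow their own momentum rule.
        """
        pairs = []
        for layer in self.layers:
            if isinstance(layer, nn.TF2Activation) and \
                    not self.cfg.tf2_via_main_optimizer:
                continue
            for k in layer.params:
                pairs.append((layer.params[k], layer.grads[k]))
        return pairs

    def apply_tf2_updates(self) -> None:
        if self.cfg.tf2_via_main_optimizer:
            for layer in self._tf2_layers:
                layer.sync_from_array()
        else:
            for layer in self._tf2_layers:
                layer.apply_momentum_update()

    def parameter_counts(self) -> dict[str, int]:
        """Learnable-scalar count per named layer (model introspection)."""
        counts: dict[str, int] = {}
        for i, conv in enumerate(self._conv_layers, start=1):
            counts[f"graph_conv{i}"] = conv.param_count()
        counts["head"] = self.layers[-1].param_count()
        if self.cfg.batchnorm:
            counts["batchnorm"] = sum(
                l.param_count() for l in self.layers
                if isinstance(l, nn.BatchNorm))
        if self._tf2_layers:
            counts["tf2"] = sum(l.param_count() for l in self._tf2_layers)
        return counts

    def n_tf2_params(self) -> int:
        return sum(l.param_count() for l in self._tf2_layers)

    # ------------------------------------------------------------------
    # checkpointing
    # ------------------------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.params.items():
                state[f"layer{i}:{k}"] = v
            if isinstance(layer, nn.BatchNorm):
                state[f"layer{i}:running_mean"] = layer.running_mean
                state[f"layer{i}:running_var"] = layer.running_var
        return state

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for k in layer.params:
                layer.params[k][...] = state[f"layer{i}:{k}"]
            if isinstance(layer, nn.BatchNorm):
                layer.running_mean[...] = state[f"layer{i}:running_mean"]
                layer.running_var[...] = state[f"layer{i}:running_var"]
        for layer in self._tf2_layers:
            layer.sync_from_array()

    def copy_state(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.state_arrays().items()}
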