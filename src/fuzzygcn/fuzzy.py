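"""Learnable type-2 fuzzy (TF-2) activation units.

A TF-2 activation replaces ReLU/Leaky-ReLU with a parametric nonlinearity
derived from type-2 fuzzy membership grades. Each activation layer carries a
single learnable triple gamma = [alpha, P, N]:

* ``alpha`` in (0, 1) controls the curvature ("fuzziness") of the membership
  kernel k; as alpha -> 1 the kernel flattens to 1/2,
* ``P`` scales the positive branch, ``N`` the negative branch.

The forward map, for pre-activation sigma, is

    f(sigma) = P * sigma * k(sigma; alpha)    for sigma > 0
    f(sigma) = N * sigma * k(-sigma; alpha)   for sigma <= 0

with the membership kernel

    k(s; alpha) = 1/2 * [ 1 / (alpha + (1 - alpha) s)
                          + (1 - alpha) / (1 - alpha s) ],   s in [0, 1].

k(1; alpha) = 1 for every alpha, so f(1) = P and f(-1) = -N: with P near 1
and N small the unit starts out Leaky-ReLU-like. The kernel argument is
clamped at |sigma| = 1 and the function continues *exactly linearly* beyond
(slope P, resp. N), which keeps the rational kernel away from its pole at
s = 1/alpha for unbounded pre-activations.

A network with C activation layers adds only 3C learnable scalars. The triple
is updated by a dedicated momentum rule

    delta <- rho * delta + xi * grad;   gamma <- gamma - delta

independent of whatever optimizer drives the network weights (configurable).
All gradients here are analytic and validated against central finite
differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: alpha is kept inside [CLAMP_EPS, 1 - CLAMP_EPS]
CLAMP_EPS = 1e-3


@dataclass
class TF2Params:
    """One learnable triple gamma = [alpha, P, N] plus its momentum state."""

    alpha: float = 0.5
    p: float = 1.0
    n: float = 0.1
    rho: float = 0.9      # momentum coefficient
    xi: float = 0.01      # learning rate for the gamma update
    clamp_eps: float = CLAMP_EPS
    momentum: np.ndarray = field(
        default_factory=lambda: np.zeros(3))  # (d_alpha, d_p, d_n)

    def __post_init__(self) -> None:
        self.alpha = float(np.clip(self.alpha, self.clamp_eps,
                                   1.0 - self.clamp_eps))

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.p, self.n])


def k_func(sigma: np.ndarray | float, alpha: float) -> np.ndarray | float:
    """Membership kernel k(sigma; alpha) for sigma in [0, 1] (clamped)."""
    s = np.clip(sigma, 0.0, 1.0)
    return 0.5 * (1.0 / (alpha + (1.0 - alpha) * s)
                  + (1.0 - alpha) / (1.0 - alpha * s))


def _k_dsigma(s: np.ndarray, alpha: float) -> np.ndarray:
    """dk/ds on [0, 1]."""
    a = alpha
    return 0.5 * (-(1.0 - a) / (a + (1.0 - a) * s) ** 2
                  + a * (1.0 - a) / (1.0 - a * s) ** 2)


def _k_dalpha(s: np.ndarray, alpha: float) -> np.ndarray:
    """dk/dalpha on [0, 1].

    Both partial terms share the factor (1 - s), so the derivative vanishes
    at s = 1 — the linear extension beyond |sigma| = 1 is therefore smooth in
    alpha as well.
    """
    a = alpha
    return -0.5 * (1.0 - s) * (1.0 / (a + (1.0 - a) * s) ** 2
                               + 1.0 / (1.0 - a * s) ** 2)


def tf2_forward(sigma: np.ndarray | float, params: TF2Params) -> np.ndarray:
    """Elementwise TF-2 activation f(sigma; gamma)."""
    s = np.asarray(sigma, dtype=np.float64)
    pos = s > 0
    mag = np.minimum(np.abs(s), 1.0)
    k = k_func(mag, params.alpha)
    inner = np.where(pos, params.p, params.n) * s * k
    outer = np.where(pos, params.p, params.n) * s  # exact linear extension
    return np.where(np.abs(s) <= 1.0, inner, outer)


def tf2_backward(sigma: np.ndarray | float, params: TF2Params,
                 upstream_grad: np.ndarray | float
                 ) -> tuple[np.ndarray, float, float, float]:
    """Analytic partials of the activation, chained with ``upstream_grad``.

    Returns ``(d_sigma, d_alpha, d_p, d_n)``: the elementwise gradient with
    respect to the pre-activation, and the three scalar parameter gradients
    summed over all elements (one triple per layer, shared across the layer's
    units and the batch).
    """
    s = np.asarray(sigma, dtype=np.float64)
    g = np.asarray(upstream_grad, dtype=np.float64)
    a, p, n = params.alpha, params.p, params.n

    pos = s > 0
    interior = np.abs(s) <= 1.0
    mag = np.minimum(np.abs(s), 1.0)
    k = k_func(mag, a)
    dk_ds = _k_dsigma(mag, a)
    dk_da = _k_dalpha(mag, a)

    scale = np.where(pos, p, n)
    # interior: d/ds [scale * s * k(|s|)] = scale * (k(|s|) + s * k'(|s|) * sign(s))
    #   sign(s) * s = |s| = mag, so the product rule term is scale*(k + mag*dk_ds)
    d_sigma_in = scale * (k + mag * dk_ds)
    d_sigma = np.where(interior, d_sigma_in, scale) * g

    df_dp = np.where(pos, s * np.where(interior, k, 1.0), 0.0)
    df_dn = np.where(pos, 0.0, s * np.where(interior, k, 1.0))
    df_da = np.where(interior, scale * s * dk_da, 0.0)

    d_alpha = float(np.sum(g * df_da))
    d_p = float(np.sum(g * df_dp))
    d_n = float(np.sum(g * df_dn))
    return d_sigma, d_alpha, d_p, d_n


def update_params(params: TF2Params, grads: tuple[float, float, float]
                  ) -> TF2Params:
    """Momentum update of gamma: delta <- rho*delta + xi*g; gamma <- gamma - delta.

    Mutates and returns ``params``. ``alpha`` is re-clamped into
    [clamp_eps, 1 - clamp_eps] after the step so the kernel stays defined.
    """
    g = np.asarray(grads, dtype=np.float64)
    params.momentum = params.rho * params.momentum + params.xi * g
    params.alpha = float(np.clip(params.alpha - params.momentum[0],
                                 params.clamp_eps, 1.0 - params.clamp_eps))
    params.p = float(params.p - params.momentum[1])
    params.n = float(params.n - params.momentum[2])
    return params


def count_params(n_layers: int) -> int:
    """Learnable TF-2 scalars in a network with ``n_layers`` activation layers."""
    if n_layers < 1:
        raise ValueError("layer count must be >= 1")
    return 3 * n_layers
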