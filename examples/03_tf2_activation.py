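"""The learnable type-2 fuzzy activation: shape, gradients, momentum updates.

f(sigma) = P * sigma * k(sigma; alpha) on the positive branch and
N * sigma * k(-sigma; alpha) on the negative one, with the rational
membership kernel k satisfying k(1) = 1 (so f(1) = P, f(-1) = -N) and an
exact linear continuation beyond |sigma| = 1. With alpha = 0.5, P = 1,
N = 0.1 the unit starts out Leaky-ReLU-like and then learns its own shape:
only 3 scalars per activation layer, updated by a dedicated momentum rule.
"""

import numpy as np

from fuzzygcn import TF2Params, count_params, tf2_backward, tf2_forward
from fuzzygcn.fuzzy import update_params

params = TF2Params(alpha=0.5, p=1.0, n=0.1, rho=0.9, xi=0.1)
for s in (-1.5, -1.0, -0.5, 0.0, 0.5, 1.0, 1.5):
    print(f"f({s:+.1f}) = {float(tf2_forward(s, params)):+.4f}")
# f(1) = P = 1, f(-1) = -N = -0.1; outside [-1,1] the slope is exactly P or N

sigma = np.array([0.3, -0.7, 1.4])
upstream = np.ones_like(sigma)
d_sigma, d_alpha, d_p, d_n = tf2_backward(sigma, params, upstream)
print("\nanalytic gradients at sigma =", sigma)
print("  d/dsigma:", np.round(d_sigma, 4))
print(f"  d/dalpha: {d_alpha:+.4f}  d/dP: {d_p:+.4f}  d/dN: {d_n:+.4f}")
# d/dN collects only the negative-branch element (-0.7); d/dP the others

update_params(params, (d_alpha, d_p, d_n))
print("\nafter one momentum step (rho=0.9, xi=0.1):")
print(f"  alpha={params.alpha:.4f}  P={params.p:.4f}  N={params.n:.4f}")

print(f"\nlearnable TF-2 scalars in a 6-layer network: {count_params(6)}")
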