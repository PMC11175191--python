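"""The graph-convolutional classifier: filtering, accounting, passes."""

from __future__ import annotations

import numpy as np
import pytest

from fuzzygcn.graph import graph_from_adjacency
from fuzzygcn.model import GCNModel, ModelConfig, PAPER_DIMS
from fuzzygcn import nn


def random_graph(rng, n=4):
    W = np.abs(rng.standard_normal((n, n)))
    W = (W + W.T) / 2
    np.fill_diagonal(W, 0)
    return graph_from_adjacency(W)


def spectral_filter_oracle(graph, x, theta):
    """Dense spectral-domain filtering: U (sum_s Theta_s T_s(Lambda~)) U^T X.

    Evaluates the Chebyshev polynomial on the eigenvalues of the rescaled
    Laplacian directly — the brute-force reference for the recursion.
    """
    lam_scaled = np.linalg.eigvalsh(graph.L_scaled)
    U = np.linalg.eigh(graph.L_scaled)[1]
    S = theta.shape[0]
    n = len(lam_scaled)
    out = np.zeros((x.shape[0], n, theta.shape[2]))
    t_prev, t_curr = np.ones(n), lam_scaled.copy()
    for s in range(S):
        ts = t_prev if s == 0 else t_curr
        filt = U @ np.diag(ts) @ U.T
        out += (filt @ x) @ theta[s]
        if s >= 1:
            t_prev, t_curr = t_curr, 2 * lam_scaled * t_curr - t_prev
    return out


class TestChebConv:
    def test_identity_filter(self, rng):
        g = random_graph(rng, 5)
        layer = nn.ChebGraphConv(3, 3, 1, g, rng)
        layer.params["theta"][0] = np.eye(3)
        layer.params["bias"][:] = 0.0
        x = rng.standard_normal((2, 5, 3))
        np.testing.assert_allclose(layer.forward(x, False), x, atol=1e-12)

    @pytest.mark.parametrize("n,s", [(4, 3), (6, 2), (8, 4)])
    def test_recursion_matches_dense_spectral_oracle(self, rng, n, s):
        g = random_graph(rng, n)
        layer = nn.ChebGraphConv(3, 2, s, g, rng)
        layer.params["bias"][:] = 0.0
        x = rng.standard_normal((2, n, 3))
        got = layer.forward(x, False)
        want = spectral_filter_oracle(g, x, layer.params["theta"])
        np.testing.assert_allclose(got, want, atol=1e-8)

    def test_backward_matches_finite_differences(self, rng):
        g = random_graph(rng, 3)
        layer = nn.ChebGraphConv(2, 2, 2, g, rng)
        x = rng.standard_normal((2, 3, 2))
        dy = rng.standard_normal((2, 3, 2))
        y = layer.forward(x, False)
        dx = layer.backward(dy)
        h = 1e-6

        def loss(x_):
            return np.sum(layer.forward(x_, False) * dy)

        for idx in np.ndindex(x.shape):
            xp, xm = x.copy(), x.copy()
            xp[idx] += h
            xm[idx] -= h
            assert dx[idx] == pytest.approx(
                (loss(xp) - loss(xm)) / (2 * h), rel=1e-4, abs=1e-6)
        # parameter gradient spot check
        th = layer.params["theta"]
        for idx in [(0, 0, 0), (1, 1, 1)]:
            orig = th[idx]
            th[idx] = orig + h
            lp = loss(x)
            th[idx] = orig - h
            lm = loss(x)
            th[idx] = orig
            layer.forward(x, False)
            layer.backward(dy)
            assert layer.grads["theta"][idx] == pytest.approx(
                (lp - lm) / (2 * h), rel=1e-4, abs=1e-6)


class TestAccounting:
    def test_paper_scale_conv_rows(self):
        cfg = ModelConfig.paper_scale()
        assert cfg.dims == PAPER_DIMS
        assert cfg.conv_parameter_counts() == [
            100_000_000 + 10_000,
            50_000_000 + 5_000,
            12_500_000 + 2_500,
            3_125_000 + 1_250,
            781_250 + 625,
            195_000 + 312,
        ]

    def test_accounting_scales_with_cheb_terms(self):
        cfg = ModelConfig(dims=(8, 4, 4, 4, 4, 4, 4),
                          cheb_orders=(3, 1, 1, 1, 1, 2))
        assert cfg.conv_parameter_counts()[0] == 3 * 8 * 4 + 4
        assert cfg.conv_parameter_counts()[5] == 2 * 4 * 4 + 4

    def test_introspection_matches_closed_form(self, rng):
        cfg = ModelConfig(dims=(16, 8, 8, 8, 8, 8, 4), n_nodes=3)
        g = random_graph(rng, 3)
        model = GCNModel(cfg, g, seed=0)
        counts = model.parameter_counts()
        for i, want in enumerate(cfg.conv_parameter_counts(), start=1):
            assert counts[f"graph_conv{i}"] == want
        assert counts["head"] == cfg.head_parameter_count()
        assert counts["tf2"] == 3 * cfg.n_layers
        assert model.n_tf2_params() == 3 * 6

    def test_flatten_feeds_two_unit_head(self):
        cfg = ModelConfig(dims=(16, 8, 8, 8, 8, 8, 4), n_nodes=5)
        assert cfg.flatten_size == 5 * 4
        assert cfg.head_parameter_count() == 20 * 2 + 2


class TestForward:
    def small_model(self, rng, activation="tf2", seed=0, n_nodes=4):
        cfg = ModelConfig(dims=(12, 8, 8, 6, 6, 4, 4), n_nodes=n_nodes,
                          activation=activation)
        return GCNModel(cfg, random_graph(rng, n_nodes), seed=seed)

    def test_rows_are_probability_vectors(self, rng):
        model = self.small_model(rng)
        x = rng.standard_normal((7, 4, 12))
        p = model.forward(x, training=False)
        assert p.shape == (7, 2)
        assert np.all(p >= 0)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_eval_mode_deterministic_and_pure(self, rng):
        model = self.small_model(rng)
        x = rng.standard_normal((3, 4, 12))
        p1 = model.forward(x, training=False)
        p2 = model.forward(x, training=False)
        np.testing.assert_array_equal(p1, p2)
        xd = np.concatenate([x, x[:1]], axis=0)
        pd = model.forward(xd, training=False)
        np.testing.assert_allclose(pd[3], pd[0], atol=1e-12)

    @pytest.mark.parametrize("activation", ["relu", "leaky_relu"])
    def test_ablation_activations_build_and_train(self, rng, activation):
        model = self.small_model(rng, activation=activation)
        x = rng.standard_normal((8, 4, 12))
        y = np.array([0, 1] * 4)
        loss0, _ = model.loss_and_grads(x, y)
        from fuzzygcn.optim import Adadelta
        opt = Adadelta(lr=1.0)
        for _ in range(30):
            loss, _ = model.loss_and_grads(x, y)
            opt.step(model.weight_pairs())
            model.apply_tf2_updates()
        assert np.isfinite(loss)

    def test_unknown_activation_rejected(self):
        with pytest.raises(ValueError, match="activation"):
            ModelConfig(dims=(4, 2), activation="gelu")

    def test_feature_stack_is_permutation_equivariant(self, rng):
        # graph filtering commutes with vertex relabeling: permuting W and
        # the rows of X permutes the per-vertex features identically
        n = 5
        g = random_graph(rng, n)
        cfg = ModelConfig(dims=(6, 4, 4, 4, 4, 4, 4), n_nodes=n,
                          cheb_orders=(2, 1, 2, 1, 1, 1), dropout_rate=0.0)
        model = GCNModel(cfg, g, seed=3)
        perm = rng.permutation(n)
        gp = graph_from_adjacency(g.W[np.ix_(perm, perm)])
        model_p = GCNModel(cfg, gp, seed=3)
        for lay, lay_p in zip(model.layers, model_p.layers):
            for k in lay.params:
                lay_p.params[k][...] = lay.params[k]
        x = rng.standard_normal((2, n, 6))
        np.testing.assert_allclose(
            model_p.features(x[:, perm, :]),
            model.features(x)[:, perm, :], atol=1e-9)

    def test_input_shape_validated(self, rng):
        model = self.small_model(rng)
        with pytest.raises(ValueError, match="match"):
            model.forward(rng.standard_normal((2, 4, 99)))

    def test_non_chaining_dims_rejected_at_build(self, rng):
        # chaining is implied by the dims sequence itself; a wrong node
        # count between graph and config must fail loudly
        cfg = ModelConfig(dims=(6, 4), n_nodes=7)
        with pytest.raises(ValueError, match="nodes"):
            GCNModel(cfg, random_graph(rng, 4), seed=0)


class TestWholeModelGradient:
    def test_backprop_matches_finite_differences_end_to_end(self, rng):
        cfg = ModelConfig(dims=(5, 4, 3), n_nodes=3, dropout_rate=0.0,
                          batchnorm=True, cheb_orders=(2, 1))
        g = random_graph(rng, 3)
        model = GCNModel(cfg, g, seed=1)
        x = rng.standard_normal((4, 3, 5))
        y = np.array([0, 1, 1, 0])
        model.loss_and_grads(x, y)
        h = 1e-6
        # check a handful of scalar parameters across layer types
        checked = 0
        for layer in model.layers:
            for key, arr in layer.params.items():
                idx = tuple(0 for _ in arr.shape)
                grad = layer.grads[key][idx]
                orig = arr[idx]
                arr[idx] = orig + h
                lp = _loss_only(model, x, y)
                arr[idx] = orig - h
                lm = _loss_only(model, x, y)
                arr[idx] = orig
                num = (lp - lm) / (2 * h)
                assert grad == pytest.approx(num, rel=5e-3, abs=1e-7), key
                checked += 1
        assert checked >= 8


def _loss_only(model, x, y):
    from fuzzygcn import nn as _nn
    probs = model.forward(x, training=True)
    return _nn.cross_entropy(probs, y)
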