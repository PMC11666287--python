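"""Autoencoder forward passes, closed-form losses and pre-training behavior."""

import numpy as np
import pandas as pd
import pytest

import spotcycle as sp
from spotcycle import cgan
from spotcycle.graph import SpatialGraph, build_knn_graph
from spotcycle.nn import EdgeIndex, GATv2Layer, NetworkParameters


def make_params(d_in, d_h, d_z, seed=0, d_disc=8):
    return NetworkParameters.init(d_in, d_h, d_z, np.random.default_rng(seed),
                                  d_disc=d_disc)


def zero_weights(params):
    for p in params.all_parameters():
        p.data[...] = 0.0


class TestDecodeAdjacency:
    def test_zero_latent_gives_half(self):
        np.testing.assert_allclose(cgan.decode_adjacency(np.zeros((4, 3))), 0.5)

    def test_orthonormal_rows(self):
        z = np.eye(3)
        a = cgan.decode_adjacency(z)
        sig1 = 1 / (1 + np.exp(-1.0))
        np.testing.assert_allclose(np.diagonal(a), sig1, atol=1e-12)
        off = a[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 0.5, atol=1e-12)

    def test_symmetric_in_unit_interval(self, rng):
        a = cgan.decode_adjacency(rng.normal(size=(6, 4)))
        np.testing.assert_allclose(a, a.T, atol=1e-15)
        assert ((a > 0) & (a < 1)).all()


class TestReparameterize:
    def test_zero_noise_returns_mu(self, rng):
        mu = rng.normal(size=(3, 2))
        st = cgan.LatentState(mu, rng.normal(size=(3, 2)), mu)
        np.testing.assert_array_equal(cgan.reparameterize(st, np.zeros((3, 2))), mu)

    def test_unit_noise_zero_logvar(self):
        mu = np.full((2, 2), 3.0)
        st = cgan.LatentState(mu, np.zeros((2, 2)), mu)
        np.testing.assert_allclose(cgan.reparameterize(st, np.ones((2, 2))), mu + 1.0)

    def test_literal_convention(self, rng):
        mu, logvar = rng.normal(size=(2, 2)), rng.normal(size=(2, 2))
        eps = rng.normal(size=(2, 2))
        st = cgan.LatentState(mu, logvar, mu)
        np.testing.assert_allclose(
            cgan.reparameterize(st, eps, literal=True), mu + logvar * eps)
        np.testing.assert_allclose(
            cgan.reparameterize(st, eps), mu + np.exp(0.5 * logvar) * eps)


class TestReconstructionLoss:
    A2 = np.array([[0.0, 1], [1, 0]])

    def test_vanishes_when_perfect(self, rng):
        X = rng.normal(size=(2, 3))
        val = cgan.reconstruction_loss(X, X, self.A2, np.full((2, 2), 0.5),
                                       np.zeros((2, 2)), np.zeros((2, 2)), 0.0)
        assert val == 0.0

    def test_bce_hand_value(self, rng):
        # X = X̂, μ = logvar = 0, Â = 0.5 everywhere: only the BCE remains
        X = rng.normal(size=(2, 3))
        val = cgan.reconstruction_loss(X, X, self.A2, np.full((2, 2), 0.5),
                                       np.zeros((2, 1)), np.zeros((2, 1)), 1.0)
        np.testing.assert_allclose(val, np.log(2), rtol=1e-9)

    def test_kl_zero_iff_standard_normal(self, rng):
        X = rng.normal(size=(2, 3))
        base = cgan.reconstruction_loss(X, X, self.A2, np.full((2, 2), 0.5),
                                        np.zeros((2, 4)), np.zeros((2, 4)), 1.0)
        for mu, lv in [(rng.normal(size=(2, 4)), np.zeros((2, 4))),
                       (np.zeros((2, 4)), rng.normal(size=(2, 4)))]:
            val = cgan.reconstruction_loss(X, X, self.A2, np.full((2, 2), 0.5),
                                           mu, lv, 1.0)
            assert val > base  # KL strictly positive away from N(0, I)

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            cgan.reconstruction_loss(np.zeros((1, 1)), np.zeros((1, 1)),
                                     np.zeros((1, 1)), np.full((1, 1), 0.5),
                                     np.zeros((1, 1)), np.zeros((1, 1)), -1.0)


class TestDiscriminatorLoss:
    def test_uniform_predictor_is_ln2(self):
        labels = np.array([0, 0, 1, 1])
        probs = np.full((4, 2), 0.5)
        assert abs(cgan.domain_discriminator_loss(labels, probs) - np.log(2)) < 1e-12

    def test_perfect_predictor_is_zero(self):
        labels = np.array([0, 1])
        probs = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert cgan.domain_discriminator_loss(labels, probs) == 0.0

    def test_hand_value(self):
        labels = np.array([0, 1])
        probs = np.array([[0.8, 0.2], [0.2, 0.8]])
        np.testing.assert_allclose(cgan.domain_discriminator_loss(labels, probs),
                                   -np.log(0.8), rtol=1e-12)

    def test_zero_probability_clamped(self):
        labels = np.array([0])
        val = cgan.domain_discriminator_loss(labels, np.array([[0.0, 1.0]]))
        assert np.isfinite(val)


def test_cgan_loss_arithmetic():
    assert cgan.cgan_loss(0.5, 2.0, 10.0) == 20.5
    assert cgan.cgan_loss(0.7, 123.0, 0.0) == 0.7
    # linear in L_re
    assert cgan.cgan_loss(0.0, 3.0, 2.0) == 2 * cgan.cgan_loss(0.0, 1.5, 2.0)


class TestEncodeDecode:
    def test_zero_weights_zero_outputs(self):
        params = make_params(3, 4, 2)
        zero_weights(params)
        graph = build_knn_graph(np.array([[0.0, 0], [1, 0], [0, 1]]), 1)
        state = cgan.encode(np.ones((3, 3)), graph, params)
        np.testing.assert_array_equal(state.mu, 0.0)
        np.testing.assert_array_equal(state.logvar, 0.0)
        np.testing.assert_array_equal(
            cgan.decode_expression(np.ones((3, 2)), graph, params), 0.0)

    def test_single_node_hand_computed(self, rng):
        # one spot, empty adjacency: attention softmax over the self-loop is 1,
        # so a GATv2 layer reduces to x ↦ W_r x + bias (then the activation)
        params = make_params(2, 3, 2, seed=3)
        x = rng.normal(size=(1, 2))
        A = np.zeros((1, 1))

        def layer_fwd(layer, v, act):
            out = v @ layer.W_r.data + layer.bias.data
            if act:
                out = np.where(out < 0, np.expm1(out), out)
            return out

        h = layer_fwd(params.enc0, x, True)
        mu_hand = layer_fwd(params.enc_mu, h, False)
        state = cgan.encode(x, A, params)
        np.testing.assert_allclose(state.mu, mu_hand, atol=1e-12)

    def test_spot_permutation_equivariance(self, rng):
        params = make_params(5, 6, 3, seed=4)
        coords = rng.uniform(0, 4, size=(12, 2))
        graph = build_knn_graph(coords, 3)
        X = rng.normal(size=(12, 5))
        perm = rng.permutation(12)
        state = cgan.encode(X, graph, params)
        A_p = graph.adjacency[np.ix_(perm, perm)]
        state_p = cgan.encode(X[perm], A_p, params)
        np.testing.assert_allclose(state_p.mu, state.mu[perm], atol=1e-9)
        x_hat = cgan.decode_expression(state.z, graph, params)
        x_hat_p = cgan.decode_expression(state.z[perm], A_p, params)
        np.testing.assert_allclose(x_hat_p, x_hat[perm], atol=1e-9)

    def test_dimension_mismatch(self):
        params = make_params(3, 4, 2)
        with pytest.raises(ValueError):
            cgan.encode(np.ones((3, 5)), np.zeros((3, 3)), params)


class TestCycleForward:
    def test_identity_toy_back_embedding_equals_z(self):
        # hand-set 1-gene, 1-spot network that behaves as the identity
        params = make_params(1, 1, 1)
        zero_weights(params)
        for layer in (params.enc0, params.enc_mu, params.dec1, params.dec2):
            layer.W_r.data[...] = 1.0
        x = np.array([[2.5]])
        state, recon, back = cgan.cycle_forward(x, np.zeros((1, 1)), params)
        np.testing.assert_allclose(recon.x_hat, x)
        np.testing.assert_allclose(back.z, state.z)

    def test_shapes_and_zero_weights(self, rng):
        params = make_params(4, 5, 3, seed=9)
        zero_weights(params)
        graph = build_knn_graph(rng.uniform(0, 3, size=(6, 2)), 2)
        state, recon, back = cgan.cycle_forward(rng.normal(size=(6, 4)), graph, params)
        assert back.z.shape == state.z.shape == (6, 3)
        np.testing.assert_array_equal(state.mu, 0.0)
        np.testing.assert_array_equal(back.mu, 0.0)
        assert recon.a_hat.shape == (6, 6)


class TestPretrain:
    @pytest.fixture
    def small_data(self):
        cfg = sp.SimulationConfig(n_types=3, n_cells=120, n_genes=60,
                                  n_markers_per_type=5, grid_side=7,
                                  cells_per_spot=4, seed=5)
        _, st, _ = sp.simulate_pair(cfg)
        from spotcycle import io as scio
        X = scio.standardize_genes(
            scio.normalize_expression(st.expression, target_sum=1e4))
        return X, build_knn_graph(st.coordinates, 6)

    def test_zero_epochs_leaves_parameters(self, small_data):
        X, graph = small_data
        cfg = sp.RunConfig(epochs_vgae=0, epochs_cgan=0, d_hidden=8, d_latent=4)
        params = make_params(X.shape[1], 8, 4)
        before = params.state_arrays()
        trace = cgan.pretrain(X, graph, params, cfg)
        assert trace.empty
        for a, b in zip(before, params.state_arrays()):
            np.testing.assert_array_equal(a, b)

    def test_loss_decreases_substantially(self, small_data):
        X, graph = small_data
        cfg = sp.RunConfig(epochs_vgae=100, epochs_cgan=0, no_cyc=True,
                           d_hidden=32, d_latent=8)
        params = make_params(X.shape[1], 32, 8, seed=2)
        trace = cgan.pretrain(X, graph, params, cfg,
                              np.random.default_rng(0))
        v = trace[trace.stage == "vgae"].L_re.to_numpy()
        assert v[-1] < v[0]
        assert v[-1] <= 0.85 * v[0]  # at least a 15% drop in 100 epochs

    def test_deterministic_given_seed(self, small_data):
        X, graph = small_data
        cfg = sp.RunConfig(epochs_vgae=5, epochs_cgan=3, d_hidden=8, d_latent=4,
                           d_disc=8)
        traces = []
        for _ in range(2):
            params = make_params(X.shape[1], 8, 4, seed=11)
            traces.append(cgan.pretrain(X, graph, params, cfg,
                                        np.random.default_rng(42)))
        pd.testing.assert_frame_equal(traces[0], traces[1])

    def test_adversarial_stage_records_all_losses(self, small_data):
        X, graph = small_data
        cfg = sp.RunConfig(epochs_vgae=2, epochs_cgan=2, d_hidden=8, d_latent=4,
                           d_disc=8)
        params = make_params(X.shape[1], 8, 4)
        trace = cgan.pretrain(X, graph, params, cfg, np.random.default_rng(0))
        cg = trace[trace.stage == "cgan"]
        assert len(cg) == 2
        assert cg[["L_re", "L_d", "L_cyc"]].notna().all().all()
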