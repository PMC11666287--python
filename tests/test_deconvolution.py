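"""Mapping-matrix operations, the spatial contrastive loss and the filter."""

import numpy as np
import pytest

import spotcycle as sp
from spotcycle import deconvolution as dec
from spotcycle.datasets import AnnotationMatrix
from spotcycle.graph import SpatialGraph, build_knn_graph
from spotcycle.nn import NetworkParameters


def sigm(x):
    return 1 / (1 + np.exp(-x))


class TestNormalizeMapping:
    def test_constant_logits_uniform(self):
        M = dec.normalize_mapping(np.zeros((5, 3)))
        np.testing.assert_allclose(M, 1 / 5)

    def test_saturation(self):
        logits = np.zeros((4, 2))
        logits[2, 1] = 1000.0
        M = dec.normalize_mapping(logits)
        np.testing.assert_allclose(M[2, 1], 1.0)

    def test_columns_sum_to_one(self, rng):
        M = dec.normalize_mapping(rng.normal(size=(5, 3)) * 10)
        np.testing.assert_allclose(M.sum(axis=0), 1.0, atol=1e-6)
        assert (M >= 0).all()


class TestProjectScToSt:
    def test_identity_mapping(self):
        X_sc = np.array([[1.0, 2], [3, 4]])
        np.testing.assert_array_equal(dec.project_sc_to_st(np.eye(2), X_sc), X_sc)

    def test_uniform_mapping_gives_mean_profile(self, rng):
        X_sc = rng.normal(size=(6, 4))
        M = np.full((6, 3), 1 / 6)
        P = dec.project_sc_to_st(M, X_sc)
        for j in range(3):
            np.testing.assert_allclose(P[j], X_sc.mean(axis=0), atol=1e-12)

    def test_convexity_bounds(self, rng):
        X_sc = rng.normal(size=(8, 5))
        M = dec.normalize_mapping(rng.normal(size=(8, 4)))
        P = dec.project_sc_to_st(M, X_sc)
        assert (P <= X_sc.max(axis=0) + 1e-12).all()
        assert (P >= X_sc.min(axis=0) - 1e-12).all()

    def test_triple_loop_oracle(self, rng):
        M = dec.normalize_mapping(rng.normal(size=(10, 8)))
        X_sc = rng.normal(size=(10, 4))
        P = dec.project_sc_to_st(M, X_sc)
        expected = np.zeros((8, 4))
        for j in range(8):
            for g in range(4):
                for i in range(10):
                    expected[j, g] += M[i, j] * X_sc[i, g]
        np.testing.assert_allclose(P, expected, atol=1e-10)


class TestSpatialRegularization:
    def test_mutual_neighbors_identical_unit_embeddings(self):
        graph = SpatialGraph(np.array([[0.0, 1], [1, 0]]), 1)
        p_z = np.array([[1.0, 0], [1.0, 0]])
        val = dec.spatial_regularization_loss(p_z, graph, negatives="all")
        np.testing.assert_allclose(val, -2 * np.log(sigm(1.0)), rtol=1e-9)

    def test_non_neighbors_orthogonal(self):
        graph = SpatialGraph(np.zeros((2, 2)), 1)
        p_z = np.array([[1.0, 0], [0, 1.0]])
        val = dec.spatial_regularization_loss(p_z, graph, negatives="all")
        np.testing.assert_allclose(val, 2 * np.log(2), rtol=1e-9)

    def test_decreases_as_neighbor_similarity_rises(self):
        graph = SpatialGraph(np.array([[0.0, 1], [1, 0]]), 1)
        base = np.array([[1.0, 0.0], [0.0, 1.0]])
        closer = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert (dec.spatial_regularization_loss(closer, graph, "all")
                < dec.spatial_regularization_loss(base, graph, "all"))

    def test_zero_norm_rows_warn(self):
        graph = SpatialGraph(np.array([[0.0, 1], [1, 0]]), 1)
        with pytest.warns(UserWarning, match="zero-norm"):
            dec.spatial_regularization_loss(np.zeros((2, 2)), graph, "all")

    def test_sampled_negatives_deterministic(self, rng):
        coords = rng.uniform(0, 5, size=(15, 2))
        graph = build_knn_graph(coords, 3)
        p_z = rng.normal(size=(15, 4))
        v1 = dec.spatial_regularization_loss(p_z, graph, negatives=3,
                                             rng=np.random.default_rng(7))
        v2 = dec.spatial_regularization_loss(p_z, graph, negatives=3,
                                             rng=np.random.default_rng(7))
        assert v1 == v2 and np.isfinite(v1)


def test_mapping_loss_arithmetic(rng):
    x_hat = rng.normal(size=(2, 3))
    assert dec.mapping_loss(0.4, 0.1, x_hat, x_hat, 1.0) == pytest.approx(0.5)
    P = x_hat + 1.0
    assert dec.mapping_loss(0.4, 0.1, x_hat, P, 0.0) == pytest.approx(0.5)
    # one spot, squared difference summing to 3 after the per-spot reduction
    xh = np.array([[0.0, 0.0]])
    pst = np.array([[np.sqrt(3.0), 0.0]])
    np.testing.assert_allclose(dec.mapping_loss(0.5, 0.2, xh, pst, 1.0), 3.7)
    with pytest.raises(ValueError):
        dec.mapping_loss(0.0, 0.0, x_hat, P, -1.0)


class TestFitMapping:
    @pytest.fixture
    def setting(self, rng):
        coords = rng.uniform(0, 4, size=(9, 2))
        graph = build_knn_graph(coords, 3)
        params = NetworkParameters.init(6, 8, 4, np.random.default_rng(0), 8)
        X_sc = rng.normal(size=(20, 6))
        x_hat = rng.normal(size=(9, 6))
        return X_sc, x_hat, graph, params

    def test_zero_epochs_returns_seeded_init(self, setting):
        X_sc, x_hat, graph, params = setting
        cfg = sp.RunConfig(epochs_mapping=0, d_hidden=8, d_latent=4)
        M, trace = dec.fit_mapping(X_sc, x_hat, graph, params, cfg,
                                   np.random.default_rng(3))
        expected = np.random.default_rng(3).standard_normal((20, 9))
        np.testing.assert_array_equal(M.logits, expected)
        assert trace.empty

    def test_column_stochastic_after_fitting(self, setting):
        X_sc, x_hat, graph, params = setting
        cfg = sp.RunConfig(epochs_mapping=5, d_hidden=8, d_latent=4,
                           reg_negatives=2)
        M, trace = dec.fit_mapping(X_sc, x_hat, graph, params, cfg,
                                   np.random.default_rng(3))
        np.testing.assert_allclose(M.matrix.sum(axis=0), 1.0, atol=1e-6)
        assert (M.matrix >= 0).all()
        assert len(trace) == 5

    def test_bitwise_deterministic_trace(self, setting):
        X_sc, x_hat, graph, params = setting
        cfg = sp.RunConfig(epochs_mapping=4, d_hidden=8, d_latent=4,
                           reg_negatives=2)
        runs = [dec.fit_mapping(X_sc, x_hat, graph, params, cfg,
                                np.random.default_rng(5)) for _ in range(2)]
        np.testing.assert_array_equal(runs[0][0].logits, runs[1][0].logits)
        assert runs[0][1].equals(runs[1][1])

    def test_network_weights_stay_frozen(self, setting):
        X_sc, x_hat, graph, params = setting
        before = params.state_arrays()
        cfg = sp.RunConfig(epochs_mapping=3, d_hidden=8, d_latent=4,
                           reg_negatives=2)
        dec.fit_mapping(X_sc, x_hat, graph, params, cfg, np.random.default_rng(1))
        for a, b in zip(before, params.state_arrays()):
            np.testing.assert_array_equal(a, b)


class TestProjectAnnotations:
    def test_hand_column(self):
        M = np.array([[0.2, 0.7], [0.8, 0.3]])
        S = np.array([[1.0, 0], [0, 1.0]])  # labels (A, B)
        P = dec.project_annotations(M, S, annot_labels=np.array(["A", "B"]))
        np.testing.assert_allclose(P.matrix[1], [0.7, 0.3])

    def test_identity(self):
        P = dec.project_annotations(np.eye(3), np.eye(3))
        np.testing.assert_array_equal(P.matrix, np.eye(3))

    def test_rows_conserve_probability(self, rng):
        M = dec.normalize_mapping(rng.normal(size=(12, 6)))
        labels = rng.integers(0, 3, size=12)
        S = np.zeros((12, 3))
        S[np.arange(12), labels] = 1.0
        P = dec.project_annotations(M, S)
        np.testing.assert_allclose(P.matrix.sum(axis=1), 1.0, atol=1e-6)

    def test_triple_loop_oracle(self, rng):
        M = dec.normalize_mapping(rng.normal(size=(10, 8)))
        labels = rng.integers(0, 4, size=10)
        S = np.zeros((10, 4))
        S[np.arange(10), labels] = 1.0
        P = dec.project_annotations(M, S).matrix
        expected = np.zeros((8, 4))
        for j in range(8):
            for a in range(4):
                for i in range(10):
                    expected[j, a] += M[i, j] * S[i, a]
        np.testing.assert_allclose(P, expected, atol=1e-10)


class TestFilterTopAnnotations:
    def labels(self, n):
        return np.array([f"t{i}" for i in range(n)], dtype=object)

    def test_keep_one_renormalize(self):
        P = dec.SpotAnnotationProbabilities(np.array([[0.5, 0.3, 0.2]]),
                                            self.labels(3))
        out = dec.filter_top_annotations(P, 0.15)
        np.testing.assert_array_equal(out.matrix, [[1.0, 0, 0]])

    def test_fraction_one_is_identity(self, rng):
        mat = dec.normalize_mapping(rng.normal(size=(4, 5))).T
        P = dec.SpotAnnotationProbabilities(mat, self.labels(4))
        out = dec.filter_top_annotations(P, 1.0)
        np.testing.assert_array_equal(out.matrix, mat)

    def test_tie_goes_to_lower_index(self):
        P = dec.SpotAnnotationProbabilities(np.full((1, 4), 0.25), self.labels(4))
        out = dec.filter_top_annotations(P, 0.15)
        np.testing.assert_array_equal(out.matrix, [[1.0, 0, 0, 0]])

    def test_ceiling_rule_keeps_two_of_ten(self, rng):
        row = rng.dirichlet(np.ones(10))
        P = dec.SpotAnnotationProbabilities(row[None, :], self.labels(10))
        out = dec.filter_top_annotations(P, 0.15)  # ceil(1.5) = 2 retained
        assert (out.matrix > 0).sum() == 2
        np.testing.assert_allclose(out.matrix.sum(), 1.0)
        kept = np.argsort(-row)[:2]
        np.testing.assert_allclose(out.matrix[0, kept],
                                   row[kept] / row[kept].sum())

    def test_invalid_fraction(self):
        P = dec.SpotAnnotationProbabilities(np.array([[1.0]]), self.labels(1))
        with pytest.raises(ValueError):
            dec.filter_top_annotations(P, 0.0)
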