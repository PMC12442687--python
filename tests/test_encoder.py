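"""GIN layers, subgraph extraction and readout strategies."""

import numpy as np
import pytest
import scipy.sparse as sp
from scipy.sparse.csgraph import shortest_path

from pairprompt.encoder import (
    EncoderParams,
    Subgraph,
    base_readouts,
    concat_states,
    encode,
    extract_subgraph,
    gin_layer,
    init_encoder_params,
    init_features,
    readout,
    readout_matrix,
)
from pairprompt.graph_construction import build_pair_nodes, connect_shared_entity
from tests.conftest import interactions_frame


def path_graph():
    """Three pair nodes forming the path 0 - 1 - 2 via shared entities."""
    df = interactions_frame(
        [
            ("d1", "drug", "p1", "protein", "dp"),
            ("d1", "drug", "p2", "protein", "dp"),
            ("d2", "drug", "p2", "protein", "dp"),
        ]
    )
    return connect_shared_entity(build_pair_nodes(df, seed=0))


class TestGinLayer:
    def setup_method(self):
        g = path_graph()
        self.adj = g.adjacency_matrix()

    def test_identity_mlp_eps_zero(self):
        h = np.array([[1.0], [2.0], [3.0]])
        out = gin_layer(h, self.adj, eps=0.0, mlp=None)
        np.testing.assert_allclose(out[:, 0], [1 + 2, 2 + 1 + 3, 3 + 2])

    def test_identity_mlp_eps_one(self):
        h = np.array([[1.0], [2.0], [3.0]])
        out = gin_layer(h, self.adj, eps=1.0, mlp=None)
        assert out[1, 0] == pytest.approx(2 * 2 + 4)

    def test_isolated_node_unchanged(self):
        adj = sp.csr_matrix((1, 1))
        h = np.array([[7.0, -2.0]])
        np.testing.assert_allclose(gin_layer(h, adj, eps=0.0), h)

    def test_nonfinite_input_rejected(self):
        h = np.array([[np.nan], [0.0], [0.0]])
        with pytest.raises(FloatingPointError):
            gin_layer(h, self.adj)


class TestEncode:
    def test_single_layer_reduces_to_gin_layer(self):
        g = path_graph()
        params = init_encoder_params(g, input_dim=4, hidden_dim=3, num_layers=1, seed=0)
        (h1,) = encode(g, params)
        h0 = params.features @ params.proj_w + params.proj_b

        def mlp(x):
            return (
                np.maximum(x @ params.mlp_w1[0] + params.mlp_b1[0], 0.0)
                @ params.mlp_w2[0]
                + params.mlp_b2[0]
            )

        expected = gin_layer(h0, g.adjacency_matrix(), params.eps[0], mlp)
        np.testing.assert_allclose(h1, expected)

    def test_permutation_equivariance(self, small_model):
        from pairprompt.graph_construction import EntityPairNode, connect_shared_entity

        g = small_model.graph
        n = g.n_nodes
        rng = np.random.default_rng(0)
        perm = rng.permutation(n)
        permuted_nodes = sorted(
            (
                EntityPairNode(int(perm[v.node_id]), v.entity_a, v.entity_b,
                               v.pair_type, v.label)
                for v in g.nodes
            ),
            key=lambda v: v.node_id,
        )
        gp = connect_shared_entity(permuted_nodes)
        params = init_encoder_params(g, 8, 4, 2, seed=3)
        params_p = params.copy()
        params_p.features = params.features[np.argsort(perm)][:]
        # rows of the permuted feature table follow the permuted node ids
        params_p.features = np.empty_like(params.features)
        params_p.features[perm] = params.features
        out = concat_states(encode(g, params))
        out_p = concat_states(encode(gp, params_p))
        np.testing.assert_allclose(out_p[perm], out, atol=1e-10)

    def test_zero_mlps_give_zero_states(self):
        g = path_graph()
        params = init_encoder_params(g, 4, 3, 2, seed=0)
        for k in range(2):
            params.mlp_w1[k][:] = 0
            params.mlp_w2[k][:] = 0
            params.mlp_b1[k][:] = 0
            params.mlp_b2[k][:] = 0
        states = encode(g, params)
        for h in states:
            np.testing.assert_allclose(h, 0.0)


class TestInitFeatures:
    def test_deterministic(self, small_model):
        a = init_features(small_model.graph, 16, seed=5)
        b = init_features(small_model.graph, 16, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_shape(self, small_model):
        assert init_features(small_model.graph, 32, seed=0).shape == (
            small_model.graph.n_nodes,
            32,
        )

    def test_gaussian_mean(self, small_model):
        table = init_features(small_model.graph, 64, seed=1)
        n = table.size
        assert abs(table.mean()) < 3.0 / np.sqrt(n)

    def test_invalid_dim(self, small_model):
        with pytest.raises(ValueError):
            init_features(small_model.graph, 0, seed=0)


class TestExtractSubgraph:
    def test_delta_zero(self):
        g = path_graph()
        sub = extract_subgraph(g, 1, 0)
        assert sub.members == frozenset({1}) and not sub.induced_edges

    def test_star_center_one_hop(self):
        df = interactions_frame(
            [("d1", "drug", f"p{i}", "protein", "dp") for i in range(4)]
        )
        g = connect_shared_entity(build_pair_nodes(df, seed=0))
        sub = extract_subgraph(g, 0, 1)
        assert sub.members == frozenset(range(4))

    def test_matches_shortest_path_oracle(self, small_model):
        g = small_model.graph
        dist = shortest_path(g.adjacency_matrix(), unweighted=True)
        rng = np.random.default_rng(2)
        for v in rng.choice(g.n_nodes, size=12, replace=False):
            for delta in (1, 2, 3):
                sub = extract_subgraph(g, int(v), delta)
                oracle = set(np.flatnonzero(dist[v] <= delta))
                assert sub.members == frozenset(oracle)

    def test_delta_beyond_diameter_gives_component(self):
        g = path_graph()
        sub = extract_subgraph(g, 0, 10)
        assert sub.members == frozenset({0, 1, 2})
        assert sub.induced_edges == frozenset({(0, 1), (1, 2)})

    def test_missing_node(self):
        with pytest.raises(KeyError):
            extract_subgraph(path_graph(), 99, 1)


class TestReadout:
    def setup_method(self):
        self.sub = Subgraph(0, 1, frozenset({0, 1}), frozenset({(0, 1)}))
        self.reps = np.array([[1.0, 1.0], [2.0, 0.0]])

    def test_sum_counts_center_twice(self):
        np.testing.assert_allclose(
            readout(self.sub, self.reps, "sum"), [4.0, 2.0]
        )

    def test_center_once_variant(self):
        np.testing.assert_allclose(
            readout(self.sub, self.reps, "sum", center_once=True), [3.0, 1.0]
        )

    def test_feature_weighted_sum_identity_equals_sum(self):
        out = readout(self.sub, self.reps, "feature_weighted_sum", np.eye(2))
        np.testing.assert_allclose(out, readout(self.sub, self.reps, "sum"))

    def test_linear_in_weight(self):
        w = np.random.default_rng(0).standard_normal((2, 2))
        one = readout(self.sub, self.reps, "feature_weighted_sum", w)
        two = readout(self.sub, self.reps, "feature_weighted_sum", 2 * w)
        np.testing.assert_allclose(two, 2 * one)

    def test_linear_mean_is_mean_then_map(self):
        w = np.eye(2)
        out = readout(self.sub, self.reps, "linear_mean", w)
        np.testing.assert_allclose(out, np.array([4.0, 2.0]) / 3.0)

    def test_zero_reps_zero_readout(self):
        reps = np.zeros((2, 2))
        for strategy in ("sum", "linear_mean", "feature_weighted_sum"):
            out = readout(self.sub, reps, strategy, np.eye(2))
            np.testing.assert_allclose(out, 0.0)

    def test_missing_weight_rejected(self):
        with pytest.raises(ValueError, match="requires"):
            readout(self.sub, self.reps, "feature_weighted_sum")

    def test_readout_matrix_agrees_with_per_node_readout(self, small_model):
        g = small_model.graph
        reps = np.random.default_rng(1).standard_normal((g.n_nodes, 3))
        S = readout_matrix(g, delta=1)
        batched = S @ reps
        for v in (0, 5, g.n_nodes - 1):
            single = readout(extract_subgraph(g, v, 1), reps, "sum")
            np.testing.assert_allclose(batched[v], single)


class TestParamsSerialization:
    def test_save_load_bit_exact(self, small_model, tmp_path):
        params = init_encoder_params(small_model.graph, 8, 4, 3, seed=9)
        path = tmp_path / "encoder.npz"
        params.save(path)
        loaded = EncoderParams.load(path)
        assert loaded.digest() == params.digest()
        np.testing.assert_array_equal(loaded.features, params.features)

    def test_digest_sensitive_to_parameters(self, small_model):
        a = init_encoder_params(small_model.graph, 8, 4, 3, seed=9)
        b = a.copy()
        b.proj_w[0, 0] += 1e-12
        assert a.digest() != b.digest()


def test_base_readouts_consistency(small_results):
    base = small_results.readouts()
    g = small_results.model.graph
    states = concat_states(encode(g, small_results.params))
    v = 3
    np.testing.assert_allclose(
        base.rep[v], readout(extract_subgraph(g, v, 1), states, "sum")
    )
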