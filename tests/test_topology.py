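"""Topological feature definitions against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from parenclitic import (ParencliticNetwork, ValidationError,
                         betweenness_centrality, degree_centrality,
                         eccentricity, eigenvector_centrality,
                         feature_group_test, feature_matrix, node_degree,
                         second_order_centrality)
from parenclitic.topology import FeatureMatrix
from oracles import (betweenness_bruteforce, eccentricity_bruteforce,
                     mannwhitney_exact_p, return_time_sds)


def _net(weights, sample_id="s"):
    w = np.asarray(weights, dtype=float)
    nodes = [chr(ord("A") + i) for i in range(w.shape[0])]
    return ParencliticNetwork(sample_id, nodes, w)


def _random_net(rng, k=6, low=0.1, high=2.0, sample_id="s"):
    w = rng.uniform(low, high, size=(k, k))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0.0)
    return _net(w, sample_id)


TRIANGLE = _net([[0, 1, 2], [1, 0, 3], [2, 3, 0]])
PATHY = _net([[0, 1, 5], [1, 0, 1], [5, 1, 0]])  # A-B=1, B-C=1, A-C=5


class TestDegree:
    def test_triangle_hand_sums(self):
        assert node_degree(TRIANGLE).tolist() == [3.0, 4.0, 5.0]

    def test_all_zero_weights(self):
        assert node_degree(_net(np.zeros((4, 4)))).tolist() == [0.0] * 4

    def test_degree_conservation(self, rng):
        for _ in range(50):
            net = _random_net(rng, k=int(rng.integers(3, 12)))
            total = node_degree(net).sum()
            assert abs(total - 2 * net.condensed().sum()) < 1e-9

    def test_scaling_is_linear(self, rng):
        net = _random_net(rng)
        scaled = _net(net.weights * 3.0)
        assert np.allclose(node_degree(scaled), 3.0 * node_degree(net))


class TestDegreeCentrality:
    def test_complete_graph_all_one(self, rng):
        net = _random_net(rng, k=5)
        assert degree_centrality(net).tolist() == [1.0] * 5

    def test_star_above_threshold(self):
        k = 5
        w = np.full((k, k), 0.5)  # exactly at the threshold: not counted
        np.fill_diagonal(w, 0.0)
        w[0, 1:] = w[1:, 0] = 2.0  # star edges from the hub
        net = _net(w)
        dc = degree_centrality(net, presence_threshold=0.5)
        assert dc.iloc[0] == 1.0
        assert np.allclose(dc.iloc[1:], 1 / (k - 1))

    def test_matches_direct_count(self, rng):
        for _ in range(20):
            net = _random_net(rng, k=7, low=0.0, high=1.0)
            eps = 0.5
            dc = degree_centrality(net, presence_threshold=eps)
            manual = [(sum(net.weights[i, j] > eps for j in range(7) if j != i)) / 6
                      for i in range(7)]
            assert np.allclose(dc.to_numpy(), manual)

    def test_threshold_invariant_to_scaling_at_zero(self, rng):
        net = _random_net(rng)
        scaled = _net(net.weights * 7.0)
        assert np.allclose(degree_centrality(net), degree_centrality(scaled))


class TestEigenvector:
    def test_symmetric_two_node_graph(self):
        net = _net([[0, 1], [1, 0]])
        assert np.allclose(eigenvector_centrality(net), 1 / np.sqrt(2))

    def test_eigen_residual(self, rng):
        for _ in range(10):
            net = _random_net(rng)
            x = eigenvector_centrality(net).to_numpy()
            lam = x @ net.weights @ x
            assert np.linalg.norm(net.weights @ x - lam * x) < 1e-7
            assert np.all(x >= 0)
            assert np.linalg.norm(x) == pytest.approx(1.0, abs=1e-9)

    def test_label_permutation_equivariance(self, rng):
        net = _random_net(rng, k=6)
        perm = rng.permutation(6)
        permuted = _net(net.weights[np.ix_(perm, perm)])
        a = eigenvector_centrality(net).to_numpy()
        b = eigenvector_centrality(permuted).to_numpy()
        assert np.allclose(a[perm], b, atol=1e-8)

    def test_matches_networkx(self, rng):
        import networkx as nx

        net = _random_net(rng)
        ours = eigenvector_centrality(net)
        ref = nx.eigenvector_centrality_numpy(net.to_networkx(), weight="weight")
        ref = np.array([ref[v] for v in net.nodes])
        ref = np.abs(ref) / np.linalg.norm(ref)
        assert np.allclose(ours.to_numpy(), ref, atol=1e-6)


class TestBetweenness:
    def test_bridge_node_carries_all_paths(self):
        bc = betweenness_centrality(PATHY)
        assert bc.tolist() == [0.0, 1.0, 0.0]

    def test_equal_weight_complete_graph_is_zero(self):
        w = np.full((5, 5), 2.0)
        np.fill_diagonal(w, 0.0)
        assert betweenness_centrality(_net(w)).tolist() == [0.0] * 5

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(10):
            net = _random_net(rng, k=6)
            assert np.allclose(betweenness_centrality(net).to_numpy(),
                               betweenness_bruteforce(net.weights), atol=1e-9)

    def test_zero_weight_edges_rejected(self):
        w = np.array([[0, 0, 1], [0, 0, 1], [1, 1, 0]], dtype=float)
        with pytest.raises(ValidationError, match="ill-posed"):
            betweenness_centrality(_net(w))


class TestEccentricity:
    def test_triangle_routing(self):
        assert eccentricity(PATHY).tolist() == [2.0, 1.0, 2.0]

    def test_equal_weight_complete_graph(self):
        w = np.full((4, 4), 0.7)
        np.fill_diagonal(w, 0.0)
        assert np.allclose(eccentricity(_net(w)), 0.7)

    def test_matches_floyd_warshall(self, rng):
        for _ in range(10):
            net = _random_net(rng, k=6)
            assert np.allclose(eccentricity(net).to_numpy(),
                               eccentricity_bruteforce(net.weights), atol=1e-9)

    def test_scales_with_weights(self, rng):
        net = _random_net(rng)
        scaled = _net(net.weights * 4.0)
        assert np.allclose(eccentricity(scaled), 4.0 * eccentricity(net))
        # path structure, hence betweenness, is scale-invariant
        assert np.allclose(betweenness_centrality(scaled),
                           betweenness_centrality(net))


class TestSecondOrder:
    def test_two_node_alternation_has_zero_sd(self):
        net = _net([[0, 1], [1, 0]])
        assert np.allclose(second_order_centrality(net), 0.0, atol=1e-9)

    def test_matches_long_simulation(self):
        rng = np.random.default_rng(8)
        net = _random_net(rng, k=5)
        analytic = second_order_centrality(net).to_numpy()
        p = net.weights / net.weights.sum(axis=1, keepdims=True)
        empirical = return_time_sds(p, steps=1_000_000, seed=99)
        assert np.allclose(analytic, empirical, rtol=0.05)
        assert (np.argsort(analytic) == np.argsort(empirical)).all()

    def test_label_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        net = _random_net(rng, k=5)
        perm = rng.permutation(5)
        permuted = _net(net.weights[np.ix_(perm, perm)])
        a = second_order_centrality(net).to_numpy()
        b = second_order_centrality(permuted).to_numpy()
        assert np.allclose(a[perm], b, atol=1e-9)

    def test_disconnected_graph_rejected(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = 1.0
        with pytest.raises(ValidationError):
            second_order_centrality(_net(w))


class TestFeatureMatrix:
    def _nets(self, rng, n=3, k=10):
        return [_random_net(rng, k=k, sample_id=f"s{i}") for i in range(n)]

    def test_shape_and_entries(self, rng):
        nets = self._nets(rng)
        fm = feature_matrix(nets, "degree")
        assert fm.frame.shape == (3, 10)
        for net in nets:
            assert np.allclose(fm.frame.loc[net.sample_id].to_numpy(),
                               node_degree(net).to_numpy())

    def test_mixed_panels_rejected(self, rng):
        nets = self._nets(rng)
        other = _random_net(rng, k=4, sample_id="bad")
        with pytest.raises(ValidationError, match="panel"):
            feature_matrix(nets + [other], "degree")

    def test_file_round_trip(self, rng, tmp_path):
        fm = feature_matrix(self._nets(rng), "degree")
        fm.write(tmp_path / "f.tsv")
        back = FeatureMatrix.read(tmp_path / "f.tsv")
        assert back.name == "degree"
        assert np.allclose(back.frame.to_numpy(), fm.frame.to_numpy())


class TestGroupTest:
    def _fm(self, values, ids):
        return FeatureMatrix(name="degree",
                             frame=pd.DataFrame(values, index=ids,
                                                columns=["cgA", "cgB"]))

    def test_identical_groups_never_reject(self):
        values = np.tile([[1.0, 2.0]], (6, 1))
        fm = self._fm(values, [f"s{i}" for i in range(6)])
        labels = pd.Series(["aggressive"] * 3 + ["non_aggressive"] * 3,
                           index=fm.frame.index)
        out = feature_group_test(fm, labels)
        assert (out["p"] == 1.0).all()
        assert (out["q"] > 0.5).all()

    def test_exact_small_sample_p_value(self):
        fm = self._fm(np.array([[0.1, 0.7], [0.2, 0.8], [0.3, 0.9],
                                [0.7, 0.1], [0.8, 0.2], [0.9, 0.3]]),
                      [f"s{i}" for i in range(6)])
        labels = pd.Series(["aggressive"] * 3 + ["non_aggressive"] * 3,
                           index=fm.frame.index)
        out = feature_group_test(fm, labels)
        expected = mannwhitney_exact_p([0.1, 0.2, 0.3], [0.7, 0.8, 0.9])
        assert expected == pytest.approx(0.1)
        assert np.allclose(out["p"], expected)

    def test_empty_group_rejected(self):
        fm = self._fm(np.ones((3, 2)), ["a", "b", "c"])
        labels = pd.Series(["aggressive"] * 3, index=fm.frame.index)
        with pytest.raises(ValidationError, match="non-empty"):
            feature_group_test(fm, labels)
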