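"""Centrality conventions: strength, betweenness, closeness, expected
influence and bridge metrics."""
import numpy as np
import pytest

from symptomnet.centrality import (
    betweenness_closeness,
    bridge_centrality,
    centrality_table,
    expected_influence,
    node_strength,
)
from symptomnet.ggm import NetworkModel


def _model(weights, communities=None, labels=None):
    W = np.asarray(weights, dtype=float)
    labels = labels or [f"V{i}" for i in range(W.shape[0])]
    return NetworkModel(labels=labels, weights=W, communities=communities or {})


def _path_abc(w_ab=0.5, w_bc=0.4):
    W = np.zeros((3, 3))
    W[0, 1] = W[1, 0] = w_ab
    W[1, 2] = W[2, 1] = w_bc
    return _model(W, labels=["a", "b", "c"])


class TestStrengthAndInfluence:
    def test_isolated_node_zero_and_direct_sum(self):
        net = _path_abc(0.5, 0.3)
        s = node_strength(net)
        assert s["b"] == pytest.approx(0.8)
        iso = _model(np.zeros((3, 3)))
        assert (node_strength(iso) == 0).all()

    def test_sign_cancellation(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.5
        W[1, 2] = W[2, 1] = -0.5
        net = _model(W)
        assert expected_influence(net).iloc[1] == pytest.approx(0.0)
        assert node_strength(net).iloc[1] == pytest.approx(1.0)

    def test_all_positive_equality_and_brute_force(self, cohort_small):
        rng = np.random.default_rng(0)
        W = np.abs(rng.normal(scale=0.1, size=(8, 8)))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0.0)
        net = _model(W)
        assert np.allclose(node_strength(net), np.abs(W).sum(axis=1))
        assert np.allclose(expected_influence(net), node_strength(net))

    def test_strength_sum_is_twice_edge_mass(self):
        rng = np.random.default_rng(1)
        W = rng.normal(scale=0.1, size=(10, 10))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0.0)
        net = _model(W)
        assert node_strength(net).sum() == pytest.approx(
            2 * np.abs(W[np.triu_indices(10, 1)]).sum()
        )


class TestPaths:
    def test_three_node_path_betweenness(self):
        bc = betweenness_closeness(_path_abc())
        assert bc.loc["b", "betweenness"] == 1.0
        assert bc.loc["a", "betweenness"] == 0.0 and bc.loc["c", "betweenness"] == 0.0

    def test_star_center_betweenness(self):
        k = 5
        W = np.zeros((k + 1, k + 1))
        W[0, 1:] = W[1:, 0] = 0.3
        net = _model(W)
        bc = betweenness_closeness(net)
        assert bc.iloc[0]["betweenness"] == k * (k - 1) / 2

    def test_equal_triangle_no_betweenness(self):
        W = np.full((3, 3), 0.5)
        np.fill_diagonal(W, 0.0)
        bc = betweenness_closeness(_model(W))
        assert (bc["betweenness"] == 0).all()

    def test_closeness_is_inverse_total_distance(self):
        net = _path_abc(0.5, 0.4)
        bc = betweenness_closeness(net)
        d_ab, d_bc = 1 / 0.5, 1 / 0.4
        assert bc.loc["a", "closeness"] == pytest.approx(1 / (d_ab + d_ab + d_bc))
        assert bc.loc["b", "closeness"] == pytest.approx(1 / (d_ab + d_bc))

    def test_isolated_node_flagged_zero_closeness(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.5
        bc = betweenness_closeness(_model(W))
        assert bc.iloc[2]["closeness"] == 0.0
        assert bc.attrs["disconnected"]


class TestBridge:
    def test_cross_community_sum(self):
        W = np.zeros((4, 4))
        W[0, 2] = W[2, 0] = 0.06
        W[0, 3] = W[3, 0] = 0.04
        W[0, 1] = W[1, 0] = 0.5      # within-community, excluded
        comm = {"V0": 1, "V1": 1, "V2": 2, "V3": 2}
        net = _model(W, communities=comm)
        b = bridge_centrality(net)
        assert b.loc["V0", "bridge_strength"] == pytest.approx(0.10)

    def test_no_cross_edges_all_zero(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 0.3
        W[2, 3] = W[3, 2] = 0.2
        net = _model(W, communities={"V0": 1, "V1": 1, "V2": 2, "V3": 2})
        assert (bridge_centrality(net)["bridge_strength"] == 0).all()

    def test_single_community_errors(self):
        net = _model(np.zeros((3, 3)), communities={"V0": 1, "V1": 1, "V2": 1})
        with pytest.raises(ValueError):
            bridge_centrality(net)

    def test_bridge_plus_within_equals_strength(self, cohort_small):
        data, truth = cohort_small
        rng = np.random.default_rng(2)
        W = rng.normal(scale=0.08, size=(6, 6))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0.0)
        net = _model(W, communities=truth.communities, labels=truth.labels)
        tab = centrality_table(net)
        within = tab.strength - tab.bridge_strength
        assert (tab.bridge_strength <= tab.strength + 1e-12).all()
        assert np.allclose(within + tab.bridge_strength, tab.strength)

    def test_relabelling_invariance(self):
        rng = np.random.default_rng(3)
        W = rng.normal(scale=0.1, size=(5, 5))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0.0)
        comm = {f"V{i}": 1 if i < 3 else 2 for i in range(5)}
        net = _model(W, communities=comm)
        perm = [3, 1, 4, 0, 2]
        net_p = _model(
            W[np.ix_(perm, perm)],
            communities={f"V{i}": comm[f"V{perm[i]}"] for i in range(5)},
        )
        t1 = centrality_table(net)
        t2 = centrality_table(net_p)
        for row_new, row_old in enumerate(perm):
            assert np.allclose(
                t2.iloc[row_new].to_numpy(), t1.iloc[row_old].to_numpy(), atol=1e-10
            )
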