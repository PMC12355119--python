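"""Graphical lasso, EBIC model selection and network summaries."""
import numpy as np
import pytest

from symptomnet.correlations import correlation_matrix
from symptomnet.ggm import (
    NetworkModel,
    constrained_mle,
    ebic_select,
    estimate_network,
    graphical_lasso,
    network_summary,
    precision_to_partial,
)
from tests.conftest import edge_f1


def _random_corr(p, n, seed):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    return np.corrcoef(X, rowvar=False)


class TestGraphicalLasso:
    def test_identity_input_stays_identity(self):
        for lam in (0.0, 0.05, 0.5):
            assert np.allclose(graphical_lasso(np.eye(4), lam), np.eye(4), atol=1e-8)

    def test_large_penalty_empties_offdiagonal(self):
        S = _random_corr(6, 80, 1)
        lam = np.abs(S - np.diag(np.diag(S))).max() * 1.001
        K = graphical_lasso(S, lam)
        off = K[~np.eye(6, dtype=bool)]
        assert np.abs(off).max() == 0.0

    def test_matches_reference_solver(self):
        from sklearn.covariance import graphical_lasso as sk_glasso

        for seed in (2, 3):
            S = _random_corr(7, 150, seed)
            for lam in (0.05, 0.15):
                K = graphical_lasso(S, lam, tol=1e-8)
                _, K_ref = sk_glasso(S, alpha=lam, tol=1e-8, max_iter=500)
                assert np.allclose(K, K_ref, atol=2e-3)

    def test_diagonal_precision_maps_to_zero_partials(self):
        P = precision_to_partial(np.diag([1.0, 2.0, 3.0]))
        assert np.array_equal(P, np.zeros((3, 3)))


class TestConstrainedMle:
    def test_matches_sample_inverse_on_full_support(self):
        S = _random_corr(5, 200, 4)
        support = ~np.eye(5, dtype=bool)
        K = constrained_mle(S, support)
        assert np.allclose(K, np.linalg.inv(S), atol=1e-6)

    def test_zero_pattern_enforced_and_moments_matched(self):
        S = _random_corr(5, 200, 5)
        support = np.zeros((5, 5), dtype=bool)
        support[0, 1] = support[1, 0] = True
        K = constrained_mle(S, support)
        W = np.linalg.inv(K)
        assert K[0, 2] == 0.0 and K[3, 4] == 0.0
        # matched moments on the support and diagonal
        assert W[0, 1] == pytest.approx(S[0, 1], abs=1e-6)
        assert np.allclose(np.diag(W), np.diag(S), atol=1e-6)


class TestEbicSelect:
    def test_identity_selects_empty_network(self):
        net = ebic_select(np.eye(8), n=500)
        assert np.count_nonzero(net.weights) == 0

    def test_edge_recovery_on_synthetic_truth(self, cohort_small):
        data, truth = cohort_small
        net = estimate_network(data, communities=truth.communities)
        assert edge_f1(net, truth) >= 0.8

    def test_gamma_zero_is_bic_and_denser(self, cohort_small):
        data, truth = cohort_small
        corr = correlation_matrix(data)
        e0 = np.count_nonzero(ebic_select(corr, n=len(data), gamma=0.0).weights) // 2
        e5 = np.count_nonzero(ebic_select(corr, n=len(data), gamma=0.5).weights) // 2
        assert e5 <= e0

    def test_selected_support_reproducible_at_lambda(self, cohort_small):
        data, truth = cohort_small
        corr = correlation_matrix(data)
        net = ebic_select(corr, n=len(data))
        K = graphical_lasso(corr.values, net.lambda_selected)
        np.fill_diagonal(K, 0.0)
        assert np.array_equal(np.abs(K) > 1e-8, np.abs(net.weights) > 0)

    def test_label_equivariance(self, cohort_small):
        data, truth = cohort_small
        net = estimate_network(data)
        perm = list(data.columns[::-1])
        net_p = estimate_network(data[perm])
        idx = [net.labels.index(l) for l in perm]
        assert np.allclose(net_p.weights, net.weights[np.ix_(idx, idx)], atol=1e-6)


class TestNetworkSummary:
    def _model_with_zero_edges(self, p, n_zero, seed=0):
        rng = np.random.default_rng(seed)
        iu = np.triu_indices(p, 1)
        w = rng.uniform(0.05, 0.3, size=iu[0].size)
        w[rng.choice(iu[0].size, size=n_zero, replace=False)] = 0.0
        W = np.zeros((p, p))
        W[iu] = w
        W += W.T
        return NetworkModel(labels=[f"V{i}" for i in range(p)], weights=W)

    @pytest.mark.parametrize(
        "p,n_zero,pct_zero", [(7, 5, 23.81), (13, 29, 37.18)]
    )
    def test_zero_edge_percentages(self, p, n_zero, pct_zero):
        s = network_summary(self._model_with_zero_edges(p, n_zero))
        assert s["pct_zero"] == pct_zero

    def test_twenty_node_possible_edges(self):
        s = network_summary(self._model_with_zero_edges(20, 84))
        assert s["n_possible"] == 190
        assert s["n_nonzero"] == 106 and s["pct_nonzero"] == 55.79

    def test_strongest_edges_sorted(self):
        s = network_summary(self._model_with_zero_edges(6, 3, seed=2))
        mags = [abs(w) for _, _, w in s["strongest_edges"]]
        assert mags == sorted(mags, reverse=True)
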