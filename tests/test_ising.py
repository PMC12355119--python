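"""Ising estimation and simulated interventions."""
import numpy as np
import pandas as pd
import pytest

from symptomnet.ising import (
    dichotomize,
    fit_ising,
    nodewise_predictability,
    rank_consistency,
    rank_targets,
    run_all_interventions,
    simulate_intervention,
)
from symptomnet.synthetic import sample_ising


def _two_node_model(beta=1.0, tau=(-0.5, -0.5), n=5000, seed=0):
    B = np.array([[0.0, beta], [beta, 0.0]])
    data = sample_ising(np.array(tau), B, n, burn_in=1000, seed=seed, labels=["a", "b"])
    return data, B


class TestDichotomize:
    def test_rule_and_degenerate_flagging(self):
        data = pd.DataFrame({"x": [0, 1, 2, 3, 4], "y": [0, 0, 0, 0, 0], "z": [4, 4, 4, 4, 4]})
        out = dichotomize(data)
        assert out["x"].tolist() == [0, 1, 1, 1, 1]
        assert set(out.attrs["degenerate_columns"]) == {"y", "z"}


class TestFitIsing:
    def test_two_node_parameter_recovery(self):
        data, _ = _two_node_model(beta=1.0, n=5000, seed=1)
        model = fit_ising(data, rule="OR")
        assert model.couplings[0, 1] == pytest.approx(1.0, abs=0.25)
        assert model.thresholds[0] == pytest.approx(-0.5, abs=0.25)

    def test_independent_columns_mostly_empty(self):
        rng = np.random.default_rng(2)
        data = pd.DataFrame((rng.random((2000, 6)) < 0.4).astype(int))
        model = fit_ising(data)
        iu = np.triu_indices(6, 1)
        assert np.mean(model.couplings[iu] == 0.0) >= 0.95

    def test_and_rule_subset_of_or_rule(self):
        rng = np.random.default_rng(3)
        z = rng.multivariate_normal(np.zeros(5), np.eye(5) * 0.7 + 0.3, size=600)
        data = pd.DataFrame((z > 0.3).astype(int))
        m_and = fit_ising(data, rule="AND")
        m_or = fit_ising(data, rule="OR")
        assert set(map(tuple, np.argwhere(m_and.couplings != 0))) <= set(
            map(tuple, np.argwhere(m_or.couplings != 0))
        )

    def test_constant_column_rejected(self):
        data = pd.DataFrame({"a": [0, 1, 0, 1], "b": [1, 1, 1, 1]})
        with pytest.raises(ValueError):
            fit_ising(data)


class TestPredictability:
    def test_disconnected_node_near_zero(self):
        rng = np.random.default_rng(4)
        data = pd.DataFrame((rng.random((2000, 4)) < 0.35).astype(int))
        model = fit_ising(data)
        r2 = nodewise_predictability(model, data)
        assert (r2 < 0.05).all()

    def test_strongly_coupled_pair_predictable(self):
        data, _ = _two_node_model(beta=4.0, tau=(-2.0, -2.0), n=4000, seed=5)
        model = fit_ising(data, rule="OR")
        r2 = nodewise_predictability(model, data)
        assert (r2 > 0.5).all()
        assert ((r2 >= 0) & (r2 <= 1)).all()


@pytest.fixture(scope="module")
def fitted():
    data, _ = _two_node_model(beta=1.5, tau=(-1.0, -0.2), n=3000, seed=6)
    return fit_ising(data, rule="OR")


class TestInterventions:
    def test_zero_multiplier_is_exact_control(self, fitted):
        row = simulate_intervention(fitted, "a", "amplify", sd_multiplier=0.0,
                                    n_sim=2000, burn_in=200, seed=7)
        assert row.delta_sum_score == 0.0
        assert (row.delta_prevalence == 0.0).all()

    def test_disconnected_model_localizes_effect(self):
        model = fit_ising(
            pd.DataFrame((np.random.default_rng(8).random((2000, 3)) < 0.4).astype(int))
        )
        model.couplings[:] = 0.0
        row = simulate_intervention(model, model.labels[0], "amplify",
                                    n_sim=4000, burn_in=400, seed=9)
        assert (row.delta_prevalence.iloc[1:] == 0.0).all()
        assert row.delta_sum_score == pytest.approx(row.delta_prevalence.iloc[0])

    def test_amplify_attenuate_opposite_signs(self, fitted):
        up = simulate_intervention(fitted, "b", "amplify", n_sim=4000, burn_in=400, seed=10)
        dn = simulate_intervention(fitted, "b", "attenuate", n_sim=4000, burn_in=400, seed=10)
        assert up.delta_sum_score > 0 > dn.delta_sum_score

    def test_rank_consistency_on_dominant_pair(self, fitted):
        out = rank_consistency(fitted, n_replicates=3, seed=12, n_sim=600, burn_in=100)
        for key in ("aggravation", "alleviation"):
            assert 0 < out[key]["consistency"] <= 1
            assert out[key]["modal_top"] in fitted.labels

    def test_rankings_deterministic_and_consistent(self, fitted):
        res1 = run_all_interventions(fitted, n_sim=1500, burn_in=200, seed=11)
        res2 = run_all_interventions(fitted, n_sim=1500, burn_in=200, seed=11)
        pd.testing.assert_frame_equal(res1, res2)
        ranks = rank_targets(res1)
        agg = ranks["aggravation"]
        assert (agg.direction == "amplify").all()
        assert agg.delta_score.is_monotonic_decreasing
        assert abs(agg.relative_influence.abs().sum() - 1.0) < 1e-9
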