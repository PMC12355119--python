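"""Polychoric estimation, matrix assembly and the redundancy screen."""
import numpy as np
import pandas as pd
import pytest

from symptomnet.bvn import bvn_cdf
from symptomnet.correlations import (
    correlation_matrix,
    goldbricker,
    polychoric_pair,
)


def _discretize(z, cuts):
    return np.searchsorted(np.asarray(cuts), z)


class TestBvn:
    def test_matches_scipy_reference(self):
        from scipy.stats import multivariate_normal

        rng = np.random.default_rng(0)
        for rho in (-0.99, -0.9, -0.5, 0.0, 0.4, 0.93, 0.99):
            h = rng.uniform(-3.5, 3.5, 12)
            k = rng.uniform(-3.5, 3.5, 12)
            ref = [
                multivariate_normal.cdf([a, b], cov=[[1, rho], [rho, 1]])
                for a, b in zip(h, k)
            ]
            assert np.allclose(bvn_cdf(h, k, rho), ref, atol=5e-7)


class TestPolychoric:
    def test_identical_vectors_near_one(self):
        x = np.array([0, 1, 2, 3, 4] * 40)
        with pytest.warns(UserWarning):
            res = polychoric_pair(x, x)
        assert res.rho >= 0.99

    def test_latent_rho_recovered(self):
        rng = np.random.default_rng(1)
        z = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], size=5000)
        cuts = [-0.25, 0.55, 1.15, 1.75]
        res = polychoric_pair(_discretize(z[:, 0], cuts), _discretize(z[:, 1], cuts))
        assert res.rho == pytest.approx(0.5, abs=0.05)
        # thresholds recover the cut points
        assert np.allclose(res.x_thresholds, cuts, atol=0.1)

    def test_symmetry_in_arguments(self):
        rng = np.random.default_rng(2)
        z = rng.multivariate_normal([0, 0], [[1, -0.4], [-0.4, 1]], size=1500)
        x, y = _discretize(z[:, 0], [-0.5, 0.5]), _discretize(z[:, 1], [0.0])
        assert polychoric_pair(x, y).rho == pytest.approx(polychoric_pair(y, x).rho, abs=1e-6)

    def test_constant_variable_errors(self):
        with pytest.raises(ValueError):
            polychoric_pair(np.zeros(100, dtype=int), np.arange(100) % 3)


class TestCorrelationMatrix:
    def test_auto_dispatch(self):
        rng = np.random.default_rng(3)
        ordinal = pd.DataFrame(rng.integers(0, 5, size=(200, 3)), columns=list("abc"))
        continuous = ordinal + rng.normal(size=ordinal.shape)
        assert correlation_matrix(ordinal).method == "polychoric"
        assert correlation_matrix(continuous).method == "pearson"

    def test_null_data_off_diagonals_small_and_psd(self):
        rng = np.random.default_rng(4)
        data = pd.DataFrame(rng.integers(0, 5, size=(5000, 5)))
        corr = correlation_matrix(data)
        off = corr.values[~np.eye(5, dtype=bool)]
        assert np.abs(off).max() < 0.06
        assert np.linalg.eigvalsh(corr.values).min() >= -1e-8
        assert np.allclose(np.diag(corr.values), 1.0)

    def test_column_subset_consistency(self, cohort_small):
        data, _ = cohort_small
        full = correlation_matrix(data)
        cols = list(data.columns[:4])
        sub = correlation_matrix(data[cols])
        # pairwise polychoric estimates do not depend on other columns
        assert np.allclose(sub.values, full.submatrix(cols).values, atol=1e-10)

    def test_constant_column_named_in_error(self):
        data = pd.DataFrame({"a": [1, 2, 3, 4], "b": [2, 2, 2, 2]})
        with pytest.raises(ValueError, match="b"):
            correlation_matrix(data)


class TestGoldbricker:
    def test_duplicated_item_flagged(self):
        rng = np.random.default_rng(5)
        base = rng.multivariate_normal(np.zeros(5), np.eye(5) * 1.0 + 0.3, size=1500)
        cuts = [-0.5, 0.5, 1.0]
        data = pd.DataFrame({f"v{j}": _discretize(base[:, j], cuts) for j in range(5)})
        data["dup"] = data["v0"]
        res = goldbricker(data)
        assert ("v0", "dup", 0.0) in [(a, b, p) for a, b, p in res.redundant_pairs]

    def test_independent_items_not_flagged(self):
        rng = np.random.default_rng(6)
        data = pd.DataFrame(rng.integers(0, 5, size=(2000, 6)))
        assert goldbricker(data).redundant_pairs == []

    def test_high_correlation_with_distinct_neighbourhoods_not_flagged(self):
        # a and b correlate strongly but relate to all others with opposite
        # sign, so their third-party correlation profiles differ everywhere
        rng = np.random.default_rng(7)
        n = 2000
        f = rng.normal(size=n)
        a = f + 0.3 * rng.normal(size=n)
        b = f + 0.3 * rng.normal(size=n)
        others = {f"o{k}": f + rng.normal(size=n) for k in range(4)}
        data = pd.DataFrame({"a": a, "b": -b, **others})
        res = goldbricker(data, method="pearson")
        flagged_pairs = {(x, y) for x, y, _ in res.redundant_pairs}
        assert ("a", "b") not in flagged_pairs

    def test_too_few_third_nodes_errors(self):
        rng = np.random.default_rng(8)
        data = pd.DataFrame(rng.integers(0, 5, size=(200, 4)))
        with pytest.raises(ValueError):
            goldbricker(data)
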