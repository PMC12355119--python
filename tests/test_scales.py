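"""Scale scoring, reliability and sample-size arithmetic."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from symptomnet.scales import (
    ScaleDefinition,
    cronbach_alpha,
    fcri_definition,
    handle_missing,
    network_sample_size,
    pcs_definition,
    reverse_score,
    score_scale,
)


def _pcs_frame(value: int) -> pd.DataFrame:
    d = pcs_definition()
    return pd.DataFrame([[value] * d.n_items], columns=d.item_ids)


class TestScoring:
    @pytest.mark.parametrize("value,total", [(4, 52), (0, 0)])
    def test_pcs_total_bounds(self, value, total):
        out = score_scale(pcs_definition(), _pcs_frame(value))
        assert out["total"].iloc[0] == total

    def test_fcri_all_zero_scores_four_via_reverse_item(self):
        d = fcri_definition()
        data = pd.DataFrame([[0] * 42], columns=d.item_ids)
        out = score_scale(d, data)
        assert out["total"].iloc[0] == 4           # only reversed item 13 contributes
        assert out["F2_severity"].iloc[0] == 4

    def test_subscales_sum_to_total(self):
        d = pcs_definition()
        rng = np.random.default_rng(1)
        data = pd.DataFrame(rng.integers(0, 5, size=(30, 13)), columns=d.item_ids)
        out = score_scale(d, data)
        sub_cols = [c for c in out.columns if c != "total"]
        assert (out[sub_cols].sum(axis=1) == out["total"]).all()

    def test_total_invariant_to_column_order(self):
        d = fcri_definition()
        rng = np.random.default_rng(2)
        data = pd.DataFrame(rng.integers(0, 5, size=(20, 42)), columns=d.item_ids)
        shuffled = data[list(rng.permutation(data.columns))]
        assert (score_scale(d, data)["total"] == score_scale(d, shuffled)["total"]).all()

    @given(st.lists(st.integers(0, 4), min_size=42, max_size=42))
    @settings(max_examples=25, deadline=None)
    def test_reverse_scoring_is_involution(self, row):
        d = fcri_definition()
        data = pd.DataFrame([row], columns=d.item_ids)
        assert reverse_score(d, reverse_score(d, data)).equals(data[d.item_ids])

    def test_out_of_range_and_unknown_item_are_fatal(self):
        d = pcs_definition()
        bad = _pcs_frame(4)
        bad.iloc[0, 0] = 7
        with pytest.raises(ValueError):
            score_scale(d, bad)
        with pytest.raises(KeyError):
            score_scale(d, _pcs_frame(4).drop(columns=["pcs_1"]))

    def test_subscale_overlap_rejected(self):
        with pytest.raises(ValueError):
            ScaleDefinition(
                name="bad",
                item_ids=["a", "b"],
                subscales={"s1": ["a"], "s2": ["a", "b"]},
            )


class TestCronbachAlpha:
    def test_duplicated_columns_give_alpha_one(self):
        rng = np.random.default_rng(3)
        col = rng.integers(0, 5, size=50)
        data = pd.DataFrame({f"i{k}": col for k in range(4)})
        assert cronbach_alpha(data, list(data.columns)) == pytest.approx(1.0)

    def test_toy_matrix_matches_hand_computation(self):
        # items (0,1,2,4) and (1,3,2,4): variances 35/12? no - ddof=1:
        # var_a = 8.75/3, var_b = 5/3, var_total = 24.75/3 -> alpha = 8/9
        data = pd.DataFrame({"a": [0, 1, 2, 4], "b": [1, 3, 2, 4]})
        assert cronbach_alpha(data, ["a", "b"]) == pytest.approx(8.0 / 9.0)

    def test_independent_items_alpha_near_zero(self):
        rng = np.random.default_rng(4)
        data = pd.DataFrame(rng.integers(0, 5, size=(5000, 2)), columns=["a", "b"])
        assert abs(cronbach_alpha(data, ["a", "b"])) < 0.1

    def test_zero_total_variance_errors(self):
        data = pd.DataFrame({"a": [1, 1, 1], "b": [1, 1, 1]})
        with pytest.raises(ValueError):
            cronbach_alpha(data, ["a", "b"])


class TestSampleSize:
    @pytest.mark.parametrize(
        "n_nodes,attrition,field,expected",
        [(20, 0.0, "minimum_n", 210), (20, 0.20, "required_n", 263), (2, 0.0, "minimum_n", 3)],
    )
    def test_worked_examples(self, n_nodes, attrition, field, expected):
        assert network_sample_size(n_nodes, attrition)[field] == expected

    @given(st.integers(2, 200))
    @settings(max_examples=30, deadline=None)
    def test_zero_attrition_closed_form(self, n):
        assert network_sample_size(n, 0.0)["minimum_n"] == n * (n + 1) // 2

    def test_invalid_attrition(self):
        with pytest.raises(ValueError):
            network_sample_size(20, 1.0)


class TestHandleMissing:
    def test_study_scale_retention(self):
        rng = np.random.default_rng(5)
        data = pd.DataFrame(rng.integers(0, 5, size=(363, 10)).astype(float))
        data.iloc[:17, 0] = np.nan
        clean, report = handle_missing(data)
        assert len(clean) == 346
        assert report["pct_dropped"] == 4.7
        assert report["pct_retained"] == 95.3

    def test_no_missing_is_identity(self):
        data = pd.DataFrame({"a": [1, 2, 3], "b": [0, 1, 2]})
        clean, report = handle_missing(data)
        assert clean.equals(data) and report["dropped"] == 0

    def test_small_example_percentage(self):
        data = pd.DataFrame({"a": [1.0] * 9 + [np.nan]})
        clean, report = handle_missing(data)
        assert len(clean) == 9 and report["pct_dropped"] == 10.0

    def test_all_dropped_is_fatal(self):
        with pytest.raises(ValueError):
            handle_missing(pd.DataFrame({"a": [np.nan, np.nan]}))
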