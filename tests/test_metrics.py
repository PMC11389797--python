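import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mucoseq as mq
from mucoseq.exceptions import (
    InsufficientDataError,
    MeasurementValidationError,
    PairingError,
)


def _distance_table(per_mouse_values):
    """Build a long table from {mouse_id: {probe: values}} (group = mouse prefix)."""
    rows = []
    for mouse, probes in per_mouse_values.items():
        for probe, values in probes.items():
            for v in values:
                rows.append(
                    {
                        "mouse_id": mouse,
                        "group": mouse.split("_")[0],
                        "variable": "distance",
                        "probe": probe,
                        "time": np.nan,
                        "value": v,
                    }
                )
    return pd.DataFrame(rows)


class TestDistanceSummary:
    def test_constant_measurements_return_constant(self):
        table = _distance_table({"ctrl_m1": {"p": [7.5] * 25}})
        out = mq.mouse_distance_summary(table)
        assert out["value"].iloc[0] == 7.5

    def test_mean_of_1_to_25_is_13(self):
        table = _distance_table({"ctrl_m1": {"p": list(range(1, 26))}})
        out = mq.mouse_distance_summary(table)
        assert out["value"].iloc[0] == 13.0

    def test_median_option(self):
        table = _distance_table({"ctrl_m1": {"p": list(range(1, 26)) + [1000] * 0}})
        out = mq.mouse_distance_summary(table, statistic="median")
        assert out["value"].iloc[0] == 13.0

    def test_below_minimum_lists_offender(self):
        table = _distance_table(
            {"ctrl_m1": {"p": [1.0] * 25}, "ctrl_m2": {"p": [1.0] * 10}}
        )
        with pytest.raises(MeasurementValidationError, match="ctrl_m2"):
            mq.mouse_distance_summary(table)
        with pytest.warns(UserWarning, match="ctrl_m2"):
            out = mq.mouse_distance_summary(table, allow_below_min=True)
        assert out.shape[0] == 2


class TestTaxaRatio:
    def test_hand_arithmetic(self):
        table = _distance_table(
            {"ctrl_m1": {"num": [10.0] * 25, "den": [40.0] * 25}}
        )
        out = mq.taxa_distance_ratio(table, "num", "den")
        assert out["ratio"].iloc[0] == 0.25

    def test_reciprocal_ratios_multiply_to_one(self):
        rng = np.random.default_rng(0)
        table = _distance_table(
            {
                f"ctrl_m{i}": {
                    "a": rng.gamma(4, 10, 25).tolist(),
                    "b": rng.gamma(4, 25, 25).tolist(),
                }
                for i in range(4)
            }
        )
        ab = mq.taxa_distance_ratio(table, "a", "b").set_index("mouse_id")["ratio"]
        ba = mq.taxa_distance_ratio(table, "b", "a").set_index("mouse_id")["ratio"]
        np.testing.assert_allclose(ab * ba, 1.0)

    def test_missing_probe_raises(self):
        table = _distance_table({"ctrl_m1": {"a": [1.0] * 25}})
        with pytest.raises(MeasurementValidationError, match="'b'"):
            mq.taxa_distance_ratio(table, "a", "b")


class TestGrowthRate:
    def test_flat_series_rate_zero(self):
        series = pd.DataFrame({"time": [0, 15, 30, 45], "value": [80.0] * 4})
        assert mq.mucus_growth_rate(series) == pytest.approx(0.0)

    def test_endpoint_arithmetic(self):
        series = pd.DataFrame({"time": [0.0, 45.0], "value": [100.0, 190.0]})
        assert mq.mucus_growth_rate(series) == pytest.approx(2.0)

    def test_offset_invariance_and_time_scaling(self):
        rng = np.random.default_rng(1)
        t = np.arange(0, 50, 5.0)
        v = 60 + 1.7 * t + rng.normal(0, 1, t.size)
        base = mq.mucus_growth_rate(pd.DataFrame({"time": t, "value": v}))
        shifted = mq.mucus_growth_rate(pd.DataFrame({"time": t, "value": v + 123}))
        stretched = mq.mucus_growth_rate(pd.DataFrame({"time": t * 2, "value": v}))
        assert shifted == pytest.approx(base)
        assert stretched == pytest.approx(base / 2)

    def test_single_time_point_raises(self):
        with pytest.raises(InsufficientDataError):
            mq.mucus_growth_rate(pd.DataFrame({"time": [0.0], "value": [1.0]}))


class TestPairedComparison:
    @staticmethod
    def _rates(pairs):
        rows = []
        for i, (c, t) in enumerate(pairs):
            rows.append({"mouse_id": f"m{i}", "group": "control", "rate": c})
            rows.append({"mouse_id": f"m{i}", "group": "treated", "rate": t})
        return pd.DataFrame(rows)

    def test_identical_pairs_null(self):
        out = mq.paired_secretion_comparison(self._rates([(1, 1), (2, 2), (3, 3)]))
        assert (out["differences"] == 0).all()
        assert out["p_value"] == 1.0

    def test_mean_ratio_two(self):
        out = mq.paired_secretion_comparison(
            self._rates([(2, 1), (2.2, 1.1), (1.8, 0.9)])
        )
        assert out["mean_ratio"] == pytest.approx(2.0)
        assert (out["differences"] < 0).all()  # every treated below control

    def test_unpaired_rows_raise(self):
        rates = self._rates([(1, 2), (3, 4), (5, 6)]).drop(index=5)
        with pytest.raises(PairingError, match="m2"):
            mq.paired_secretion_comparison(rates)

    def test_too_few_pairs_raise(self):
        with pytest.raises(InsufficientDataError):
            mq.paired_secretion_comparison(self._rates([(1, 2), (3, 4)]))


class TestColitis:
    def test_healthy_animal_scores_zero(self):
        rec = mq.ColitisRecord("m1", 0, 0.0, "normal", "none")
        assert mq.dai_score(rec) == 0

    def test_worked_example_scores_eleven(self):
        # 12% weight loss -> 3, diarrhea -> 4, gross bleeding -> 4
        rec = mq.ColitisRecord("m1", 5, -12.0, "diarrhea", "gross")
        assert mq.dai_score(rec) == 11

    def test_maximum_is_twelve(self):
        rec = mq.ColitisRecord("m1", 7, -25.0, "diarrhea", "gross")
        assert mq.dai_score(rec) == 12

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        w=st.floats(-30, 5, allow_nan=False),
        stool=st.sampled_from(["normal", "solid", "loose", "diarrhea"]),
        bleed=st.sampled_from(["none", "occult", "gross"]),
    )
    def test_score_bounded_and_monotone_in_weight_loss(self, w, stool, bleed):
        rec = mq.ColitisRecord("m", 1, w, stool, bleed)
        score = mq.dai_score(rec)
        assert 0 <= score <= 12
        worse = mq.ColitisRecord("m", 1, w - 10, stool, bleed)
        assert mq.dai_score(worse) >= score

    def test_unknown_category_raises(self):
        rec = mq.ColitisRecord("m1", 0, 0.0, "soup", "none")
        with pytest.raises(MeasurementValidationError, match="soup"):
            mq.dai_score(rec)

    def test_ulceration_percent(self):
        assert mq.ulceration_percent(0.0, 5.0) == 0.0
        assert mq.ulceration_percent(2.0, 8.0) == pytest.approx(20.0)
        with pytest.raises(MeasurementValidationError):
            mq.ulceration_percent(0.0, 0.0)


class TestGroupComparison:
    def test_two_groups_use_t_test(self, rng):
        values = pd.Series(np.r_[rng.normal(0, 1, 10), rng.normal(5, 1, 10)])
        groups = pd.Series(["a"] * 10 + ["b"] * 10)
        out = mq.group_comparison(values, groups)
        assert out["test"] == "student_t"
        assert out["p_value"] < 1e-4

    def test_three_groups_use_anova_matching_scipy(self, rng):
        from scipy import stats

        values = pd.Series(rng.normal(0, 1, 30))
        groups = pd.Series(["a", "b", "c"] * 10)
        out = mq.group_comparison(values, groups)
        assert out["test"] == "one_way_anova"
        expected = stats.f_oneway(
            *(values[groups == g].to_numpy() for g in ("a", "b", "c"))
        )
        assert out["p_value"] == pytest.approx(expected.pvalue)

    def test_identical_groups_nonsignificant(self):
        values = pd.Series([1.0, 2.0, 3.0, 4.0] * 3)
        groups = pd.Series(["a"] * 4 + ["b"] * 4 + ["c"] * 4)
        out = mq.group_comparison(values, groups)
        assert out["p_value"] == pytest.approx(1.0)
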