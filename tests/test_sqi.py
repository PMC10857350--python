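"""Indicator scoring (sigmoid limbs, pH optimum) and weighted aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from soilsqi.sqi import (
    DEFAULT_WEIGHTS,
    IndicatorRule,
    MDSConfig,
    aggregate_scores,
    compute_x0,
    default_mds,
    score_indicator,
    score_linear,
    score_ph_optimum,
    score_table,
)

MORE = IndicatorRule("x", "more_is_better", 0.5)
LESS = IndicatorRule("x", "less_is_better", 0.5)


class TestScoreIndicator:
    def test_score_at_center_is_half(self):
        assert score_indicator(4.2, MORE, 4.2) == pytest.approx(0.5, abs=1e-15)
        assert score_indicator(4.2, LESS, 4.2) == pytest.approx(0.5, abs=1e-15)

    def test_double_center_more_is_better(self):
        # 1 / (1 + 2^-2.5)
        assert score_indicator(2.0, MORE, 1.0) == pytest.approx(
            1 / (1 + 2**-2.5)
        )
        assert score_indicator(2.0, MORE, 1.0) == pytest.approx(0.8498, abs=1e-4)

    def test_double_center_less_is_better(self):
        assert score_indicator(2.0, LESS, 1.0) == pytest.approx(1 / (1 + 2**2.5))

    @settings(deadline=None, derandomize=True)
    @given(st.floats(0.01, 100.0))
    def test_complement_identity(self, ratio):
        s_more = score_indicator(ratio, MORE, 1.0)
        s_less = score_indicator(ratio, LESS, 1.0)
        assert s_more + s_less == pytest.approx(1.0, abs=1e-12)
        assert 0 < s_more < 1

    def test_monotonicity(self):
        xs = np.logspace(-2, 2, 201)
        s_more = score_indicator(xs, MORE, 1.0)
        s_less = score_indicator(xs, LESS, 1.0)
        assert np.all(np.diff(s_more) > 0)
        assert np.all(np.diff(s_less) < 0)

    def test_nonpositive_center_rejected(self):
        with pytest.raises(ValueError, match="x0"):
            score_indicator(1.0, MORE, 0.0)

    def test_nonpositive_value_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            score_indicator(-1.0, MORE, 1.0)


class TestPHOptimum:
    RULE = IndicatorRule("pH", "optimum", 0.2, optimum_low=5.5, optimum_high=7.0)

    def test_rising_limb_at_low_edge(self):
        # the rising limb is centred at 5.5, so its own value there is 0.5
        rise_only = IndicatorRule("pH", "more_is_better", 0.2)
        assert score_indicator(5.5, rise_only, 5.5) == pytest.approx(0.5)

    def test_decreasing_above_band(self):
        xs = np.linspace(7.0, 9.07, 50)
        s = score_ph_optimum(xs, self.RULE)
        assert np.all(np.diff(s) < 0)
        assert score_ph_optimum(9.07, self.RULE) < score_ph_optimum(7.0, self.RULE)

    def test_increasing_below_band(self):
        xs = np.linspace(3.29, 5.5, 50)
        s = score_ph_optimum(xs, self.RULE)
        assert np.all(np.diff(s) > 0)

    def test_default_combination_is_continuous(self):
        xs = np.linspace(4.0, 8.5, 2000)
        s = score_ph_optimum(xs, self.RULE)
        assert np.max(np.abs(np.diff(s))) < 0.01

    def test_max_combination_dominates_single_limbs_inside_band(self):
        rule = IndicatorRule(
            "pH", "optimum", 0.2, optimum_low=5.5, optimum_high=7.0,
            optimum_combine="max",
        )
        xs = np.linspace(5.5, 7.0, 31)
        s = score_ph_optimum(xs, rule)
        rise = 1 / (1 + (xs / 5.5) ** -2.5)
        fall = 1 / (1 + (xs / 7.0) ** 2.5)
        assert np.all(s >= rise - 1e-12)
        assert np.all(s >= fall - 1e-12)


class TestX0:
    def test_dataset_mean(self):
        assert compute_x0([2, 4, 6]) == 4.0

    def test_fixed(self):
        assert compute_x0([2, 4, 6], policy="fixed", fixed=6.25) == 6.25

    def test_missing_excluded(self):
        assert compute_x0([2, np.nan, 6]) == 4.0

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            compute_x0([np.nan, np.nan])


class TestAggregation:
    def test_weights_sum_to_one(self):
        assert sum(DEFAULT_WEIGHTS.values()) == pytest.approx(1.0, abs=1e-12)

    def test_all_ones_gives_unity(self):
        mds = default_mds()
        assert aggregate_scores({n: 1.0 for n in mds.names}, mds) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_all_half_gives_half(self):
        mds = default_mds()
        assert aggregate_scores({n: 0.5 for n in mds.names}, mds) == pytest.approx(0.5)

    def test_hand_computed_dot_product(self):
        scores = {"OM": 0.8, "pH": 0.6, "TN": 0.5, "P": 0.4, "K": 0.4,
                  "Ca": 0.3, "Mg": 0.3}
        assert aggregate_scores(scores, default_mds()) == pytest.approx(
            0.585, abs=1e-12
        )

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            MDSConfig(rules=[IndicatorRule("a", "more_is_better", 0.4)])


class TestScoreTable:
    def make_props(self, n=40, seed=0, missing_rate=0.0):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            {
                "OM": rng.lognormal(1, 1, n),
                "pH": rng.uniform(4, 9, n),
                "TN": rng.lognormal(-1.5, 1, n),
                "P": rng.lognormal(2, 1, n),
                "K": rng.lognormal(4, 1, n),
                "Ca": rng.lognormal(8, 1, n),
                "Mg": rng.lognormal(5, 1, n),
            },
            index=[f"S{i}" for i in range(n)],
        )
        if missing_rate:
            df = df.mask(rng.random(df.shape) < missing_rate)
        return df

    def test_sqi_is_weighted_sum_of_scores(self):
        props = self.make_props()
        res = score_table(props, default_mds())
        manual = sum(
            w * res.scores[f"S_{n}"] for n, w in DEFAULT_WEIGHTS.items()
        )
        pd.testing.assert_series_equal(
            res.sqi, manual.rename("SQI"), check_exact=False, atol=1e-12
        )

    def test_scores_and_sqi_in_unit_interval(self):
        res = score_table(self.make_props(seed=3), default_mds())
        s = res.scores.to_numpy()
        assert np.all((s > 0) & (s < 1))
        assert np.all((res.sqi > 0) & (res.sqi < 1))

    def test_complete_case_count(self):
        props = self.make_props(n=200, seed=4, missing_rate=0.05)
        res = score_table(props, default_mds())
        expected = int(props.notna().all(axis=1).sum())
        assert res.n_scored == expected
        assert res.complete.sum() == expected
        assert res.sqi[~res.complete].isna().all()

    def test_renormalize_policy_scores_incomplete_rows(self):
        props = self.make_props(n=100, seed=5, missing_rate=0.1)
        res = score_table(props, default_mds(), missing_policy="renormalize")
        some_present = props.notna().any(axis=1)
        assert res.sqi[some_present].notna().all()
        assert np.all((res.sqi[some_present] > 0) & (res.sqi[some_present] < 1))

    def test_rule_order_irrelevant(self):
        props = self.make_props(seed=6)
        mds = default_mds()
        reordered = MDSConfig(rules=list(reversed(mds.rules)))
        a = score_table(props, mds).sqi
        b = score_table(props, reordered).sqi
        pd.testing.assert_series_equal(a, b)

    def test_monotone_in_more_is_better_indicator(self):
        props = self.make_props(seed=7)
        bumped = props.copy()
        bumped["OM"] *= 1.5
        mds = default_mds()
        a = score_table(props, mds, x0_reference=props).sqi
        b = score_table(bumped, mds, x0_reference=props).sqi
        assert (b >= a - 1e-12).all()

    def test_zero_values_scored_via_floor(self):
        props = self.make_props(seed=8)
        props.loc[props.index[0], "OM"] = 0.0
        res = score_table(props, default_mds())
        s0 = res.scores.loc[props.index[0], "S_OM"]
        assert 0 < s0 < 0.5  # pinned near the worst end but defined
        assert res.sqi.notna().all()

    def test_external_reference_centring(self):
        props = self.make_props(seed=9)
        other = self.make_props(seed=10) * 2.0
        res_self = score_table(props, default_mds())
        res_ref = score_table(props, default_mds(), x0_reference=other)
        assert not np.allclose(res_self.sqi, res_ref.sqi)

    def test_linear_variant_maps_to_unit_range(self):
        v = pd.Series([1.0, 2.0, 5.0])
        out = score_linear(v)
        assert out.min() == 0.0 and out.max() == 1.0
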