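"""Effect-size computation: frozen hand-computed values, sign conventions,
and the invariances the estimators must satisfy."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from seqherb.effect_sizes import (
    BinaryCounts,
    EffectSizeError,
    SummaryStats,
    apply_sign_convention,
    compute_effect_sizes,
    hedges_g,
    log_odds_ratio,
    pooled_sd,
    small_sample_correction,
)

from oracles import hedges_g_oracle, lor_oracle


class TestPooledSD:
    def test_equal_sds_pool_to_themselves(self):
        assert pooled_sd(SummaryStats(0, 0, 2, 2, 7, 13)) == pytest.approx(2.0)

    def test_hand_computed_value(self):
        # sqrt((4*9 + 4*1)/8) = sqrt(5)
        s = SummaryStats(0, 0, 3, 1, 5, 5)
        assert pooled_sd(s) == pytest.approx(math.sqrt(5), abs=1e-12)

    def test_zero_spread_pools_to_zero_and_g_raises(self):
        s = SummaryStats(1, 2, 0, 0, 5, 5)
        assert pooled_sd(s) == 0.0
        with pytest.raises(EffectSizeError, match="zero pooled SD"):
            hedges_g(s)

    def test_degenerate_denominator(self):
        with pytest.raises(EffectSizeError):
            SummaryStats(0, 0, 1, 1, 1, 1)


class TestHedgesG:
    def test_null_effect(self):
        es = hedges_g(SummaryStats(5, 5, 1, 1, 8, 12))
        assert es.value == 0.0
        assert es.variance == pytest.approx((8 + 12) / (8 * 12))

    def test_hand_computed_example(self):
        # means 8 vs 10, SDs 2/2, n 10/10: J = 1 - 3/71, g = J * (-1)
        es = hedges_g(SummaryStats(8, 10, 2, 2, 10, 10))
        j = 1 - 3 / 71
        assert es.j == pytest.approx(j, abs=1e-12)
        assert es.value == pytest.approx(-j, abs=1e-12)
        assert es.variance == pytest.approx(20 / 100 + j**2 / 40, abs=1e-12)

    def test_antisymmetry_under_arm_swap(self):
        a = hedges_g(SummaryStats(3.2, 1.1, 1.4, 0.9, 6, 9))
        b = hedges_g(SummaryStats(1.1, 3.2, 0.9, 1.4, 9, 6))
        assert a.value == pytest.approx(-b.value, abs=1e-12)
        assert a.variance == pytest.approx(b.variance, abs=1e-12)

    @given(
        mt=st.floats(-5, 5),
        mc=st.floats(-5, 5),
        st_=st.floats(0.1, 4),
        sc=st.floats(0.1, 4),
        nt=st.integers(2, 60),
        nc=st.integers(2, 60),
        scale=st.floats(0.01, 100),
    )
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_scale_invariance(self, mt, mc, st_, sc, nt, nc, scale):
        base = hedges_g(SummaryStats(mt, mc, st_, sc, nt, nc))
        scaled = hedges_g(
            SummaryStats(mt * scale, mc * scale, st_ * scale, sc * scale, nt, nc)
        )
        assert scaled.value == pytest.approx(base.value, rel=1e-9, abs=1e-9)
        assert scaled.variance == pytest.approx(base.variance, rel=1e-9, abs=1e-9)

    @given(n=st.integers(2, 500))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_j_in_unit_interval_and_monotone(self, n):
        j = small_sample_correction(n, n)
        j_next = small_sample_correction(n + 1, n + 1)
        assert 0 < j < 1
        assert j_next > j

    def test_variance_decreases_with_total_n(self):
        variances = [
            hedges_g(SummaryStats(1, 0, 1, 1, n, n)).variance
            for n in (5, 10, 20, 40, 80)
        ]
        assert all(b < a for a, b in zip(variances, variances[1:]))

    def test_matches_independent_oracle_on_random_instances(self, rng):
        for _ in range(30):
            nt, nc = int(rng.integers(2, 40)), int(rng.integers(2, 40))
            mt, mc = rng.normal(0, 3, 2)
            st_, sc = rng.uniform(0.2, 3, 2)
            es = hedges_g(SummaryStats(mt, mc, st_, sc, nt, nc))
            g, var, j = hedges_g_oracle(mt, mc, st_, sc, nt, nc)
            assert es.value == pytest.approx(g, abs=1e-10)
            assert es.variance == pytest.approx(var, abs=1e-10)
            assert es.j == pytest.approx(j, abs=1e-10)


class TestLogOddsRatio:
    def test_null_for_equal_proportions(self):
        es = log_odds_ratio(BinaryCounts(5, 10, 10, 20))
        assert es.value == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_example(self):
        # 8/10 vs 4/10: log((8/2)/(4/6)) = log 6
        es = log_odds_ratio(BinaryCounts(8, 4, 10, 10))
        assert es.value == pytest.approx(math.log(6), abs=1e-12)
        assert es.variance == pytest.approx(1 / 8 + 1 / 2 + 1 / 4 + 1 / 6, abs=1e-12)

    def test_antisymmetry_under_arm_swap(self):
        a = log_odds_ratio(BinaryCounts(7, 3, 12, 11))
        b = log_odds_ratio(BinaryCounts(3, 7, 11, 12))
        assert a.value == pytest.approx(-b.value, abs=1e-12)

    def test_zero_cell_continuity_correction(self):
        es = log_odds_ratio(BinaryCounts(10, 4, 10, 10))
        expected = math.log((10.5 / 0.5) / (4.5 / 6.5))
        assert es.value == pytest.approx(expected, abs=1e-12)

    def test_degenerate_tables_raise(self):
        with pytest.raises(EffectSizeError, match="undefined"):
            log_odds_ratio(BinaryCounts(0, 0, 10, 10))
        with pytest.raises(EffectSizeError, match="undefined"):
            log_odds_ratio(BinaryCounts(10, 10, 10, 10))

    def test_matches_independent_oracle_on_random_instances(self, rng):
        checked = 0
        while checked < 25:
            nt, nc = int(rng.integers(3, 50)), int(rng.integers(3, 50))
            a, c = int(rng.integers(0, nt + 1)), int(rng.integers(0, nc + 1))
            if (a == 0 and c == 0) or (a == nt and c == nc):
                continue
            es = log_odds_ratio(BinaryCounts(a, c, nt, nc))
            val, var = lor_oracle(a, c, nt, nc)
            assert es.value == pytest.approx(val, abs=1e-10)
            assert es.variance == pytest.approx(var, abs=1e-10)
            checked += 1


class TestSignConvention:
    @pytest.mark.parametrize(
        "outcome,value,expected,reversed_",
        [
            ("development_time", 0.4, -0.4, True),
            ("damage", -0.3, 0.3, True),
            ("growth", -0.2, -0.2, False),
            ("survival", 0.7, 0.7, False),
        ],
    )
    def test_reversal_rule(self, outcome, value, expected, reversed_):
        es = hedges_g(SummaryStats(value, 0, 1, 1, 1000, 1000))
        out = apply_sign_convention(es, outcome)
        assert out.sign_reversed is reversed_
        assert math.copysign(1, out.value) == math.copysign(1, expected)

    def test_double_application_raises(self):
        es = apply_sign_convention(
            hedges_g(SummaryStats(1, 0, 1, 1, 10, 10)), "damage"
        )
        with pytest.raises(EffectSizeError, match="already applied"):
            apply_sign_convention(es, "damage")


class TestComputeEffectSizes:
    def test_agrees_with_scalar_functions_and_keeps_order(self, small_sim):
        ds, _ = small_sim
        es = compute_effect_sizes(ds.frame)
        assert list(es["record_id"]) == [
            r for r in ds.frame["record_id"] if r in set(es["record_id"])
        ]
        for _, row in es.sample(40, random_state=0).iterrows():
            if row["metric"] == "hedges_g":
                ref = hedges_g(
                    SummaryStats(
                        row["mean_treatment"], row["mean_control"],
                        row["sd_treatment"], row["sd_control"],
                        int(row["n_treatment"]), int(row["n_control"]),
                    )
                )
            else:
                ref = log_odds_ratio(
                    BinaryCounts(
                        int(row["events_treatment"]), int(row["events_control"]),
                        int(row["n_treatment"]), int(row["n_control"]),
                    )
                )
            ref = apply_sign_convention(ref, row["outcome"])
            assert row["yi"] == pytest.approx(ref.value, abs=1e-12)
            assert row["vi"] == pytest.approx(ref.variance, abs=1e-12)

    def test_incomplete_rows_are_excluded_not_fatal(self):
        frame = pd.DataFrame(
            {
                "record_id": ["a", "b"],
                "outcome": ["growth", "growth"],
                "mean_treatment": [1.0, np.nan],
                "mean_control": [0.0, 0.0],
                "sd_treatment": [1.0, 1.0],
                "sd_control": [1.0, 1.0],
                "n_treatment": [10, 10],
                "n_control": [10, 10],
            }
        )
        es = compute_effect_sizes(frame)
        assert list(es["record_id"]) == ["a"]
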