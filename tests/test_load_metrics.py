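"""Global load scoring and the derived training measures.

Hand-computed oracles fix the arithmetic; property tests pin the structural
invariants (kernel equivalence, shift/scale behaviour, the ~2/3 kernel-mass
convention behind the 1/lambda time constant).
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from loadperf.weekly_ledger import WeeklyObservation, ValidationError
from loadperf.load_metrics import (
    LoadWeights, SmoothingSpec, LAMBDA_SET,
    global_load, rolling_mean, smoothed_load, differential_load,
    monotony_strain, acute_chronic, within_player_sd, derive_measures,
    kernel_mass_within_time_constant,
)


def obs(**kw):
    base = dict(player_id="p1", position="defender", week_index=1)
    base.update(kw)
    return WeeklyObservation(**base)


def series(values, start=1):
    return pd.Series(values, index=range(start, start + len(values)),
                     dtype=float)


def kernel_sum_oracle(loads, lam):
    """Brute-force exponential kernel sum equivalent to the recurrence.

    S_w = sum_k lam (1-lam)^k L_{w-1-k} + (1-lam)^{w-2} L_1 (decayed seed).
    """
    n = len(loads)
    out = [math.nan] * n
    for w in range(1, n):                       # S defined from 2nd week on
        acc = (1 - lam) ** (w - 1) * loads[0]   # decayed initial value
        for k in range(w):
            acc += lam * (1 - lam) ** k * loads[w - 1 - k]
        acc -= lam * (1 - lam) ** (w - 1) * loads[0]  # seed replaces its own term
        out[w] = acc
    return out


class TestGlobalLoad:
    def test_all_zero_inputs_give_zero(self):
        o = obs(training_td=0, match_td=0, training_hvd=0, match_hvd=0,
                match_work_rate=0, match_accels=0, match_decels=0,
                wellness_total=0)
        assert global_load(o) == 0.0

    def test_worked_example_sums_to_1000(self):
        o = obs(training_td=20000, match_td=12000, training_hvd=1000,
                match_hvd=500, match_work_rate=150, match_accels=10,
                match_decels=5, wellness_total=90)
        # 200 + 180 + 50 + 50 + 50 + 100 + 100 + 270
        assert global_load(o) == pytest.approx(1000.0)

    def test_wellness_only_week(self):
        assert global_load(obs(training_td=0, training_hvd=0,
                               wellness_total=100)) == pytest.approx(300.0)

    def test_missing_match_fields_count_as_zero(self):
        o = obs(training_td=10000, training_hvd=200, wellness_total=80)
        assert global_load(o) == pytest.approx(100 + 10 + 240)

    def test_week_without_sessions_is_flagged_missing(self):
        assert math.isnan(global_load(obs(wellness_total=80)))

    def test_negative_field_rejected(self):
        o = obs(training_td=1000, training_hvd=0)
        o.wellness_total = -1
        with pytest.raises(ValidationError):
            global_load(o)

    @given(st.sampled_from(["training_td", "match_td", "training_hvd",
                            "match_hvd", "match_work_rate", "wellness_total"]),
           st.floats(0, 1e4, allow_nan=False))
    @settings(max_examples=30, deadline=None)
    def test_linear_in_each_field_with_slope_equal_to_weight(self, field, v):
        weights = LoadWeights()
        slope = {"training_td": weights.w_train_td,
                 "match_td": weights.w_match_td,
                 "training_hvd": weights.w_train_hvd,
                 "match_hvd": weights.w_match_hvd,
                 "match_work_rate": weights.w_work_rate,
                 "wellness_total": weights.w_wellness}[field]
        base = dict(training_td=20000, match_td=12000, training_hvd=1000,
                    match_hvd=500, match_work_rate=150, match_accels=10,
                    match_decels=5, wellness_total=90)
        hi = dict(base)
        hi[field] = base[field] + v
        assert global_load(obs(**hi)) - global_load(obs(**base)) == \
            pytest.approx(slope * v, abs=1e-9)


class TestRollingMean:
    def test_constant_series_is_a_fixed_point(self):
        out = rolling_mean(series([500.0] * 8), 4)
        assert out.iloc[3:].tolist() == [500.0] * 5
        assert out.iloc[:3].isna().all()

    def test_hand_mean(self):
        assert rolling_mean(series([400, 600, 800]), 3).iloc[-1] == 600.0

    def test_window_one_is_identity(self):
        s = series([400, 600, 800])
        pd.testing.assert_series_equal(rolling_mean(s, 1), s)

    def test_nonpositive_window_rejected(self):
        with pytest.raises(ValueError):
            rolling_mean(series([1.0, 2.0]), 0)


class TestSmoothedLoad:
    def test_constant_series_is_a_fixed_point(self):
        out = smoothed_load(series([300.0] * 6), SmoothingSpec(0.33))
        assert out.iloc[1:].tolist() == pytest.approx([300.0] * 5)

    def test_hand_recurrence(self):
        out = smoothed_load(series([400, 600, 800]), SmoothingSpec(0.5))
        assert math.isnan(out.iloc[0])
        assert out.iloc[1:].tolist() == [400.0, 500.0]
        ext = smoothed_load(series([400, 600, 800, 0]), SmoothingSpec(0.5))
        assert ext.iloc[3] == 650.0            # lam*800 + (1-lam)*500

    @given(st.lists(st.floats(0, 2000), min_size=2, max_size=52),
           st.sampled_from(sorted(LAMBDA_SET.values())))
    @settings(max_examples=60, deadline=None)
    def test_recurrence_equals_kernel_sum_oracle(self, loads, lam):
        out = smoothed_load(series(loads), SmoothingSpec(lam)).to_numpy()
        expect = kernel_sum_oracle(loads, lam)
        scale = max(1.0, max(abs(v) for v in loads))
        for got, want in zip(out[1:], expect[1:]):
            assert abs(got - want) <= 1e-9 * scale

    @given(st.lists(st.floats(0, 2000), min_size=4, max_size=30),
           st.floats(-500, 500))
    @settings(max_examples=30, deadline=None)
    def test_shift_equivariant(self, loads, c):
        lam = 0.5
        a = smoothed_load(series(loads), SmoothingSpec(lam))
        b = smoothed_load(series([v + c for v in loads]), SmoothingSpec(lam))
        assert np.allclose(a.dropna() + c, b.dropna(), atol=1e-8)

    def test_gap_restarts_the_recurrence(self):
        s = pd.Series([400.0, 600.0, 900.0, 700.0], index=[1, 2, 4, 5])
        out = smoothed_load(s, SmoothingSpec(0.5))
        assert math.isnan(out.loc[1]) and out.loc[2] == 400.0
        assert math.isnan(out.loc[4])          # first week of the new run
        assert out.loc[5] == 900.0             # re-seeded at week 4's load

    def test_burn_in_discards_early_weeks(self):
        out = smoothed_load(series([100, 200, 300, 400, 500]),
                            SmoothingSpec(0.5, init_policy="burn_in"))
        assert out.iloc[:2].isna().all()
        assert out.iloc[2:].notna().all()


class TestDifferentialLoad:
    def test_constant_series_gives_zero_change(self):
        out = differential_load(series([500.0] * 6), SmoothingSpec(0.25))
        assert out.iloc[1:].tolist() == pytest.approx([0.0] * 5)

    def test_linear_ramp_gives_constant_slope(self):
        out = differential_load(series([400, 600, 800, 1000]), SmoothingSpec(0.5))
        assert out.iloc[1:].tolist() == pytest.approx([200.0] * 3)

    def test_hand_recurrence(self):
        out = differential_load(series([400, 600, 700]), SmoothingSpec(0.5))
        assert math.isnan(out.iloc[0])
        assert out.iloc[1:].tolist() == [200.0, 150.0]

    @given(st.lists(st.floats(0, 2000), min_size=4, max_size=30),
           st.floats(-500, 500))
    @settings(max_examples=30, deadline=None)
    def test_shift_invariant(self, loads, c):
        lam = 0.33
        a = differential_load(series(loads), SmoothingSpec(lam))
        b = differential_load(series([v + c for v in loads]), SmoothingSpec(lam))
        assert np.allclose(a.dropna(), b.dropna(), atol=1e-8)


class TestMonotonyStrain:
    def test_hand_values(self):
        mono, strain = monotony_strain(series([400, 500, 600]))
        assert mono.iloc[-1] == pytest.approx(5.0)       # 500 / 100
        assert strain.iloc[-1] == pytest.approx(2500.0)  # 5 * 500

    def test_wider_spread_lowers_monotony(self):
        mono, strain = monotony_strain(series([300, 500, 700]))
        assert mono.iloc[-1] == pytest.approx(2.5)
        assert strain.iloc[-1] == pytest.approx(1250.0)

    def test_constant_window_is_flagged_undefined(self):
        mono, strain = monotony_strain(series([500.0] * 4))
        assert mono.iloc[2:].isna().all() and strain.iloc[2:].isna().all()

    @given(st.lists(st.floats(1, 2000), min_size=3, max_size=20),
           st.floats(0.1, 10))
    @settings(max_examples=30, deadline=None)
    def test_monotony_scale_invariant_strain_scales_linearly(self, loads, c):
        m1, s1 = monotony_strain(series(loads))
        m2, s2 = monotony_strain(series([v * c for v in loads]))
        ok = m1.notna() & m2.notna()
        assert np.allclose(m1[ok], m2[ok], rtol=1e-8)
        assert np.allclose(s1[ok] * c, s2[ok], rtol=1e-8)


class TestAcuteChronic:
    def test_constant_series_gives_ratio_one(self):
        out = acute_chronic(series([500.0] * 6))
        assert out.iloc[3:].tolist() == pytest.approx([1.0] * 3)

    def test_spike_week(self):
        assert acute_chronic(series([400, 400, 400, 800])).iloc[-1] == \
            pytest.approx(1.6)                  # 800 / 500

    def test_taper_week(self):
        assert acute_chronic(series([800, 400, 400, 400])).iloc[-1] == \
            pytest.approx(0.8)                  # 400 / 500

    def test_zero_chronic_mean_flagged(self):
        out = acute_chronic(series([0.0, 0.0, 0.0, 0.0]))
        assert out.isna().all()


class TestWithinPlayerSD:
    def test_identical_sds_pool_to_themselves(self):
        assert within_player_sd([(12.0, 5), (12.0, 9)]) == pytest.approx(12.0)

    def test_equal_df_pooling(self):
        assert within_player_sd([(10, 4), (20, 4)]) == \
            pytest.approx(math.sqrt(250))

    def test_df_weighting_matters(self):
        assert within_player_sd([(10, 9), (20, 1)]) == \
            pytest.approx(math.sqrt(130))

    def test_all_zero_df_rejected(self):
        with pytest.raises(ValueError):
            within_player_sd([(10.0, 0)])


class TestTimeConstantConvention:
    def test_time_constant_is_reciprocal_lambda(self):
        got = {name: SmoothingSpec(lam).time_constant_weeks
               for name, lam in LAMBDA_SET.items()}
        # rounded to half-weeks the lambda set maps onto 1.5, 2, 3, 4 weeks
        assert {n: round(tc * 2) / 2 for n, tc in got.items()} == \
            {"1.5": 1.5, "2": 2.0, "3": 3.0, "4": 4.0}

    @pytest.mark.parametrize("lam, expected", [
        (0.67, 0.67), (0.5, 0.75), (0.33, 1 - 0.67 ** 3), (0.25, 1 - 0.75 ** 4)])
    def test_time_constant_weeks_hold_roughly_two_thirds_of_kernel_mass(
            self, lam, expected):
        # whole weeks inside the 1/lambda time constant; the worst case is
        # lambda = 0.5 whose two-week mass is exactly 0.75
        mass = kernel_mass_within_time_constant(lam)
        assert mass == pytest.approx(expected)
        assert abs(mass - 2 / 3) <= 0.09

    def test_kernel_mass_approaches_continuous_limit_for_small_lambda(self):
        # as lambda -> 0 the 1/lambda-week mass tends to 1 - e^{-1} ~ 0.632
        assert kernel_mass_within_time_constant(0.01) == \
            pytest.approx(1 - math.exp(-1), abs=5e-3)


class TestDeriveMeasures:
    def test_tidy_table_contains_every_measure(self):
        weekly = pd.DataFrame({
            "player_id": ["p1"] * 8,
            "week_index": range(1, 9),
            "weekly": [400, 500, 450, 600, 550, 500, 650, 600.0]})
        out = derive_measures(weekly)
        assert set(out.columns) == {"player_id", "week_index", "measure_name",
                                    "value"}
        present = set(out["measure_name"].astype(str))
        assert present == {"weekly", "roll1", "roll3", "roll4",
                           "smooth1.5", "smooth2", "smooth3", "smooth4",
                           "diff1.5", "diff2", "diff3", "diff4",
                           "monotony", "strain", "acwr"}
        # roll1 equals the weekly load itself
        wide = out.pivot_table(index="week_index", columns="measure_name",
                               values="value", observed=True)
        assert np.allclose(wide["roll1"], wide["weekly"])
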