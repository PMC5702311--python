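"""Quadratic mixed-model estimation, effect contrasts and reliability."""

import numpy as np
import pandas as pd
import pytest

from loadperf.effect_model import (
    ModelSpec, ModelError, fit_quadratic_mixed, effect_at_offsets,
    predict_performance_curve, reliability_between_sd,
)
from loadperf.synthetic_season import SeasonConfig, DoseResponse
from conftest import weekly_model_frame


def quad_data(rng, n_players=8, n_weeks=20, b=(100.0, 2.0, -0.5),
              player_sd=10.0, resid_sd=5.0, x_sd=4.0):
    """Balanced quadratic data with known coefficients on the raw x scale."""
    rows = []
    for p in range(n_players):
        intercept = rng.normal(0, player_sd)
        for w in range(1, n_weeks + 1):
            x = rng.normal(0, x_sd)
            y = (b[0] + intercept + b[1] * x + b[2] * x * x
                 + rng.normal(0, resid_sd))
            rows.append({"player_id": f"p{p}", "position": "defender",
                         "week_index": w, "match_id": f"M{w:02d}",
                         "value": x, "performance_score": y,
                         "match_time_pct": float(rng.uniform(60, 100)),
                         "subbed_on": False,
                         "subbed_off": False, "problem_flag": False})
    return pd.DataFrame(rows)


class TestFitQuadraticMixed:
    def test_recovers_known_coefficients(self):
        rng = np.random.default_rng(42)
        fits = [fit_quadratic_mixed(quad_data(rng), ModelSpec("m", "defender"))
                for _ in range(10)]
        b1 = np.array([f.b1 for f in fits])
        b2 = np.array([f.b2 for f in fits])
        for est, truth in ((b1, 2.0), (b2, -0.5)):
            se = est.std(ddof=1) / np.sqrt(len(est))
            assert abs(est.mean() - truth) < 3 * max(se, 1e-3)

    def test_single_player_reduces_to_ols(self):
        rng = np.random.default_rng(3)
        d = quad_data(rng, n_players=1, n_weeks=60, player_sd=0.0)
        fit = fit_quadratic_mixed(d, ModelSpec("m", "defender"))
        import statsmodels.formula.api as smf
        dd = d.copy()
        dd["x"] = dd["value"] - dd["value"].mean()
        dd["x2"] = dd["x"] ** 2
        ols = smf.ols("performance_score ~ x + x2 + match_time_pct", dd).fit()
        assert fit.b1 == pytest.approx(ols.params["x"], rel=1e-6)
        assert fit.b2 == pytest.approx(ols.params["x2"], rel=1e-6)
        assert fit.vcomp == {}

    def test_constant_measure_is_singular(self):
        rng = np.random.default_rng(0)
        d = quad_data(rng)
        d["value"] = 7.0
        with pytest.raises(ModelError):
            fit_quadratic_mixed(d, ModelSpec("m", "defender"))

    def test_too_few_observations_rejected(self):
        rng = np.random.default_rng(0)
        d = quad_data(rng, n_players=1, n_weeks=5)
        with pytest.raises(ModelError):
            fit_quadratic_mixed(d, ModelSpec("m", "defender"))

    def test_centering_invariance_of_effects(self):
        rng = np.random.default_rng(11)
        d = quad_data(rng)
        fit1 = fit_quadratic_mixed(d, ModelSpec("m", "defender"))
        d2 = d.copy()
        d2["value"] = d2["value"] + 1000.0
        fit2 = fit_quadratic_mixed(d2, ModelSpec("m", "defender"))
        e1 = effect_at_offsets(fit1, fit1.center, 4.0)
        e2 = effect_at_offsets(fit2, fit2.center, 4.0)
        for a, b in zip(e1, e2):
            assert a.delta == pytest.approx(b.delta, abs=0.15)

    def test_simple_and_complex_agree_without_match_effects(self):
        # generator has no match-level effects or substitution effects, so
        # the adjusted model should tell the same story
        mf, truth = weekly_model_frame(505)
        sd = truth.measure_sd["defender"]
        simple = fit_quadratic_mixed(mf, ModelSpec("weekly", "defender", "simple"))
        complx = fit_quadratic_mixed(mf, ModelSpec("weekly", "defender", "complex"))
        d_simple = simple.b1 * sd + simple.b2 * sd * sd
        d_complex = complx.b1 * sd + complx.b2 * sd * sd
        cl = effect_at_offsets(simple, simple.center, sd, offsets=(1,))[0].cl90
        assert abs(d_simple - d_complex) < cl


class TestEffectAtOffsets:
    def fake_fit(self, b1, b2, var1=1e-4, var2=1e-6, center=0.0):
        from loadperf.effect_model import QuadraticFitResult
        coefs = pd.Series({"Intercept": 100.0, "x": b1, "x2": b2,
                           "match_time_pct": 0.0})
        cov = pd.DataFrame(np.zeros((4, 4)), index=coefs.index,
                           columns=coefs.index)
        cov.loc["x", "x"] = var1
        cov.loc["x2", "x2"] = var2
        return QuadraticFitResult(
            measure_name="m", position="defender", variant="simple",
            b0=100.0, b1=b1, b2=b2, coefs=coefs, cov_fixed=cov, vcomp={},
            resid_var=25.0, n_obs=200, n_players=10, center=center,
            covariate_means={"match_time_pct": 85.0}, converged=True)

    def test_pure_linear_effect(self):
        fit = self.fake_fit(b1=2.0, b2=0.0)
        effs = {e.offset: e for e in effect_at_offsets(fit, 0.0, 3.0)}
        for k in (-2, -1, 1, 2):
            assert effs[k].delta == pytest.approx(2.0 * k * 3.0)

    def test_hand_quadratic(self):
        # f(x) = 2x - x^2 at mean 0, sd 1
        fit = self.fake_fit(b1=2.0, b2=-1.0)
        effs = {e.offset: e for e in effect_at_offsets(fit, 0.0, 1.0)}
        assert effs[1].delta == pytest.approx(1.0)
        assert effs[-1].delta == pytest.approx(-3.0)

    def test_symmetric_quadratic_when_b1_zero(self):
        fit = self.fake_fit(b1=0.0, b2=-0.7)
        effs = {e.offset: e for e in effect_at_offsets(fit, 0.0, 2.0)}
        assert effs[1].delta == effs[-1].delta == pytest.approx(-0.7 * 4.0)

    def test_pair_sum_identity(self):
        # delta(+k) + delta(-k) = 2 b2 k^2 sd^2 at the centred mean
        fit = self.fake_fit(b1=1.3, b2=-0.4)
        sd = 2.5
        effs = {e.offset: e for e in effect_at_offsets(fit, 0.0, sd)}
        for k in (1, 2):
            assert effs[k].delta + effs[-k].delta == \
                pytest.approx(2 * -0.4 * k * k * sd * sd)

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            effect_at_offsets(self.fake_fit(1.0, 0.0), 0.0, 0.0)


class TestPredictCurve:
    def test_flat_curve_without_dose_effect(self):
        fit = TestEffectAtOffsets().fake_fit(b1=0.0, b2=0.0)
        cur = predict_performance_curve(fit, 0.0, 1.0, grid=[-2, -1, 0, 1, 2])
        assert cur["predicted"].nunique() == 1
        assert cur["predicted"].iloc[0] == pytest.approx(100.0)

    def test_hand_grid_values(self):
        fit = TestEffectAtOffsets().fake_fit(b1=2.0, b2=-1.0)
        cur = predict_performance_curve(fit, 0.0, 1.0, grid=[-2, -1, 0, 1, 2])
        rel = cur["predicted"] - cur["predicted"][cur["offset"] == 0].iloc[0]
        assert rel.tolist() == pytest.approx([-8, -3, 0, 1, 0])

    def test_peak_at_vertex_for_concave_fit(self):
        fit = TestEffectAtOffsets().fake_fit(b1=2.0, b2=-1.0)
        grid = np.linspace(-2, 2, 81)
        cur = predict_performance_curve(fit, 0.0, 1.0, grid=grid)
        peak = cur.loc[cur["predicted"].idxmax(), "offset"]
        assert peak == pytest.approx(-fit.b1 / (2 * fit.b2), abs=0.05)


class TestReliability:
    def test_recovers_between_player_sd(self):
        sds = []
        for r in range(5):
            mf, truth = weekly_model_frame(900 + r)
            rel = reliability_between_sd(mf, "weekly", "defender")
            sds.append(rel.between_player_sd)
        sds = np.array(sds)
        se = sds.std(ddof=1) / np.sqrt(len(sds))
        assert abs(sds.mean() - 34.0) < 3 * se + 2.0

    def test_zero_between_player_variance_estimates_near_zero(self):
        mf, _ = weekly_model_frame(77, between_player_load_sd=0.0)
        rel = reliability_between_sd(mf, "weekly", "forward")
        assert rel.between_player_sd < 15.0      # boundary estimate allowed

    def test_seasonal_ramp_moves_trend_not_player_sd(self):
        mf, _ = weekly_model_frame(88)
        base = reliability_between_sd(mf, "weekly", "defender")
        ramped = mf.copy()
        ramped["value"] = ramped["value"] + 4.0 * ramped["week_index"]
        rel = reliability_between_sd(ramped, "weekly", "defender")
        assert rel.trend_coef - base.trend_coef == pytest.approx(4.0, abs=1.0)
        assert abs(rel.between_player_sd - base.between_player_sd) < 10.0
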