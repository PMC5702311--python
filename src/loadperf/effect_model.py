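"""Quadratic mixed-effects dose-response models for match performance.

Each training measure's relationship with match performance is estimated per
position group with a quadratic mixed model. The *simple* variant has fixed
effects for the intercept, the (position-mean-centred) measure, its square,
and percent match-time played; random effects are the player intercept and
independent player-level random coefficients on the linear and quadratic
terms, plus the residual. The *complex* variant adds substituted-on/off
dummies (fixed) and a match random intercept to adjust for between-match
differences.

Effects are then read off the fitted quadratic as the change in performance
for a +-k within-player-SD shift of the measure around the mean, with 90%
confidence limits from the fixed-effect covariance. A separate reliability
model (fixed: seasonal trend, problem dummy; random: player, match,
match x problem) yields the true between-player SD of each measure.

REML estimation is delegated to :mod:`statsmodels` ``MixedLM``; random-effect
covariances are fixed at zero (independent variance components), which the
small per-position samples could not support anyway. Crossed match effects
are encoded with the standard single-group variance-component construction.
Non-convergent fits are retried with the random quadratic (then linear) term
dropped; the fallback is recorded in the diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning


@dataclass(frozen=True)
class ModelSpec:
    """Which measure/position to model and with which variant.

    ``predictor_lag`` is carried through from the load-measure derivation for
    bookkeeping only; centring always happens at the position-group mean of
    the measure before squaring.
    """

    measure_name: str
    position: str
    variant: str = "simple"

    def __post_init__(self):
        if self.variant not in ("simple", "complex"):
            raise ValueError(f"variant must be simple or complex, got {self.variant!r}")


@dataclass
class QuadraticFitResult:
    """Fixed coefficients, their covariance, and variance components of one fit."""

    measure_name: str
    position: str
    variant: str
    b0: float
    b1: float
    b2: float
    coefs: pd.Series
    cov_fixed: pd.DataFrame
    vcomp: dict[str, float]
    resid_var: float
    n_obs: int
    n_players: int
    center: float
    covariate_means: dict[str, float]
    converged: bool
    fallback: str = ""

    @property
    def df_resid(self) -> int:
        """Residual df for t quantiles: observations minus fixed effects."""
        return self.n_obs - len(self.coefs)


@dataclass
class ReliabilityResult:
    """True between-player SD of a measure from the reliability mixed model."""

    measure_name: str
    position: str
    between_player_sd: float
    vcomp: dict[str, float]
    trend_coef: float
    problem_coef: float
    n_obs: int
    converged: bool


@dataclass
class EffectEstimate:
    """Change in performance for a k within-player-SD shift of a measure."""

    measure_name: str
    position: str
    offset: float
    delta: float
    cl90: float
    df: int
    standardized: float | None = None
    magnitude: str | None = None
    p_substantial_pos: float | None = None
    p_substantial_neg: float | None = None
    qualifier: str | None = None
    clear: bool | None = None


class ModelError(Exception):
    """Design degenerate (e.g. constant measure) or data insufficient."""


def _prepare(data: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, float, float]:
    d = data
    if spec.position is not None:
        d = d[d["position"] == spec.position]
    d = d.dropna(subset=["value", "performance_score", "match_time_pct"]).copy()
    if len(d) < 10:
        raise ModelError(
            f"{spec.measure_name}/{spec.position}: only {len(d)} usable observations")
    center = float(d["value"].mean())
    d["x"] = d["value"] - center
    scale = float(d["x"].std(ddof=1))
    if scale == 0.0:
        raise ModelError(f"{spec.measure_name}/{spec.position}: measure is constant")
    # the optimiser works on a unit-variance measure; coefficients are
    # transformed back to the raw scale afterwards
    d["z"] = d["x"] / scale
    d["z2"] = d["z"] ** 2
    for c in ("subbed_on", "subbed_off"):
        if c in d:
            d[c] = d[c].map(lambda v: int(bool(v)) if pd.notna(v) else 0)
    return d, center, scale


def _fit_mixedlm(model) -> tuple:
    last = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "nm", "bfgs"):
            try:
                res = model.fit(reml=True, method=method, maxiter=500)
            except Exception:
                continue
            last = res
            if bool(getattr(res, "converged", False)) and np.all(
                    np.isfinite(res.fe_params.to_numpy())):
                return res, True
    return last, False


def fit_quadratic_mixed(data: pd.DataFrame, spec: ModelSpec) -> QuadraticFitResult:
    """Fit the quadratic dose-response mixed model for one measure/position.

    Parameters
    ----------
    data
        Player-week rows with columns ``player_id``, ``position``, ``value``
        (the training measure), ``performance_score``, ``match_time_pct``
        and, for the complex variant, ``subbed_on``, ``subbed_off``,
        ``match_id``.

    Notes
    -----
    With a single player (no between-player structure to estimate) the fit
    degenerates to an ordinary least-squares quadratic, reported with zero
    variance components.
    """
    d, center, scale = _prepare(data, spec)
    n_players = d["player_id"].nunique()
    fixed = "performance_score ~ z + z2 + match_time_pct"
    if spec.variant == "complex":
        fixed += " + subbed_on + subbed_off"
    covariate_means = {"match_time_pct": float(d["match_time_pct"].mean()),
                       "subbed_on": 0.0, "subbed_off": 0.0}

    if n_players < 2:
        ols = smf.ols(fixed, data=d).fit()
        return _wrap(spec, ols.params, ols.cov_params(), {}, float(ols.scale),
                     len(d), n_players, center, scale, covariate_means, True,
                     fallback="single player: ordinary least squares")

    if spec.variant == "simple":
        vc_full = {"player_z": "0 + z", "player_z2": "0 + z2"}
        attempts = [("", vc_full),
                    ("dropped random quadratic", {"player_z": "0 + z"}),
                    ("dropped random slopes", {})]
        res = None
        for note, vc in attempts:
            model = smf.mixedlm(fixed, d, groups=d["player_id"],
                                re_formula="1", vc_formula=vc or None)
            res, ok = _fit_mixedlm(model)
            if ok:
                vcomp = {"player_intercept": float(res.cov_re.iloc[0, 0])}
                vcomp.update({n: float(v) for n, v in
                              zip(model.exog_vc.names, np.atleast_1d(res.vcomp))})
                return _wrap(spec, res.fe_params, _fixed_cov(res), vcomp,
                             float(res.scale), len(d), n_players, center,
                             scale, covariate_means, True, fallback=note)
    else:
        d = d.dropna(subset=["match_id"]).copy()
        d["allgrp"] = 1
        vc_full = {"player": "0 + C(player_id)",
                   "player_z": "0 + C(player_id):z",
                   "player_z2": "0 + C(player_id):z2",
                   "match": "0 + C(match_id)"}
        attempts = [("", vc_full),
                    ("dropped random quadratic",
                     {k: v for k, v in vc_full.items() if k != "player_z2"}),
                    ("dropped random slopes",
                     {"player": vc_full["player"], "match": vc_full["match"]})]
        res = None
        for note, vc in attempts:
            model = smf.mixedlm(fixed, d, groups=d["allgrp"],
                                re_formula="0", vc_formula=vc)
            res, ok = _fit_mixedlm(model)
            if ok:
                vcomp = {n: float(v) for n, v in
                         zip(model.exog_vc.names, np.atleast_1d(res.vcomp))}
                return _wrap(spec, res.fe_params, _fixed_cov(res), vcomp,
                             float(res.scale), len(d), n_players, center,
                             scale, covariate_means, True, fallback=note)

    # nothing converged: report the last attempt, flagged
    if res is None:
        raise ModelError(f"{spec.measure_name}/{spec.position}: estimation failed")
    return _wrap(spec, res.fe_params, _fixed_cov(res), {}, float(res.scale),
                 len(d), n_players, center, scale, covariate_means, False,
                 fallback="non-convergent after fallbacks")


def _fixed_cov(res) -> pd.DataFrame:
    cov = res.cov_params()
    names = list(res.fe_params.index)
    return cov.loc[names, names]


def _wrap(spec, params, cov, vcomp, resid_var, n_obs, n_players, center,
          scale, covariate_means, converged, fallback="") -> QuadraticFitResult:
    """Transform z-scale estimates back to the raw measure scale."""
    params = pd.Series(params).rename({"z": "x", "z2": "x2"})
    cov = pd.DataFrame(cov).rename(index={"z": "x", "z2": "x2"},
                                   columns={"z": "x", "z2": "x2"})
    jac = pd.Series(1.0, index=params.index)
    jac["x"] = 1.0 / scale
    jac["x2"] = 1.0 / scale ** 2
    params = params * jac
    cov = cov.mul(jac, axis=0).mul(jac, axis=1)
    return QuadraticFitResult(
        measure_name=spec.measure_name, position=spec.position,
        variant=spec.variant,
        b0=float(params["Intercept"]), b1=float(params["x"]),
        b2=float(params["x2"]),
        coefs=params, cov_fixed=cov, vcomp=vcomp, resid_var=resid_var,
        n_obs=n_obs, n_players=n_players, center=center,
        covariate_means=covariate_means, converged=converged, fallback=fallback)


def effect_at_offsets(fit: QuadraticFitResult, mean: float, sd: float,
                      offsets: Sequence[float] = (-2, -1, 1, 2)) -> list[EffectEstimate]:
    """Change in performance for each +-k SD shift of the measure from the mean.

    delta(k) = f(mean + k sd) - f(mean) for the fitted quadratic f, with
    covariates held fixed; the 90% CL comes from the covariance of (b1, b2)
    under a t distribution with ``fit.df_resid`` degrees of freedom.
    """
    if sd <= 0:
        raise ValueError(f"within-player SD must be > 0, got {sd}")
    m = mean - fit.center            # evaluation point on the centred scale
    cov = fit.cov_fixed.loc[["x", "x2"], ["x", "x2"]].to_numpy()
    tq = stats.t.ppf(0.95, fit.df_resid)
    out = []
    for k in offsets:
        shift = k * sd
        c = np.array([shift, 2 * m * shift + shift ** 2])
        delta = float(c @ np.array([fit.b1, fit.b2]))
        quad = float(c @ cov @ c)
        se = np.sqrt(quad) if quad >= 0 else float("nan")
        out.append(EffectEstimate(
            measure_name=fit.measure_name, position=fit.position,
            offset=float(k), delta=delta, cl90=float(tq * se), df=fit.df_resid))
    return out


def predict_performance_curve(fit: QuadraticFitResult, mean: float, sd: float,
                              grid: Sequence[float] | None = None) -> pd.DataFrame:
    """Predicted performance over a grid of SD offsets, with a 90% CL band.

    Covariates are held at their sample means (substitution dummies at 0).
    Returns columns offset, measure_value, predicted, cl90.
    """
    if sd <= 0:
        raise ValueError(f"within-player SD must be > 0, got {sd}")
    if grid is None:
        grid = np.linspace(-2, 2, 41)
    names = list(fit.coefs.index)
    cov = fit.cov_fixed.loc[names, names].to_numpy()
    beta = fit.coefs.to_numpy()
    tq = stats.t.ppf(0.95, fit.df_resid)
    rows = []
    for k in grid:
        xval = mean + k * sd
        xc = xval - fit.center
        design = []
        for name in names:
            if name == "Intercept":
                design.append(1.0)
            elif name == "x":
                design.append(xc)
            elif name == "x2":
                design.append(xc ** 2)
            else:
                design.append(fit.covariate_means.get(name, 0.0))
        design = np.array(design)
        pred = float(design @ beta)
        quad = float(design @ cov @ design)
        se = np.sqrt(quad) if quad >= 0 else float("nan")
        rows.append({"offset": float(k), "measure_value": xval,
                     "predicted": pred, "cl90": float(tq * se)})
    return pd.DataFrame(rows)


def reliability_between_sd(data: pd.DataFrame, measure_name: str,
                           position: str | None = None) -> ReliabilityResult:
    """True between-player SD of a measure from the reliability mixed model.

    Fixed effects: linear seasonal trend (week index) and the problem dummy
    (injury/illness-modified week). Random: player identity, match identity,
    and match x problem; the between-player SD is the square root of the
    player variance component. The team plays one match per week, so the
    week index doubles as the match identity.
    """
    d = data
    if position is not None:
        d = d[d["position"] == position]
    d = d.dropna(subset=["value"]).copy()
    if d["player_id"].nunique() < 2 or d["week_index"].nunique() < 2:
        raise ModelError(f"{measure_name}: need >= 2 players and >= 2 weeks")
    d["problem"] = d["problem_flag"].map(lambda v: int(bool(v)) if pd.notna(v) else 0)
    d["allgrp"] = 1
    # unit-variance response for the optimiser; components rescaled after
    vscale = float(d["value"].std(ddof=1))
    if vscale == 0.0:
        raise ModelError(f"{measure_name}: measure is constant")
    d["v"] = d["value"] / vscale
    vc_full = {"player": "0 + C(player_id)", "match": "0 + C(week_index)"}
    fixed = "v ~ week_index"
    if d["problem"].nunique() > 1:
        fixed += " + problem"
        vc_full["match_problem"] = "0 + C(week_index):problem"
    # fall back from the crossed structure to plainer models when the
    # boundary-heavy likelihood defeats every optimiser
    attempts = [vc_full,
                {k: v for k, v in vc_full.items() if k != "match_problem"},
                None]
    res = model = None
    ok = False
    for vc in attempts:
        if vc is not None:
            model = smf.mixedlm(fixed, d, groups=d["allgrp"],
                                re_formula="0", vc_formula=vc)
        else:
            model = smf.mixedlm(fixed, d, groups=d["player_id"],
                                re_formula="1")
        res, ok = _fit_mixedlm(model)
        if ok:
            break
    if res is None:
        raise ModelError(f"{measure_name}: reliability model failed")
    if getattr(model.exog_vc, "names", None):
        vcomp = {n: float(v) * vscale ** 2
                 for n, v in zip(model.exog_vc.names, np.atleast_1d(res.vcomp))}
    else:
        vcomp = {"player": float(res.cov_re.iloc[0, 0]) * vscale ** 2}
    return ReliabilityResult(
        measure_name=measure_name, position=position or "all",
        between_player_sd=float(np.sqrt(max(vcomp.get("player", 0.0), 0.0))),
        vcomp=vcomp,
        trend_coef=float(res.fe_params.get("week_index", np.nan)) * vscale,
        problem_coef=float(res.fe_params.get("problem", np.nan)) * vscale,
        n_obs=len(d), converged=ok)
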