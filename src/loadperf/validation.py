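"""Simulation studies validating the estimation pipeline against ground truth.

These routines drive the synthetic-season generator end to end — records ->
aggregation -> global load -> mixed-model fit -> effect contrasts — and
compare what the pipeline reports with what the generator planted. They back
both the test suite and the reproduction script:

* ``recovery_study``: are the fitted +-1 SD effects unbiased for the planted
  quadratic dose-response?
* ``null_coverage_study``: with no planted effect, do the 90% confidence
  intervals cover zero at roughly their nominal rate?
* ``peak_pattern_study``: with an inverted-U planted to peak about half an
  SD below the mean load, does the fitted performance curve peak "near the
  mean or below" in nearly all replicate seasons?
* ``smoothing_oracle_max_error``: does the smoothing recurrence agree with
  the explicit exponential-kernel sum on random series?

Replicate counts are modest (tens to low hundreds of single-season fits) so
a full run stays in the minutes range on one core.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from loadperf.effect_model import ModelSpec, ModelError, fit_quadratic_mixed, \
    effect_at_offsets
from loadperf.load_metrics import SmoothingSpec, smoothed_load, weekly_load_series
from loadperf.synthetic_season import (SeasonConfig, DoseResponse,
                                       simulate_squad, true_effect_of_offset)
from loadperf.weekly_ledger import aggregate_week, observations_to_frame

WELL_SAMPLED_POSITIONS = ("defender", "forward", "midfielder")


def _weekly_model_frame(seed: int, dose_response: DoseResponse):
    cfg = SeasonConfig(dose_response=dose_response)
    sessions, wellness, matches, roster, problems, truth = simulate_squad(
        cfg, seed)
    frame = observations_to_frame(
        aggregate_week(sessions, wellness, matches, roster, problems))
    weekly = weekly_load_series(frame)
    mf = frame.merge(weekly.rename(columns={"weekly": "value"}),
                     on=["player_id", "week_index"])
    return mf, truth


def recovery_study(n_reps: int = 100, seed: int = 0,
                   dose_response: DoseResponse = DoseResponse(),
                   position: str = "defender") -> dict:
    """Fit replicate seasons and compare mean +-1 SD effects with the truth.

    Returns, per offset k in {-1, +1}: the replicate mean of the fitted
    delta(k), the matching truth (evaluated at each fit's own centring
    point, since the quadratic's k-SD effect depends on where the shift
    starts), the Monte-Carlo standard error of the error, and whether the
    mean error sits within 3 MC SEs of zero.
    """
    deltas: dict[int, list[float]] = {-1: [], 1: []}
    truths: dict[int, list[float]] = {-1: [], 1: []}
    for r in range(n_reps):
        mf, truth = _weekly_model_frame(seed * 100_003 + r, dose_response)
        try:
            fit = fit_quadratic_mixed(mf, ModelSpec("weekly", position))
        except ModelError:
            continue
        if not fit.converged:
            continue
        sd = truth.measure_sd[position]
        for e in effect_at_offsets(fit, fit.center, sd, offsets=(-1, 1)):
            k = int(e.offset)
            deltas[k].append(e.delta)
            truths[k].append(true_effect_of_offset(
                truth, k, position=position, at_value=fit.center))
    out = {"n_reps": n_reps, "n_used": len(deltas[1])}
    for k in (-1, 1):
        err = np.asarray(deltas[k]) - np.asarray(truths[k])
        mc_se = err.std(ddof=1) / math.sqrt(len(err))
        out[k] = {"mean": float(np.mean(deltas[k])),
                  "truth": float(np.mean(truths[k])),
                  "mc_se": float(mc_se),
                  "within_3se": bool(abs(err.mean()) < 3 * mc_se)}
    return out


def null_coverage_study(n_reps: int = 100, seed: int = 0,
                        position: str = "defender") -> dict:
    """CI coverage of zero when the generator plants no dose-response."""
    null = DoseResponse("weekly", 0.0, 0.0)
    covered, total = 0, 0
    for r in range(n_reps):
        mf, truth = _weekly_model_frame(seed * 100_003 + 50_000_000 + r, null)
        try:
            fit = fit_quadratic_mixed(mf, ModelSpec("weekly", position))
        except ModelError:
            continue
        if not fit.converged:
            continue
        sd = truth.measure_sd[position]
        for e in effect_at_offsets(fit, fit.center, sd, offsets=(-1, 1)):
            if np.isfinite(e.cl90):
                total += 1
                covered += abs(e.delta) <= e.cl90
    return {"n_reps": n_reps, "n_intervals": total,
            "coverage": covered / total if total else float("nan")}


def peak_pattern_study(n_reps: int = 50, seed: int = 0,
                       dose_response: DoseResponse = DoseResponse(),
                       positions=WELL_SAMPLED_POSITIONS,
                       peak_threshold_sd: float = 0.5) -> dict:
    """How often replicate seasons reproduce the near-or-below-mean peak.

    A replicate counts as reproducing the pattern when, for a majority of
    the well-sampled position groups, the fitted quadratic's maximum over
    the -2..+2 SD grid falls at or below ``peak_threshold_sd`` — i.e.
    performance is highest near the mean of the training measure or below
    it, not above.
    """
    grid = np.round(np.arange(-2.0, 2.01, 0.25), 4)
    successes, used = 0, 0
    for r in range(n_reps):
        mf, truth = _weekly_model_frame(seed * 100_003 + 90_000_000 + r,
                                        dose_response)
        hits, fitted = 0, 0
        for pos in positions:
            try:
                fit = fit_quadratic_mixed(mf, ModelSpec("weekly", pos))
            except ModelError:
                continue
            if not fit.converged:
                continue
            sd = truth.measure_sd[pos]
            curve = fit.b1 * (grid * sd) + fit.b2 * (grid * sd) ** 2
            fitted += 1
            hits += grid[int(np.argmax(curve))] <= peak_threshold_sd
        if fitted == 0:
            continue
        used += 1
        successes += hits * 2 > fitted          # majority of fitted positions
    return {"n_reps": n_reps, "n_used": used,
            "fraction": successes / used if used else float("nan"),
            "true_peak_offset_sd": dose_response.peak_offset_sd}


def smoothing_oracle_max_error(n_series: int = 1000, seed: int = 0,
                               max_weeks: int = 52) -> float:
    """Max relative error of the recurrence vs the explicit kernel sum."""
    rng = np.random.default_rng(seed)
    lambdas = (0.67, 0.5, 0.33, 0.25)
    worst = 0.0
    for i in range(n_series):
        n = int(rng.integers(2, max_weeks + 1))
        loads = rng.uniform(0, 2000, size=n)
        lam = lambdas[i % len(lambdas)]
        got = smoothed_load(pd.Series(loads, index=range(1, n + 1)),
                            SmoothingSpec(lam)).to_numpy()
        # explicit weighted sum: decayed seed plus kernel over past loads
        for w in range(1, n):
            acc = (1 - lam) ** (w - 1) * loads[0]
            for k in range(w - 1):
                acc += lam * (1 - lam) ** k * loads[w - 1 - k]
            scale = max(abs(acc), 1.0)
            worst = max(worst, abs(got[w] - acc) / scale)
    return worst
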