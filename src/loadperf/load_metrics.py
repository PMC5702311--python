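"""Global load scoring and derivative weekly training measures.

The weekly global load is a weighted sum of eight monitoring inputs — GPS
externals (distances, work rate, acceleration/deceleration events) and the
wellness total — expressed in arbitrary units. From the per-player weekly
series we derive:

* plain rolling means over 1, 3 and 4 weeks;
* exponentially smoothed load with decay factor ``lambda``, using the
  convention that the time constant is ``1/lambda`` weeks (the span holding
  roughly two thirds of the kernel weight), so lambda in
  {0.67, 0.5, 0.33, 0.25} gives 1.5-, 2-, 3- and 4-week smoothing;
* differential load — the same smoothing applied to week-to-week changes,
  a smoothed rate of change;
* weekly monotony (trailing 3-week mean / 3-week sample SD) and strain
  (monotony x 3-week mean);
* the acute:chronic ratio (current week / trailing 4-week mean, current
  week included in the chronic window).

Division-by-zero cases (constant 3-week window, zero chronic mean) are
flagged missing (NaN), never infinite, so model fits skip them. A gap in a
player's weekly series breaks the smoothing recurrences, which re-initialise
after the gap rather than fabricating load through bye or injury weeks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from loadperf.weekly_ledger import WeeklyObservation, ValidationError

# decay factors and the measure-name vocabulary used throughout
LAMBDA_SET = {"1.5": 0.67, "2": 0.5, "3": 0.33, "4": 0.25}
MEASURE_NAMES = ("weekly", "roll1", "roll3", "roll4",
                 "smooth1.5", "smooth2", "smooth3", "smooth4",
                 "diff1.5", "diff2", "diff3", "diff4",
                 "monotony", "strain", "acwr")
DIMENSIONLESS_MEASURES = ("monotony", "acwr")


@dataclass(frozen=True)
class LoadWeights:
    """The eight coefficients of the global load score (arbitrary units).

    Defaults follow the importance weighting assigned by performance staff:
    training distance /100, match distance /100 x 1.5, training
    high-velocity distance /20, match high-velocity distance /10, match work
    rate /3, high accelerations x10, high decelerations x20, wellness x3.
    """

    w_train_td: float = 1 / 100
    w_match_td: float = 1.5 / 100
    w_train_hvd: float = 1 / 20
    w_match_hvd: float = 1 / 10
    w_work_rate: float = 1 / 3
    w_accel: float = 10.0
    w_decel: float = 20.0
    w_wellness: float = 3.0

    def __post_init__(self):
        for name, v in self.__dict__.items():
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class SmoothingSpec:
    """Exponential-smoothing settings: decay factor and initialisation policy.

    ``time_constant_weeks`` is ``1/lambda`` — the window containing ~2/3 of
    the total kernel weight. ``first_value`` seeds the recurrence with the
    first observed load (or change); ``burn_in`` instead discards the first
    ``ceil(1/lambda)`` output weeks of each contiguous run.
    """

    lam: float
    init_policy: str = "first_value"

    def __post_init__(self):
        if not 0 < self.lam <= 1:
            raise ValueError(f"lambda must be in (0, 1], got {self.lam}")
        if self.init_policy not in ("first_value", "burn_in"):
            raise ValueError(f"unknown init_policy {self.init_policy!r}")

    @property
    def time_constant_weeks(self) -> float:
        return 1.0 / self.lam


def global_load(week: WeeklyObservation, weights: LoadWeights = LoadWeights()) -> float:
    """Score one player-week into global load units.

    Match fields absent in a non-match week contribute zero; a week with no
    recorded sessions at all returns NaN (flagged missing). Negative inputs
    raise ``ValidationError``.
    """
    if not week.has_sessions:
        return float("nan")
    terms = [
        (week.training_td, weights.w_train_td, "training_td"),
        (week.match_td, weights.w_match_td, "match_td"),
        (week.training_hvd, weights.w_train_hvd, "training_hvd"),
        (week.match_hvd, weights.w_match_hvd, "match_hvd"),
        (week.match_work_rate, weights.w_work_rate, "match_work_rate"),
        (week.match_accels, weights.w_accel, "match_accels"),
        (week.match_decels, weights.w_decel, "match_decels"),
        (week.wellness_total, weights.w_wellness, "wellness_total"),
    ]
    total = 0.0
    for value, w, name in terms:
        if value is None:
            continue
        if value < 0:
            raise ValidationError(f"{name} must be >= 0, got {value}")
        total += value * w
    return total


def rolling_mean(series: pd.Series, k: int) -> pd.Series:
    """Trailing k-week mean; NaN until k weeks are available (gaps break windows)."""
    if k < 1:
        raise ValueError(f"window must be >= 1 week, got {k}")
    s = _on_week_grid(series)
    return s.rolling(k, min_periods=k).mean().reindex(series.index)


def _on_week_grid(series: pd.Series) -> pd.Series:
    """Reindex onto the full integer week range so gaps are explicit NaNs."""
    idx = series.index
    if len(idx) == 0:
        return series.astype(float)
    if not idx.is_monotonic_increasing or idx.has_duplicates:
        raise ValueError("weekly series index must be strictly increasing weeks")
    full = pd.RangeIndex(int(idx.min()), int(idx.max()) + 1)
    return series.reindex(full).astype(float)


def _contiguous_runs(values: np.ndarray) -> Iterable[tuple[int, int]]:
    """Yield [start, stop) index ranges of consecutive non-NaN entries."""
    n = len(values)
    i = 0
    while i < n:
        if np.isnan(values[i]):
            i += 1
            continue
        j = i
        while j < n and not np.isnan(values[j]):
            j += 1
        yield i, j
        i = j


def _ewma_run(x: np.ndarray, lam: float) -> np.ndarray:
    """out[i] = lam*x[i] + (1-lam)*out[i-1], seeded with out[0] = x[0]."""
    out = np.empty_like(x)
    out[0] = x[0]
    for i in range(1, len(x)):
        out[i] = lam * x[i] + (1 - lam) * out[i - 1]
    return out


def smoothed_load(series: pd.Series, spec: SmoothingSpec, lag: int = 1) -> pd.Series:
    """Exponentially smoothed load per week.

    With the default ``lag=1`` the week-w value uses loads only through week
    w-1: S_w = lam * L_{w-1} + (1-lam) * S_{w-1}, seeded so that S at the
    second observed week equals the first observed load. ``lag=0`` includes
    the current week (S_w = lam * L_w + (1-lam) * S_{w-1}). The recurrence
    restarts after any gap in the series.
    """
    if lag not in (0, 1):
        raise ValueError("lag must be 0 or 1")
    grid = _on_week_grid(series)
    vals = grid.to_numpy()
    out = np.full(len(vals), np.nan)
    for a, b in _contiguous_runs(vals):
        run = _ewma_run(vals[a:b], spec.lam)
        if lag == 1:
            out[a + 1:b] = run[:b - a - 1]
        else:
            out[a:b] = run
        if spec.init_policy == "burn_in":
            cut = math.ceil(1.0 / spec.lam)
            out[a:min(a + cut, b)] = np.nan
    return pd.Series(out, index=grid.index).reindex(series.index)


def differential_load(series: pd.Series, spec: SmoothingSpec, lag: int = 0) -> pd.Series:
    """Smoothed week-to-week rate of change in load.

    The smoothing recurrence is applied to delta_w = L_w - L_{w-1}. With the
    default ``lag=0`` the week-w value incorporates the change between the
    current and previous week: D_w = lam * delta_w + (1-lam) * D_{w-1},
    seeded at the first defined change. ``lag=1`` shifts by one week so only
    changes through w-1 enter. Restarts after gaps.
    """
    if lag not in (0, 1):
        raise ValueError("lag must be 0 or 1")
    grid = _on_week_grid(series)
    vals = grid.to_numpy()
    out = np.full(len(vals), np.nan)
    for a, b in _contiguous_runs(vals):
        if b - a < 2:
            continue
        deltas = np.diff(vals[a:b])         # aligned to weeks a+1 .. b-1
        run = _ewma_run(deltas, spec.lam)
        if lag == 0:
            out[a + 1:b] = run
        else:
            out[a + 2:b] = run[:b - a - 2]
        if spec.init_policy == "burn_in":
            cut = math.ceil(1.0 / spec.lam)
            out[a:min(a + 1 + cut, b)] = np.nan
    return pd.Series(out, index=grid.index).reindex(series.index)


def monotony_strain(series: pd.Series) -> tuple[pd.Series, pd.Series]:
    """Weekly monotony and strain over the trailing 3-week window.

    monotony = 3-week mean / 3-week sample SD (n-1 denominator);
    strain = monotony x 3-week mean. A zero-SD (constant) window is flagged
    missing rather than infinite.
    """
    grid = _on_week_grid(series)
    mean3 = grid.rolling(3, min_periods=3).mean()
    sd3 = grid.rolling(3, min_periods=3).std(ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        monotony = mean3 / sd3
    monotony[sd3 == 0] = np.nan
    strain = monotony * mean3
    return (monotony.reindex(series.index), strain.reindex(series.index))


def acute_chronic(series: pd.Series) -> pd.Series:
    """Acute:chronic ratio: week-w load / mean of weeks w-3..w (coupled windows)."""
    grid = _on_week_grid(series)
    chronic = grid.rolling(4, min_periods=4).mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = grid / chronic
    ratio[chronic == 0] = np.nan
    return ratio.reindex(series.index)


def kernel_mass_within_time_constant(lam: float, weeks: int | None = None) -> float:
    """Fraction of the exponential kernel's weight inside the time constant.

    The kernel weights are lam * (1-lam)^k for lags k = 0, 1, ...; by the
    1/lam time-constant convention that span holds roughly two thirds of the
    total weight. ``weeks`` defaults to the whole weeks completed within the
    time constant, floor(1/lam); the mass has the closed form
    1 - (1-lam)^weeks and tends to 1 - e^{-1} ~ 0.632 as lam shrinks.
    """
    if weeks is None:
        weeks = math.floor(1.0 / lam)
    return 1.0 - (1.0 - lam) ** weeks


def within_player_sd(per_player: Sequence[tuple[float, int]]) -> float:
    """Pool per-player SDs: sqrt of the df-weighted mean of squared SDs.

    ``per_player`` is a sequence of (sd, degrees_of_freedom). This is the
    within-player SD used as the unit of a "1 SD" training change.
    """
    total_df = sum(df for _, df in per_player)
    if total_df <= 0:
        raise ValueError("no degrees of freedom: need at least one player with df >= 1")
    ss = sum(df * sd * sd for sd, df in per_player)
    return math.sqrt(ss / total_df)


def weekly_load_series(obs_frame: pd.DataFrame,
                       weights: LoadWeights = LoadWeights()) -> pd.DataFrame:
    """Score every observation row; returns player_id, week_index, weekly."""
    from loadperf.weekly_ledger import WeeklyObservation

    rows = []
    for _, r in obs_frame.iterrows():
        o = WeeklyObservation(
            player_id=r["player_id"], position=r["position"],
            week_index=int(r["week_index"]),
            **{c: (None if pd.isna(r[c]) else r[c])
               for c in ("training_td", "match_td", "training_hvd", "match_hvd",
                         "match_work_rate", "match_accels", "match_decels",
                         "wellness_total")})
        rows.append({"player_id": r["player_id"], "week_index": int(r["week_index"]),
                     "weekly": global_load(o, weights)})
    return pd.DataFrame(rows)


def derive_measures(weekly: pd.DataFrame, init_policy: str = "first_value",
                    smooth_lag: int = 1, diff_lag: int = 0) -> pd.DataFrame:
    """Compute every training measure for every player from weekly loads.

    Parameters
    ----------
    weekly
        Long frame with columns player_id, week_index, weekly (global load).

    Returns
    -------
    Tidy frame with columns player_id, week_index, measure_name, value —
    one row per defined (non-flagged) measure value.
    """
    frames = []
    for pid, grp in weekly.groupby("player_id", sort=True):
        s = grp.set_index("week_index")["weekly"].sort_index()
        s = s[s.notna()]
        per: dict[str, pd.Series] = {"weekly": s}
        for k in (1, 3, 4):
            per[f"roll{k}"] = rolling_mean(s, k)
        for name, lam in LAMBDA_SET.items():
            spec = SmoothingSpec(lam, init_policy)
            per[f"smooth{name}"] = smoothed_load(s, spec, lag=smooth_lag)
            per[f"diff{name}"] = differential_load(s, spec, lag=diff_lag)
        mono, strain = monotony_strain(s)
        per["monotony"] = mono
        per["strain"] = strain
        per["acwr"] = acute_chronic(s)
        tidy = pd.DataFrame(per).rename_axis("week_index").reset_index()
        tidy = tidy.melt(id_vars="week_index", var_name="measure_name",
                         value_name="value")
        tidy.insert(0, "player_id", pid)
        frames.append(tidy.dropna(subset=["value"]))
    if not frames:
        return pd.DataFrame(columns=["player_id", "week_index", "measure_name", "value"])
    out = pd.concat(frames, ignore_index=True)
    out["measure_name"] = pd.Categorical(out["measure_name"],
                                         categories=MEASURE_NAMES, ordered=True)
    return out.sort_values(["player_id", "measure_name", "week_index"],
                           ignore_index=True)
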