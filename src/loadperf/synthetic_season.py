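"""Synthetic-season generator with known ground truth.

The original cohort data (one elite Australian-football squad over a 24-week
season) are proprietary, so this module emulates their structure: a squad of
13 defenders, 13 forwards, 6 midfielders and 3 rucks; position-stratified
weekly global loads with realistic means and within-player SDs (defender
541 +- 138, forward 576 +- 144, midfielder 560 +- 135, ruck 475 +- 98
arbitrary units); player random intercepts; and a configurable quadratic
dependence of the match performance score on a chosen training measure.

Each week's target global load is decomposed into session GPS fields and a
wellness total *consistently with the load weights*, so that scoring the
generated records recovers the target load to numerical precision — the
conservation contract every downstream stage is tested against. Wellness is
drawn first (12 Likert items), match fields fill a fixed share of the
remainder on match weeks, and training distance absorbs the residual;
infeasible decompositions (target below the wellness floor) are clipped at
zero training and logged.

Weekly load noise is i.i.d. around the player mean by default; an optional
AR(1) switch adds week-to-week persistence, without which the smoothed and
differential measures carry no signal beyond the weekly load. "Problem"
weeks (injury/illness) scale the training share of load down and feed the
reliability model's problem dummy.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from loadperf.weekly_ledger import (
    SessionRecord, WellnessRecord, MatchRecord, POSITIONS, aggregate_week,
    observations_to_frame,
)
from loadperf.load_metrics import LoadWeights, weekly_load_series, derive_measures

# cohort defaults: per-position squad sizes, weekly-load and performance
# moments (mean, within-player SD), and match-participation rates chosen to
# reproduce realistic per-position observation counts (~151/167/99/27).
DEFAULT_SQUAD = {"defender": 13, "forward": 13, "midfielder": 6, "ruck": 3}
DEFAULT_LOAD = {"defender": (541.0, 138.0), "forward": (576.0, 144.0),
                "midfielder": (560.0, 135.0), "ruck": (475.0, 98.0)}
DEFAULT_PERFORMANCE = {"defender": (65.0, 27.0), "forward": (68.0, 28.0),
                       "midfielder": (101.0, 27.0), "ruck": (80.0, 21.0)}
DEFAULT_MATCH_PLAY_PROB = {"defender": 0.48, "forward": 0.54,
                           "midfielder": 0.69, "ruck": 0.38}


@dataclass(frozen=True)
class DoseResponse:
    """Planted quadratic dose-response of performance on a training measure.

    Coefficients are in performance units per within-player SD of the
    measure: delta(k) = b1_sd * k + b2_sd * k^2 for a k-SD shift from the
    position mean. The defaults plant an inverted U peaking about half an SD
    below the mean (small decrement at +1 SD, near-trivial change at -1 SD),
    the shape typical of in-season load-performance relationships.
    """

    measure_name: str = "weekly"
    b1_sd: float = -3.5
    b2_sd: float = -3.0

    @property
    def peak_offset_sd(self) -> float:
        """SD offset at which predicted performance peaks (if concave)."""
        if self.b2_sd >= 0:
            return float("nan")
        return -self.b1_sd / (2 * self.b2_sd)


@dataclass(frozen=True)
class SeasonConfig:
    """All knobs of the synthetic season; defaults are the study conditions."""

    n_weeks: int = 24
    squad: dict = field(default_factory=lambda: dict(DEFAULT_SQUAD))
    load_moments: dict = field(default_factory=lambda: dict(DEFAULT_LOAD))
    performance_moments: dict = field(
        default_factory=lambda: dict(DEFAULT_PERFORMANCE))
    player_perf_intercept_sd: float = 25.0
    between_player_load_sd: float = 34.0
    dose_response: DoseResponse = field(default_factory=DoseResponse)
    match_play_prob: dict = field(
        default_factory=lambda: dict(DEFAULT_MATCH_PLAY_PROB))
    problem_prob: float = 0.05
    problem_training_factor: float = 0.5
    subbed_on_prob: float = 0.05
    subbed_off_prob: float = 0.05
    ar1_rho: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for pos, n in self.squad.items():
            if pos not in POSITIONS or n < 1:
                raise ValueError(f"bad squad entry {pos!r}: {n}")
        for prob in (self.problem_prob, self.subbed_on_prob, self.subbed_off_prob,
                     *self.match_play_prob.values()):
            if not 0 <= prob <= 1:
                raise ValueError(f"probability out of [0, 1]: {prob}")
        if not -1 < self.ar1_rho < 1:
            raise ValueError(f"ar1_rho must be in (-1, 1), got {self.ar1_rho}")


@dataclass
class GroundTruth:
    """Generating parameters actually used, exposed for recovery tests."""

    config: SeasonConfig
    dose_response: DoseResponse
    player_load_offsets: dict[str, float]
    player_perf_intercepts: dict[str, float]
    measure_center: dict[str, float]     # per position, centre used for x
    measure_sd: dict[str, float]         # per position, SD scaling the truth
    target_loads: pd.DataFrame           # player_id, week_index, target load


# share of the post-wellness load budget taken by the match on match weeks,
# and template splits within the match and training budgets
_MATCH_SHARE = 0.45
_TRAIN_HVD_SHARE = 0.08
_SESSION_SPLIT = (0.45, 0.35, 0.12, 0.08)   # two field + two recovery sessions
_MIN_TARGET = 60.0


def _wellness_items(rng: np.random.Generator, max_total: int | None = None
                    ) -> tuple[int, ...]:
    items = np.clip(np.rint(rng.normal(6.5, 1.2, size=12)), 1, 10).astype(int)
    if max_total is not None and items.sum() > max_total:
        # lower items one by one (highest first) until the cap is met
        items = items.copy()
        while items.sum() > max_total and items.max() > 1:
            items[int(np.argmax(items))] -= 1
    return tuple(int(v) for v in items)


def _decompose_week(target: float, played: bool, problem: bool,
                    cfg: SeasonConfig, rng: np.random.Generator):
    """Split a target global load into wellness + match + training fields.

    Returns (items, match fields or None, training_td, training_hvd,
    realized load). The weighted sum of the emitted fields equals the
    realized load exactly; realized differs from target only on problem
    weeks (training share scaled down) or at the wellness floor.
    """
    items = _wellness_items(rng)
    w = 3 * sum(items)
    if target - w < 0:
        items = _wellness_items(rng, max_total=max(12, int(target // 3)))
        w = 3 * sum(items)
    remainder = max(target - w, 0.0)

    match_fields = None
    match_budget = 0.0
    if played:
        match_budget = _MATCH_SHARE * remainder
        accels = int(0.2 * match_budget // 10)
        decels = int(0.2 * match_budget // 20)
        leftover = match_budget - 10 * accels - 20 * decels
        match_fields = {
            "match_td": 0.6 * leftover * 100 / 1.5,
            "match_hvd": 0.2 * leftover * 10,
            "work_rate": 0.2 * leftover * 3,
            "accels": accels, "decels": decels,
        }
    training_budget = remainder - match_budget
    if problem:
        training_budget *= cfg.problem_training_factor
    training_hvd = _TRAIN_HVD_SHARE * training_budget * 20
    training_td = (1 - _TRAIN_HVD_SHARE) * training_budget * 100
    realized = w + match_budget + training_budget
    return items, match_fields, training_td, training_hvd, realized


def simulate_squad(cfg: SeasonConfig = SeasonConfig(), seed: int | None = None):
    """Generate one season of session, wellness and match records.

    Returns ``(sessions, wellness, matches, roster, problems, truth)`` where
    the first three are record lists in the ledger schemas, ``roster`` maps
    player to position, ``problems`` is the set of injury/illness-modified
    player-weeks, and ``truth`` carries the generating parameters.
    """
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)
    weeks = range(1, cfg.n_weeks + 1)

    roster: dict[str, str] = {}
    prefix = {"defender": "D", "forward": "F", "midfielder": "M", "ruck": "R"}
    for pos in POSITIONS:
        for i in range(cfg.squad.get(pos, 0)):
            roster[f"{prefix[pos]}{i + 1:02d}"] = pos

    load_offsets = {pid: float(rng.normal(0, cfg.between_player_load_sd))
                    for pid in roster}
    perf_intercepts = {pid: float(rng.normal(0, cfg.player_perf_intercept_sd))
                       for pid in roster}

    sessions: list[SessionRecord] = []
    wellness: list[WellnessRecord] = []
    problems: set[tuple[str, int]] = set()
    played: dict[tuple[str, int], bool] = {}
    realized_loads: list[dict] = []

    for pid, pos in roster.items():
        mean, within_sd = cfg.load_moments[pos]
        # AR(1) with the configured marginal SD (reduces to i.i.d. at rho=0)
        eps = np.empty(cfg.n_weeks)
        eps[0] = rng.normal(0, within_sd)
        innov_sd = within_sd * np.sqrt(1 - cfg.ar1_rho ** 2)
        for t in range(1, cfg.n_weeks):
            eps[t] = cfg.ar1_rho * eps[t - 1] + rng.normal(0, innov_sd)
        for wk, e in zip(weeks, eps):
            target = max(mean + load_offsets[pid] + e, _MIN_TARGET)
            problem = rng.random() < cfg.problem_prob
            play = rng.random() < cfg.match_play_prob[pos]
            items, match_fields, train_td, train_hvd, realized = _decompose_week(
                target, play, problem, cfg, rng)
            if problem:
                problems.add((pid, wk))
            played[(pid, wk)] = play
            realized_loads.append({"player_id": pid, "week_index": wk,
                                   "target": realized})
            wellness.append(WellnessRecord(pid, wk, items))
            td_splits = [s * train_td for s in _SESSION_SPLIT]
            hvd_splits = [0.6 * train_hvd, 0.4 * train_hvd, 0.0, 0.0]
            kinds = ["training", "training", "recovery", "recovery"]
            for kind, td, hvd in zip(kinds, td_splits, hvd_splits):
                sessions.append(SessionRecord(pid, wk, kind, td, hvd))
            if match_fields is not None:
                sessions.append(SessionRecord(
                    pid, wk, "match", match_fields["match_td"],
                    match_fields["match_hvd"], match_fields["work_rate"],
                    match_fields["accels"], match_fields["decels"]))

    target_df = pd.DataFrame(realized_loads)

    # resolve the dose measure per player-week from the realized loads
    dr = cfg.dose_response
    if dr.measure_name == "weekly":
        measure = target_df.rename(columns={"target": "value"}).copy()
    else:
        measures = derive_measures(
            target_df.rename(columns={"target": "weekly"}))
        measure = measures[measures["measure_name"] == dr.measure_name][
            ["player_id", "week_index", "value"]].copy()
    measure["position"] = measure["player_id"].map(roster)

    center: dict[str, float] = {}
    sd_used: dict[str, float] = {}
    for pos in POSITIONS:
        if cfg.squad.get(pos, 0) == 0:
            continue
        if dr.measure_name == "weekly":
            center[pos] = cfg.load_moments[pos][0]
            sd_used[pos] = cfg.load_moments[pos][1]
        else:
            sub = measure[measure["position"] == pos]["value"]
            center[pos] = float(sub.mean())
            sd_used[pos] = float(sub.std(ddof=1))

    value_map = {(r.player_id, r.week_index): r.value
                 for r in measure.itertuples()}
    matches: list[MatchRecord] = []
    for (pid, wk), did_play in played.items():
        if not did_play:
            continue
        pos = roster[pid]
        key = (pid, wk)
        if key not in value_map:
            continue  # measure undefined this week (e.g. smoothing transient)
        sd = sd_used[pos]
        x = (value_map[key] - center[pos]) / sd if sd > 0 else 0.0
        perf_mean, perf_sd = cfg.performance_moments[pos]
        perf = (perf_mean + perf_intercepts[pid]
                + dr.b1_sd * x + dr.b2_sd * x * x
                + rng.normal(0, perf_sd))
        subbed_on = rng.random() < cfg.subbed_on_prob
        subbed_off = (not subbed_on) and rng.random() < cfg.subbed_off_prob
        match_time = float(np.clip(rng.normal(85, 10), 40, 100))
        matches.append(MatchRecord(pid, wk, float(perf), match_time,
                                   subbed_on, subbed_off, f"M{wk:02d}"))

    truth = GroundTruth(config=cfg, dose_response=dr,
                        player_load_offsets=load_offsets,
                        player_perf_intercepts=perf_intercepts,
                        measure_center=center, measure_sd=sd_used,
                        target_loads=target_df)
    return sessions, wellness, matches, roster, problems, truth


def true_effect_of_offset(truth: GroundTruth, k: float,
                          position: str | None = None,
                          at_value: float | None = None) -> float:
    """Exact generating delta(k), in performance units, for a k-SD shift.

    By default the shift is taken around the generator's own centre. When an
    estimator evaluates its contrast at a different point (e.g. the sample
    mean of the realized loads), pass that point as ``at_value`` with its
    ``position``: with a quadratic truth the effect of a k-SD shift depends
    on where it starts, delta(k) = b1 k + b2 k^2 + 2 b2 k (x0 - centre)/sd.
    """
    dr = truth.dose_response
    delta = dr.b1_sd * k + dr.b2_sd * k * k
    if at_value is not None:
        if position is None:
            raise ValueError("position is required with at_value")
        offset0 = ((at_value - truth.measure_center[position])
                   / truth.measure_sd[position])
        delta += 2 * dr.b2_sd * k * offset0
    return delta


def season_frame(cfg: SeasonConfig = SeasonConfig(), seed: int | None = None,
                 weights: LoadWeights = LoadWeights()):
    """Simulate, aggregate and score a season in one call.

    Returns ``(obs_frame, measures, truth)``: the player-week observation
    frame, the tidy derived-measure table, and the ground truth.
    """
    sessions, wellness, matches, roster, problems, truth = simulate_squad(cfg, seed)
    obs = aggregate_week(sessions, wellness, matches, roster, problems)
    frame = observations_to_frame(obs)
    weekly = weekly_load_series(frame, weights)
    measures = derive_measures(weekly)
    return frame, measures, truth
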