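"""Data model and I/O for the weekly athlete-monitoring ledger.

Three record kinds arrive as CSV files — per-session GPS summaries, weekly
wellness questionnaires, and per-match performance scores — plus a small
roster mapping each player to a season-long position group. ``aggregate_week``
collapses them onto the player-week grain every downstream computation runs
on: training fields are summed over non-match sessions (recovery sessions
included), match fields are taken from that week's single match.

Week indices are 1-based season weeks. Positions are static per player
(predominant role); the wellness score is assigned to the week it was
recorded in.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

POSITIONS = ("defender", "forward", "midfielder", "ruck")
SESSION_KINDS = ("training", "match", "recovery")
N_WELLNESS_ITEMS = 12


class LedgerError(Exception):
    """Base class for ledger I/O and validation failures."""


class SchemaError(LedgerError):
    """A required column is missing or a header does not match the schema."""


class ValidationError(LedgerError):
    """A field value is out of range; carries the offending row number."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        super().__init__(message if row is None else f"row {row}: {message}")


class AmbiguityError(LedgerError):
    """Two matches recorded for one player-week."""


def _require_nonneg(name: str, value: float, row: int | None = None) -> None:
    if value is not None and value < 0:
        raise ValidationError(f"{name} must be >= 0, got {value}", row)


@dataclass
class SessionRecord:
    """One monitored session: GPS totals for a training, recovery or match bout.

    ``high_velocity_distance`` is the distance covered above 5.5 m/s;
    acceleration/deceleration counts are events beyond +-3 m/s^2. Average
    speed (work rate, m/min) is recorded for matches only.
    """

    player_id: str
    week_index: int
    session_kind: str
    total_distance: float = 0.0
    high_velocity_distance: float = 0.0
    avg_speed: float | None = None
    high_accel_count: int = 0
    high_decel_count: int = 0

    def __post_init__(self):
        if self.session_kind not in SESSION_KINDS:
            raise ValidationError(
                f"session_kind must be one of {SESSION_KINDS}, got {self.session_kind!r}")
        if self.week_index < 1:
            raise ValidationError(f"week_index must be >= 1, got {self.week_index}")
        for name in ("total_distance", "high_velocity_distance",
                     "high_accel_count", "high_decel_count"):
            _require_nonneg(name, getattr(self, name))
        if self.high_velocity_distance > self.total_distance:
            raise ValidationError(
                f"high_velocity_distance ({self.high_velocity_distance}) exceeds "
                f"total_distance ({self.total_distance})")
        if (self.avg_speed is not None) != (self.session_kind == "match"):
            raise ValidationError(
                "avg_speed must be present for match sessions and absent otherwise")


@dataclass
class WellnessRecord:
    """Weekly 12-item wellness questionnaire, each item on a 1-10 Likert scale."""

    player_id: str
    week_index: int
    item_scores: tuple[int, ...]

    def __post_init__(self):
        self.item_scores = tuple(int(s) for s in self.item_scores)
        if len(self.item_scores) != N_WELLNESS_ITEMS:
            raise ValidationError(
                f"expected {N_WELLNESS_ITEMS} wellness items, got {len(self.item_scores)}")
        for s in self.item_scores:
            if not 1 <= s <= 10:
                raise ValidationError(
                    f"wellness item score {s} outside Likert range [1, 10]")

    @property
    def total(self) -> int:
        return sum(self.item_scores)


@dataclass
class MatchRecord:
    """One player's match outcome: performance score and participation details."""

    player_id: str
    week_index: int
    performance_score: float
    match_time_pct: float
    subbed_on: bool = False
    subbed_off: bool = False
    match_id: str = ""

    def __post_init__(self):
        import math
        if not math.isfinite(self.performance_score):
            raise ValidationError("performance_score must be finite")
        if not 0 <= self.match_time_pct <= 100:
            raise ValidationError(
                f"match_time_pct must be in [0, 100], got {self.match_time_pct}")


@dataclass
class WeeklyObservation:
    """One player-week of aggregated load inputs and (if played) match outcome.

    Load inputs are ``None`` when explicitly missing (no sessions recorded
    that week); match fields are ``None`` in weeks without a match.
    ``problem_flag`` marks injury/illness-modified training weeks.
    """

    player_id: str
    position: str
    week_index: int
    training_td: float | None = None
    match_td: float | None = None
    training_hvd: float | None = None
    match_hvd: float | None = None
    match_work_rate: float | None = None
    match_accels: int | None = None
    match_decels: int | None = None
    wellness_total: int | None = None
    performance_score: float | None = None
    match_time_pct: float | None = None
    subbed_on: bool | None = None
    subbed_off: bool | None = None
    problem_flag: bool = False
    match_id: str | None = None

    def __post_init__(self):
        if self.position not in POSITIONS:
            raise ValidationError(
                f"position must be one of {POSITIONS}, got {self.position!r}")
        for name in ("training_td", "match_td", "training_hvd", "match_hvd",
                     "match_work_rate", "match_accels", "match_decels",
                     "wellness_total"):
            _require_nonneg(name, getattr(self, name))

    @property
    def has_sessions(self) -> bool:
        return self.training_td is not None or self.match_td is not None

    @property
    def played_match(self) -> bool:
        return self.performance_score is not None


# ---------------------------------------------------------------------------
# CSV schemas

_SESSION_COLS = ["player_id", "week_index", "session_kind", "total_distance",
                 "high_velocity_distance", "avg_speed", "high_accel_count",
                 "high_decel_count"]
_WELLNESS_COLS = ["player_id", "week_index"] + [
    f"item_{i:02d}" for i in range(1, N_WELLNESS_ITEMS + 1)]
_MATCH_COLS = ["player_id", "week_index", "performance_score", "match_time_pct",
               "subbed_on", "subbed_off", "match_id"]
_ROSTER_COLS = ["player_id", "position"]
_PROBLEM_COLS = ["player_id", "week_index"]


def _check_header(path: Path, header: Sequence[str], required: Sequence[str]) -> None:
    missing = [c for c in required if c not in header]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")


def _read_csv_rows(path: Path, required: Sequence[str]):
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, no header row")
        _check_header(path, reader.fieldnames, required)
        # row numbers are 1-based data rows (header excluded)
        for i, row in enumerate(reader, start=1):
            yield i, row


def _opt_float(v: str) -> float | None:
    return None if v in ("", "NA", "nan") else float(v)


def read_ledger(paths: Mapping[str, str | Path]):
    """Read the ledger CSVs into typed, validated record lists.

    Parameters
    ----------
    paths
        Mapping with keys ``sessions``, ``wellness``, ``matches`` and
        ``roster`` (required), plus optional ``problems`` (player-weeks with
        injury/illness-adjusted training).

    Returns
    -------
    (sessions, wellness, matches, roster, problems)
        Lists of records, a ``{player_id: position}`` dict, and a set of
        ``(player_id, week_index)`` problem keys.
    """
    sessions: list[SessionRecord] = []
    for i, row in _read_csv_rows(Path(paths["sessions"]), _SESSION_COLS):
        try:
            sessions.append(SessionRecord(
                player_id=row["player_id"],
                week_index=int(row["week_index"]),
                session_kind=row["session_kind"],
                total_distance=float(row["total_distance"]),
                high_velocity_distance=float(row["high_velocity_distance"]),
                avg_speed=_opt_float(row["avg_speed"]),
                high_accel_count=int(row["high_accel_count"]),
                high_decel_count=int(row["high_decel_count"]),
            ))
        except ValidationError as e:
            raise ValidationError(str(e.args[0]), row=i) from None

    wellness: list[WellnessRecord] = []
    for i, row in _read_csv_rows(Path(paths["wellness"]), _WELLNESS_COLS):
        try:
            wellness.append(WellnessRecord(
                player_id=row["player_id"],
                week_index=int(row["week_index"]),
                item_scores=tuple(int(row[f"item_{j:02d}"])
                                  for j in range(1, N_WELLNESS_ITEMS + 1)),
            ))
        except ValidationError as e:
            raise ValidationError(str(e.args[0]), row=i) from None

    matches: list[MatchRecord] = []
    for i, row in _read_csv_rows(Path(paths["matches"]), _MATCH_COLS):
        try:
            matches.append(MatchRecord(
                player_id=row["player_id"],
                week_index=int(row["week_index"]),
                performance_score=float(row["performance_score"]),
                match_time_pct=float(row["match_time_pct"]),
                subbed_on=row["subbed_on"] in ("True", "true", "1"),
                subbed_off=row["subbed_off"] in ("True", "true", "1"),
                match_id=row["match_id"],
            ))
        except ValidationError as e:
            raise ValidationError(str(e.args[0]), row=i) from None

    roster: dict[str, str] = {}
    for i, row in _read_csv_rows(Path(paths["roster"]), _ROSTER_COLS):
        if row["position"] not in POSITIONS:
            raise ValidationError(
                f"position must be one of {POSITIONS}, got {row['position']!r}", row=i)
        roster[row["player_id"]] = row["position"]

    problems: set[tuple[str, int]] = set()
    if "problems" in paths and paths["problems"] is not None:
        for i, row in _read_csv_rows(Path(paths["problems"]), _PROBLEM_COLS):
            problems.add((row["player_id"], int(row["week_index"])))

    return sessions, wellness, matches, roster, problems


def write_ledger(outdir: str | Path, sessions: Iterable[SessionRecord],
                 wellness: Iterable[WellnessRecord],
                 matches: Iterable[MatchRecord],
                 roster: Mapping[str, str],
                 problems: Iterable[tuple[str, int]] = ()) -> dict[str, Path]:
    """Write record lists back to the canonical CSV schemas; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {k: outdir / f"{k}.csv"
             for k in ("sessions", "wellness", "matches", "roster", "problems")}

    with open(paths["sessions"], "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_SESSION_COLS)
        for s in sessions:
            w.writerow([s.player_id, int(s.week_index), s.session_kind,
                        repr(float(s.total_distance)),
                        repr(float(s.high_velocity_distance)),
                        "" if s.avg_speed is None else repr(float(s.avg_speed)),
                        int(s.high_accel_count), int(s.high_decel_count)])

    with open(paths["wellness"], "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_WELLNESS_COLS)
        for r in wellness:
            w.writerow([r.player_id, r.week_index, *r.item_scores])

    with open(paths["matches"], "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_MATCH_COLS)
        for m in matches:
            w.writerow([m.player_id, int(m.week_index),
                        repr(float(m.performance_score)),
                        repr(float(m.match_time_pct)),
                        bool(m.subbed_on), bool(m.subbed_off), m.match_id])

    with open(paths["roster"], "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_ROSTER_COLS)
        for pid in sorted(roster):
            w.writerow([pid, roster[pid]])

    with open(paths["problems"], "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_PROBLEM_COLS)
        for pid, wk in sorted(problems):
            w.writerow([pid, wk])

    return paths


# ---------------------------------------------------------------------------
# Aggregation to the player-week grain

def aggregate_week(sessions: Sequence[SessionRecord],
                   wellness: Sequence[WellnessRecord],
                   matches: Sequence[MatchRecord],
                   roster: Mapping[str, str],
                   problems: Iterable[tuple[str, int]] = ()) -> list[WeeklyObservation]:
    """Collapse session/wellness/match records onto the player-week grain.

    Training fields sum GPS totals over all non-match sessions (field and
    recovery alike); match fields come from the week's match session and
    match record. A player-week with two matches raises ``AmbiguityError``.
    Weeks with no sessions at all keep their load inputs ``None`` so that
    downstream load scoring skips them.
    """
    problems = set(problems)
    keys: set[tuple[str, int]] = set()
    sess_by_key: dict[tuple[str, int], list[SessionRecord]] = {}
    for s in sessions:
        k = (s.player_id, s.week_index)
        sess_by_key.setdefault(k, []).append(s)
        keys.add(k)
    well_by_key: dict[tuple[str, int], WellnessRecord] = {}
    for r in wellness:
        well_by_key[(r.player_id, r.week_index)] = r
        keys.add((r.player_id, r.week_index))
    match_by_key: dict[tuple[str, int], MatchRecord] = {}
    for m in matches:
        k = (m.player_id, m.week_index)
        if k in match_by_key:
            raise AmbiguityError(
                f"two match records for player {m.player_id} week {m.week_index}")
        match_by_key[k] = m
        keys.add(k)

    obs: list[WeeklyObservation] = []
    for pid, wk in sorted(keys):
        if pid not in roster:
            raise ValidationError(f"player {pid!r} missing from roster")
        week_sessions = sess_by_key.get((pid, wk), [])
        match_sessions = [s for s in week_sessions if s.session_kind == "match"]
        if len(match_sessions) > 1:
            raise AmbiguityError(
                f"two match sessions for player {pid} week {wk}")
        train_sessions = [s for s in week_sessions if s.session_kind != "match"]

        o = WeeklyObservation(player_id=pid, position=roster[pid], week_index=wk,
                              problem_flag=(pid, wk) in problems)
        if train_sessions:
            o.training_td = sum(s.total_distance for s in train_sessions)
            o.training_hvd = sum(s.high_velocity_distance for s in train_sessions)
        elif week_sessions:
            o.training_td = 0.0
            o.training_hvd = 0.0
        if match_sessions:
            ms = match_sessions[0]
            o.match_td = ms.total_distance
            o.match_hvd = ms.high_velocity_distance
            o.match_work_rate = ms.avg_speed
            o.match_accels = ms.high_accel_count
            o.match_decels = ms.high_decel_count
        wr = well_by_key.get((pid, wk))
        if wr is not None:
            o.wellness_total = wr.total
        mr = match_by_key.get((pid, wk))
        if mr is not None:
            o.performance_score = mr.performance_score
            o.match_time_pct = mr.match_time_pct
            o.subbed_on = mr.subbed_on
            o.subbed_off = mr.subbed_off
            o.match_id = mr.match_id
        obs.append(o)
    return obs


def observations_to_frame(obs: Sequence[WeeklyObservation]) -> pd.DataFrame:
    """Tabulate observations as a DataFrame (None becomes NaN)."""
    cols = [f.name for f in dc_fields(WeeklyObservation)]
    return pd.DataFrame([{c: getattr(o, c) for c in cols} for o in obs],
                        columns=cols)
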