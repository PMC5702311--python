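#!/usr/bin/env python
"""Score the season into global load, derive all training measures, and
summarise them per position as mean +- within-player SD.

Reads the ledger written by 01_simulate_season.py (falling back to
simulating it if absent) and writes results/measures.csv and
results/descriptives.csv. The printed table mirrors the usual descriptive
layout: one row per measure, one column per position group.
"""

from pathlib import Path

from loadperf.weekly_ledger import (read_ledger, aggregate_week,
                                    observations_to_frame)
from loadperf.load_metrics import weekly_load_series, derive_measures
from loadperf.reports import summarize_descriptives

SEED = 1


def load_frame():
    season = Path("results/season")
    if not season.exists():
        from loadperf.synthetic_season import SeasonConfig, simulate_squad
        sessions, wellness, matches, roster, problems, _ = simulate_squad(
            SeasonConfig(), SEED)
    else:
        sessions, wellness, matches, roster, problems = read_ledger(
            {k: season / f"{k}.csv"
             for k in ("sessions", "wellness", "matches", "roster", "problems")})
    return observations_to_frame(
        aggregate_week(sessions, wellness, matches, roster, problems))


def main():
    frame = load_frame()
    weekly = weekly_load_series(frame)
    measures = derive_measures(weekly)
    desc = summarize_descriptives(frame, measures)

    Path("results").mkdir(exist_ok=True)
    measures.to_csv("results/measures.csv", index=False, float_format="%.6g")
    desc.to_csv("results/descriptives.csv", index=False, float_format="%.6g")

    wide = desc.assign(cell=lambda d: d["mean"].round(0).astype(int).astype(str)
                       + " ± " + d["within_player_sd"].round(0)
                       .fillna(0).astype(int).astype(str)) \
        .pivot_table(index="measure", columns="position", values="cell",
                     aggfunc="first", observed=True)
    print("mean ± within-player SD per position "
          "(monotony and acute:chronic are dimensionless):")
    print(wide.to_string())
    print("\nwrote results/measures.csv and results/descriptives.csv")


if __name__ == "__main__":
    main()
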