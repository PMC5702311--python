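#!/usr/bin/env python
"""Simulate one synthetic in-season block and write its monitoring ledger.

Generates the default squad (13 defenders, 13 forwards, 6 midfielders,
3 rucks) over 24 weeks, writes the session/wellness/match/roster CSVs under
results/season/, and verifies the decomposition contract: scoring the
generated records with the global-load weights reproduces each week's target
load to numerical precision.
"""

import numpy as np

from loadperf.synthetic_season import SeasonConfig, simulate_squad
from loadperf.weekly_ledger import (write_ledger, aggregate_week,
                                    observations_to_frame)
from loadperf.load_metrics import weekly_load_series

SEED = 1


def main():
    cfg = SeasonConfig()
    sessions, wellness, matches, roster, problems, truth = simulate_squad(
        cfg, SEED)
    paths = write_ledger("results/season", sessions, wellness, matches,
                         roster, problems)
    print(f"simulated {len(roster)} players x {cfg.n_weeks} weeks "
          f"(seed {SEED})")
    print(f"  {len(sessions)} sessions, {len(wellness)} wellness entries, "
          f"{len(matches)} player-matches, {len(problems)} problem weeks")

    frame = observations_to_frame(
        aggregate_week(sessions, wellness, matches, roster, problems))
    weekly = weekly_load_series(frame)
    merged = weekly.merge(truth.target_loads, on=["player_id", "week_index"])
    err = float(np.abs(merged["weekly"] - merged["target"]).max())
    print(f"  load-decomposition conservation: max |scored - target| = {err:.2e}")
    for k, p in paths.items():
        print(f"  wrote {p}")


if __name__ == "__main__":
    main()
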