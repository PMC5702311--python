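import pytest

from loadperf.synthetic_season import (SeasonConfig, DoseResponse,
                                       simulate_squad)
from loadperf.weekly_ledger import aggregate_week, observations_to_frame
from loadperf.load_metrics import weekly_load_series, derive_measures


@pytest.fixture(scope="session")
def default_season():
    """One default synthetic season, aggregated and scored (shared, read-only)."""
    sessions, wellness, matches, roster, problems, truth = simulate_squad(
        SeasonConfig(), seed=7)
    obs = aggregate_week(sessions, wellness, matches, roster, problems)
    frame = observations_to_frame(obs)
    weekly = weekly_load_series(frame)
    measures = derive_measures(weekly)
    return {"sessions": sessions, "wellness": wellness, "matches": matches,
            "roster": roster, "problems": problems, "truth": truth,
            "frame": frame, "weekly": weekly, "measures": measures}


def weekly_model_frame(seed, dose_response=DoseResponse(), **cfg_kwargs):
    """Simulate a season and join weekly load onto the observation frame.

    Shared helper for recovery tests: returns (model_frame, truth) where the
    model frame has the ``value`` column the effect models expect.
    """
    cfg = SeasonConfig(dose_response=dose_response, **cfg_kwargs)
    sessions, wellness, matches, roster, problems, truth = simulate_squad(cfg, seed)
    frame = observations_to_frame(
        aggregate_week(sessions, wellness, matches, roster, problems))
    weekly = weekly_load_series(frame)
    mf = frame.merge(weekly.rename(columns={"weekly": "value"}),
                     on=["player_id", "week_index"])
    return mf, truth
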