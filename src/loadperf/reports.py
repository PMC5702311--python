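"""Pipeline driver and report builders.

Runs ledger -> load measures -> mixed-model fits -> magnitude-based
inference over a real or simulated season and writes three report surfaces:

* a descriptives table (per-position mean +- within-player SD of every
  measure, plus the performance score);
* an effects table (the +-1 SD changes in performance with 90% CL,
  qualifiers and a training recommendation, one row per measure x position);
* predicted performance curves over -2..+2 SD of each measure, with
  confidence bands (optionally rendered to a figure).

Positions with very few players (rucks in the default squad) produce wide,
often unclear estimates; the pipeline reports them with a small-sample
warning rather than suppressing them. All randomness flows from the
config seed and reports embed the fully-resolved configuration, so a rerun
with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from loadperf.weekly_ledger import POSITIONS, read_ledger, aggregate_week, \
    observations_to_frame, write_ledger
from loadperf.load_metrics import (LoadWeights, MEASURE_NAMES,
                                   DIMENSIONLESS_MEASURES, weekly_load_series,
                                   derive_measures, within_player_sd)
from loadperf.effect_model import (ModelSpec, ModelError, fit_quadratic_mixed,
                                   effect_at_offsets, predict_performance_curve)
from loadperf.magnitude_inference import (InferenceConfig, annotate_effect,
                                          qualifier_symbol, recommend_training)
from loadperf.synthetic_season import SeasonConfig, simulate_squad

# the measure set reported by default (weekly plus the informative deriveds)
DEFAULT_REPORT_MEASURES = ("weekly", "smooth1.5", "smooth4", "diff1.5",
                           "diff4", "strain", "monotony", "acwr")
SMALL_SAMPLE_PLAYERS = 4
_CSV_FLOAT = "%.10g"


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run.

    Exactly one of ``simulate`` (a :class:`SeasonConfig`) or ``input_paths``
    (the ledger CSV locations) must be provided.
    """

    simulate: SeasonConfig | None = None
    input_paths: dict | None = None
    measures: tuple = DEFAULT_REPORT_MEASURES
    variant: str = "simple"
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    outdir: str | Path = "results/pipeline"
    seed: int = 0
    make_figure: bool = False

    def __post_init__(self):
        if (self.simulate is None) == (self.input_paths is None):
            raise ValueError("provide exactly one of simulate or input_paths")
        unknown = [m for m in self.measures if m not in MEASURE_NAMES]
        if unknown:
            raise ValueError(f"unknown measure(s): {unknown}")


def summarize_descriptives(frame: pd.DataFrame, measures: pd.DataFrame
                           ) -> pd.DataFrame:
    """Per-position mean +- within-player SD of performance and every measure.

    The SD pools each player's week-to-week SD weighted by its degrees of
    freedom; positions where no player has two observations carry a flagged
    (NaN) SD.
    """
    long = measures.merge(frame[["player_id", "position"]].drop_duplicates(),
                          on="player_id")
    perf = frame.dropna(subset=["performance_score"])[
        ["player_id", "position", "week_index", "performance_score"]].rename(
        columns={"performance_score": "value"})
    perf["measure_name"] = "performance"
    long = pd.concat([perf, long], ignore_index=True)

    rows = []
    for (measure, pos), grp in long.groupby(["measure_name", "position"],
                                            observed=True, sort=False):
        per_player = [(g["value"].std(ddof=1), len(g) - 1)
                      for _, g in grp.groupby("player_id") if len(g) >= 2]
        try:
            sd = within_player_sd(per_player) if per_player else float("nan")
        except ValueError:
            sd = float("nan")
        units = ("dimensionless" if measure in DIMENSIONLESS_MEASURES
                 else "arbitrary units")
        rows.append({"measure": measure, "position": pos,
                     "mean": float(grp["value"].mean()),
                     "within_player_sd": sd, "n_obs": len(grp), "units": units})
    out = pd.DataFrame(rows)
    order = ["performance"] + list(MEASURE_NAMES)
    out["measure"] = pd.Categorical(out["measure"], categories=order, ordered=True)
    out["position"] = pd.Categorical(out["position"], categories=POSITIONS,
                                     ordered=True)
    return out.sort_values(["measure", "position"], ignore_index=True)


def _measure_within_sd(long: pd.DataFrame) -> float:
    per_player = [(g["value"].std(ddof=1), len(g) - 1)
                  for _, g in long.groupby("player_id") if len(g) >= 2]
    return within_player_sd(per_player)


def _model_frame(frame: pd.DataFrame, measures: pd.DataFrame,
                 measure: str) -> pd.DataFrame:
    vals = measures[measures["measure_name"] == measure][
        ["player_id", "week_index", "value"]]
    cols = ["player_id", "position", "week_index", "performance_score",
            "match_time_pct", "subbed_on", "subbed_off", "match_id",
            "problem_flag"]
    return frame[cols].merge(vals, on=["player_id", "week_index"], how="inner")


def build_effects_table(frame: pd.DataFrame, measures: pd.DataFrame,
                        measure_list=DEFAULT_REPORT_MEASURES,
                        variant: str = "simple",
                        cfg: InferenceConfig = InferenceConfig()):
    """Fit every measure x position and tabulate +-1 SD effects.

    Returns ``(effects_table, fits, log)``: the report DataFrame, the raw
    fit objects keyed by (measure, position), and a list of log lines
    (fallbacks, skipped fits, small-sample warnings).
    """
    rows, fits, log = [], {}, []
    for measure in measure_list:
        mf = _model_frame(frame, measures, measure)
        for pos in POSITIONS:
            sub = mf[mf["position"] == pos]
            usable = sub.dropna(subset=["value", "performance_score"])
            if usable.empty:
                continue
            n_players = usable["player_id"].nunique()
            if n_players < SMALL_SAMPLE_PLAYERS:
                log.append(f"{measure}/{pos}: only {n_players} players; "
                           "estimates will be wide")
            try:
                sd = _measure_within_sd(usable)
                fit = fit_quadratic_mixed(mf, ModelSpec(measure, pos, variant))
            except (ModelError, ValueError) as e:
                log.append(f"{measure}/{pos}: skipped ({e})")
                continue
            if fit.fallback:
                log.append(f"{measure}/{pos}: {fit.fallback}")
            if not fit.converged:
                log.append(f"{measure}/{pos}: non-convergent, excluded from report")
                continue
            raw_effects = effect_at_offsets(fit, fit.center, sd)
            if any(not np.isfinite(e.cl90) or e.cl90 <= 0 for e in raw_effects):
                log.append(f"{measure}/{pos}: degenerate fixed-effect covariance, "
                           "excluded from report")
                continue
            fits[(measure, pos)] = (fit, sd)
            effects = {e.offset: annotate_effect(e, cfg) for e in raw_effects}
            m1, p1 = effects[-1.0], effects[1.0]
            rows.append({
                "measure": measure, "position": pos,
                "delta_minus1": m1.delta, "cl90_minus1": m1.cl90,
                "standardized_minus1": m1.standardized,
                "magnitude_minus1": m1.magnitude,
                "qualifier_minus1": m1.qualifier,
                "code_minus1": qualifier_symbol(
                    m1.qualifier, "positive" if m1.delta >= 0 else "negative"),
                "delta_plus1": p1.delta, "cl90_plus1": p1.cl90,
                "standardized_plus1": p1.standardized,
                "magnitude_plus1": p1.magnitude,
                "qualifier_plus1": p1.qualifier,
                "code_plus1": qualifier_symbol(
                    p1.qualifier, "positive" if p1.delta >= 0 else "negative"),
                "recommendation": recommend_training(m1, p1, cfg),
                "n_obs": fit.n_obs, "n_players": fit.n_players,
                "fallback": fit.fallback,
            })
    return pd.DataFrame(rows), fits, log


def build_curves(fits: dict, grid=None) -> pd.DataFrame:
    """Predicted performance curves (-2..+2 SD) for every fitted model."""
    if grid is None:
        grid = np.round(np.arange(-2.0, 2.01, 0.25), 4)
    frames = []
    for (measure, pos), (fit, sd) in fits.items():
        cur = predict_performance_curve(fit, fit.center, sd, grid)
        cur.insert(0, "position", pos)
        cur.insert(0, "measure", measure)
        frames.append(cur)
    if not frames:
        return pd.DataFrame(columns=["measure", "position", "offset",
                                     "measure_value", "predicted", "cl90"])
    return pd.concat(frames, ignore_index=True)


def plot_curves(curves: pd.DataFrame, path: str | Path) -> None:
    """Render the predicted-performance curves, one panel per measure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    measures = curves["measure"].unique()
    ncol = min(4, max(1, len(measures)))
    nrow = int(np.ceil(len(measures) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3.2 * nrow),
                             squeeze=False, sharex=True)
    for ax, measure in zip(axes.flat, measures):
        for pos, grp in curves[curves["measure"] == measure].groupby("position"):
            ax.plot(grp["offset"], grp["predicted"], label=pos)
            ax.fill_between(grp["offset"], grp["predicted"] - grp["cl90"],
                            grp["predicted"] + grp["cl90"], alpha=0.15)
        ax.set_title(measure)
        ax.set_xlabel("within-player SD from mean")
        ax.set_ylabel("predicted performance")
    axes.flat[0].legend(fontsize=8)
    for ax in axes.flat[len(measures):]:
        ax.set_visible(False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _resolved_config_dict(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["outdir"] = str(d["outdir"])
    d["measures"] = list(d["measures"])
    return d


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full pipeline and write the report bundle.

    Returns a dict with the in-memory tables (``descriptives``, ``effects``,
    ``curves``, ``measures``, ``frame``) and the output paths. Writes, under
    ``cfg.outdir``: descriptives.csv, effects.csv, curves.csv, measures.csv,
    resolved_config.yaml and pipeline.log (plus curves.png if requested).
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"seed: {cfg.seed}", f"variant: {cfg.variant}"]

    if cfg.simulate is not None:
        stage = "simulate"
        sessions, wellness, matches, roster, problems, truth = simulate_squad(
            cfg.simulate, seed=cfg.seed)
        write_ledger(outdir / "season", sessions, wellness, matches, roster,
                     problems)
        log.append(f"simulated {len(roster)} players x "
                   f"{cfg.simulate.n_weeks} weeks")
    else:
        stage = "read"
        sessions, wellness, matches, roster, problems = read_ledger(
            cfg.input_paths)
        truth = None
    try:
        stage = "aggregate"
        obs = aggregate_week(sessions, wellness, matches, roster, problems)
        frame = observations_to_frame(obs)
        stage = "load_metrics"
        weekly = weekly_load_series(frame)
        measures = derive_measures(weekly)
        stage = "descriptives"
        descriptives = summarize_descriptives(frame, measures)
        stage = "effect_model"
        effects, fits, fit_log = build_effects_table(
            frame, measures, cfg.measures, cfg.variant, cfg.inference)
        log.extend(fit_log)
        stage = "curves"
        curves = build_curves(fits)
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    descriptives.to_csv(outdir / "descriptives.csv", index=False,
                        float_format=_CSV_FLOAT)
    effects.to_csv(outdir / "effects.csv", index=False, float_format=_CSV_FLOAT)
    curves.to_csv(outdir / "curves.csv", index=False, float_format=_CSV_FLOAT)
    measures.to_csv(outdir / "measures.csv", index=False, float_format=_CSV_FLOAT)
    with open(outdir / "resolved_config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(_resolved_config_dict(cfg), fh, sort_keys=True)
    (outdir / "pipeline.log").write_text("\n".join(log) + "\n", encoding="utf-8")
    if cfg.make_figure and not curves.empty:
        plot_curves(curves, outdir / "curves.png")

    return {"descriptives": descriptives, "effects": effects, "curves": curves,
            "measures": measures, "frame": frame, "fits": fits, "truth": truth,
            "log": log, "outdir": outdir}
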