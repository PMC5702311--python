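#!/usr/bin/env python
"""Estimate each training measure's quadratic dose-response on performance.

Runs the full pipeline (simulate -> score -> fit per measure x position ->
magnitude-based inference) with the default inverted-U truth peaking about
half an SD below the mean load, and writes the effects table, predicted
curves and a rendered figure under results/dose_response/.
"""

from loadperf.reports import PipelineConfig, run_pipeline
from loadperf.synthetic_season import SeasonConfig

SEED = 1


def main():
    cfg = PipelineConfig(simulate=SeasonConfig(),
                         outdir="results/dose_response", seed=SEED,
                         make_figure=True)
    bundle = run_pipeline(cfg)
    eff = bundle["effects"]
    cols = ["measure", "position", "delta_minus1", "cl90_minus1",
            "delta_plus1", "cl90_plus1", "recommendation"]
    print("change in performance for -1/+1 within-player SD of each measure "
          "(mean; ±90%CL):")
    print(eff[cols].round(1).to_string(index=False))
    n_reduce = eff["recommendation"].str.startswith("Reduce").sum()
    print(f"\n{n_reduce}/{len(eff)} measure x position cells recommend "
          "reducing load — the planted decrement above the mean dominates.")
    print("wrote effects.csv, curves.csv and curves.png under "
          "results/dose_response/")


if __name__ == "__main__":
    main()
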