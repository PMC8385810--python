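#!/usr/bin/env python
"""Build the euploid reference panels the screening pipeline standardizes against.

Simulates euploid pregnancies under study conditions (~0.1x depth, library
GC bias, lognormal depth variation), processes them with the three-step GC
correction, and writes panel summaries.  Two panels are produced: the
cohort panel (full chain including intra-run normalization, matching how
the cohort is processed in 02) and a deep ~0.5x panel used for the
subchromosomal-event experiments in 04.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from niptcall.io import setup_logging
from niptcall.pipeline import build_panel_from_sims, default_setup

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"
SEED = 1


def main() -> None:
    setup_logging()
    SCRATCH.mkdir(exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    bins, config = default_setup()

    panel = build_panel_from_sims(bins, seed=SEED, run_size=48)
    panel.to_json(SCRATCH / "panel_cohort.json")

    panel_deep = build_panel_from_sims(
        bins, seed=SEED + 1, n_female=80, n_male=20, depth=15_000_000
    )
    panel_deep.to_json(SCRATCH / "panel_deep.json")

    summary = {
        "panel_cohort": {
            "n_samples": panel.n_samples,
            "chrY_female_background": panel.r_y0,
            "chrY_full_male_share": panel.r_y,
            "chrom_sd_relative": {
                c: panel.chrom_sd[c] / panel.chrom_mean[c]
                for c in ("21", "18", "13", "X")
            },
        },
        "panel_deep": {"n_samples": panel_deep.n_samples, "depth": 15_000_000},
    }
    (RESULTS / "panel_summary.json").write_text(json.dumps(summary, indent=1))
    print("Cohort panel:", panel.n_samples, "euploid samples;",
          "relative SD of the chr21 proportion =",
          f"{summary['panel_cohort']['chrom_sd_relative']['21']:.4f}")
    print("Panels written to scratch/, summary to results/panel_summary.json")


if __name__ == "__main__":
    main()
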