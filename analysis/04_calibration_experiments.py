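#!/usr/bin/env python
"""Calibration and power experiments for the simulation-calling loop.

Measures, end to end (simulate -> GC-correct -> call): the fetal
fraction/gestational-age correlation of the generator; euploid z-score
calibration; T21 detection power as a function of fetal fraction; chrY
fetal-fraction estimator recovery; sex-karyotype recovery; 3-Mb CNV
boundary recovery at ~0.5x depth; and the variance reduction delivered
by the GC-correction chain.  Writes results/calibration.json and a
power-curve table.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from niptcall import ReferencePanel
from niptcall.io import setup_logging
from niptcall.pipeline import (
    build_panel_from_sims,
    cnv_recovery,
    default_setup,
    euploid_false_positive_rate,
    euploid_z_stats,
    ff_ga_correlation,
    ff_recovery,
    gc_correction_sd_reduction,
    sex_karyotype_recovery,
    trisomy_detection_rate,
)

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"
SEED = 21


def main() -> None:
    setup_logging()
    bins, config = default_setup()
    panel = build_panel_from_sims(bins, seed=SEED)
    panel_deep = ReferencePanel.from_json(SCRATCH / "panel_deep.json")

    out = {}
    out["ff_ga_pearson_r"] = ff_ga_correlation(n=5000, seed=SEED)
    mean, sd = euploid_z_stats(panel, bins, seed=SEED + 1, n=100)
    out["euploid_z21"] = {"mean": mean, "sd": sd, "n": 100}

    power_rows = []
    for ff in (0.04, 0.06, 0.08, 0.10, 0.12):
        rate = trisomy_detection_rate(panel, bins, seed=SEED + 2, ff=ff, n=100)
        power_rows.append((ff, rate))
    with open(RESULTS / "t21_power_curve.tsv", "w") as fh:
        fh.write("fetal_fraction\tdetection_rate\n")
        for ff, rate in power_rows:
            fh.write(f"{ff:.2f}\t{rate:.3f}\n")
    out["t21_power"] = {f"{ff:.2f}": rate for ff, rate in power_rows}

    out["euploid_false_positive_rate"] = euploid_false_positive_rate(
        panel, bins, seed=SEED + 3, n=500
    )
    ff_mean, ff_sd = ff_recovery(panel, bins, seed=SEED + 4, true_ff=0.10, n=200)
    out["ff_recovery_at_0p10"] = {"mean": ff_mean, "sd": ff_sd, "n": 200}
    out["sex_karyotype_recovery"] = {
        k: sex_karyotype_recovery(panel, bins, seed=SEED + 5, karyotype=k, n=50)
        for k in ("XO", "XXY", "XXX", "XYY")
    }
    rec = cnv_recovery(panel_deep, bins, seed=SEED + 6, ff=0.15, n=100, depth=15_000_000)
    out["cnv_3mb_recovery"] = {
        "detected": rec.detected, "boundary_within_1_window": rec.boundary_ok, "n": rec.n,
    }
    reduced, total = gc_correction_sd_reduction(bins, seed=SEED + 7, n=50)
    out["gc_sd_reduction"] = {"autosomes_reduced": reduced, "autosomes": total}

    (RESULTS / "calibration.json").write_text(json.dumps(out, indent=1, default=float))
    print(json.dumps(out, indent=1, default=float))


if __name__ == "__main__":
    main()
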