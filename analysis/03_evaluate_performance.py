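#!/usr/bin/env python
"""Screening-performance tables for the simulated cohort, plus the
published cohort's arithmetic recomputed from its printed counts.

Reads scratch/cohort_records.csv (written by 02), builds the per-class
and per-indication performance tables, runs the chi-square comparison of
positive rates between the advanced-maternal-age and abnormal-serum-
screening strata of the simulated cohort, and reproduces the published
cohort's headline statistics (PPVs, rates, chi-squares) from printed
counts so the two can be read side by side.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from niptcall import chi_square_2x2, confusion_stats, records_from_counts, stratified_report
from niptcall.evaluate import pct2, round2
from niptcall.simulate import CohortRecord

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"


def load_records() -> list[CohortRecord]:
    df = pd.read_csv(SCRATCH / "cohort_records.csv", keep_default_na=False)
    records = []
    for row in df.itertuples(index=False):
        pos = [c for c in str(row.positive_classes).split(";") if c]
        records.append(
            CohortRecord(
                sample_id=row.sample_id, maternal_age=float(row.maternal_age),
                ga_weeks=float(row.ga_weeks), bmi=float(row.bmi),
                indication=row.indication,
                nipt_result={c: "positive" for c in pos},
                confirmation=row.confirmation, notes=str(row.notes),
            )
        )
    return records


def main() -> None:
    records = load_records()
    rep = stratified_report(records)
    rep.by_class.to_csv(RESULTS / "performance_by_class.tsv", sep="\t")
    rep.by_indication.round(2).to_csv(RESULTS / "performance_by_indication.tsv", sep="\t")

    ama = rep.by_indication.loc["AMA"]
    amss = rep.by_indication.loc["aMSS"]
    chi2_sim, _, p_sim = chi_square_2x2(
        int(ama["P"]), int(ama["n"] - ama["P"]), int(amss["P"]), int(amss["n"] - amss["P"])
    )

    published = {
        "ppv_pct": {
            "T21": pct2(confusion_stats(49, 45, 0, 0).ppv),
            "T18": pct2(confusion_stats(16, 11, 0, 0).ppv),
            "T13": pct2(confusion_stats(16, 6, 0, 0).ppv),
            "SCA": pct2(confusion_stats(63, 42, 0, 0).ppv),
            "XO": pct2(confusion_stats(29, 22, 0, 0).ppv),
            "CNV": pct2(confusion_stats(14, 2, 0, 0).ppv),
        },
        "sensitivity_t21_pct": pct2(confusion_stats(49, 45, 1, 0).sensitivity),
        "overall_positive_rate_pct": stratified_report(
            records_from_counts(14_316, {
                "T21": (49, 45), "T18": (16, 11), "T13": (16, 6),
                "XO": (29, 22), "XXY": (16, 8), "XYY": (9, 5), "XXX": (9, 3),
                "CNV": (14, 2), "other_autosomal": (31, 2),
            })
        ).positive_rate_pct,
        "chi2_ama_vs_amss": round2(chi_square_2x2(63, 3232, 24, 7584)[0]),
        "chi2_policy_periods": round2(chi_square_2x2(182, 415, 3113, 10606)[0]),
    }
    out = {
        "simulated": {
            "positive_rate_pct": rep.positive_rate_pct,
            "confirmed_fraction_pct": rep.confirmed_fraction_pct,
            "chi2_ama_vs_amss": round2(chi2_sim),
            "chi2_p_value": p_sim,
            "ppv_pct": {
                c: rep.by_class.loc[c, "PPV_pct"]
                for c in ("T21", "T18", "T13", "XO")
            },
        },
        "published_from_printed_counts": published,
    }
    (RESULTS / "performance_summary.json").write_text(
        json.dumps(out, indent=1, default=float)
    )
    print("Simulated cohort:")
    print(rep.by_class[["P", "TP", "FN", "PPV_pct", "sensitivity_pct"]])
    print(f"\npositive rate {rep.positive_rate_pct}%, "
          f"confirmed fraction {rep.confirmed_fraction_pct}%")
    print(f"AMA vs aMSS positive rates: chi2 = {round2(chi2_sim)} (p = {p_sim:.2g})")
    print("\nPublished-cohort arithmetic (from printed counts):")
    print(json.dumps(published, indent=1))


if __name__ == "__main__":
    main()
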