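"""Screening-performance arithmetic: confusion statistics, chi-square
group comparisons, correlations, and indication-stratified tables.

Conventions follow clinical screening practice: P is the number of
screen-positive cases, TP those confirmed by invasive diagnosis,
PPV = TP/P, sensitivity = TP/(TP+FN).  Specificity and NPV are computed
against the followed-up pool only — cases without a genetic diagnosis or
with incomplete pregnancy are excluded before computation.  Display
rounding is half-up to two decimals; internal values keep full precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import CohortRecord

ABNORMALITY_CLASSES = (
    "T21", "T18", "T13", "XO", "XXY", "XXX", "XYY", "CNV", "other_autosomal"
)
SCA_CLASSES = ("XO", "XXY", "XXX", "XYY")


def round2(x: float) -> float:
    """Half-up rounding to 2 decimals (display convention)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def pct2(x: float) -> float:
    """A proportion as a percentage rounded half-up to 2 decimals."""
    return round2(100.0 * x)


@dataclass
class ConfusionStats:
    """Screening confusion statistics; NaN marks an undefined (NA) cell."""

    p: int
    tp: int
    fn: int
    tn: int
    ppv: float
    sensitivity: float
    specificity: float
    npv: float

    @property
    def fp(self) -> int:
        return self.p - self.tp


def confusion_stats(p: int, tp: int, fn: int, tn_pool: int) -> ConfusionStats:
    """Compute PPV/sensitivity/specificity/NPV from followed-up counts.

    ``tn_pool`` is the number of screen-negative (or unconfirmed-positive
    excluded) cases established negative through confirmation or
    follow-up; it is the denominator base for specificity and NPV.
    Undefined ratios (zero denominators) are returned as NaN.
    """
    if min(p, tp, fn, tn_pool) < 0:
        raise ValueError("counts must be non-negative")
    if tp > p:
        raise ValueError("TP cannot exceed P")
    fp = p - tp
    ppv = tp / p if p > 0 else math.nan
    sens = tp / (tp + fn) if tp + fn > 0 else math.nan
    spec = tn_pool / (tn_pool + fp) if tn_pool + fp > 0 else math.nan
    npv = tn_pool / (tn_pool + fn) if tn_pool + fn > 0 else math.nan
    return ConfusionStats(p=p, tp=tp, fn=fn, tn=tn_pool,
                          ppv=ppv, sensitivity=sens, specificity=spec, npv=npv)


def chi_square_2x2(a: int, b: int, c: int, d: int) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) on [[a, b], [c, d]].

    Returns (statistic, df=1, p-value).  Rejects tables with a zero
    margin, where the statistic is undefined.
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero margin in 2x2 table")
    stat, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), int(dof), float(p)


def pearson_r(x, y) -> float:
    """Product-moment correlation; rejects constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    return float(stats.pearsonr(x, y).statistic)


def records_frame(records: list[CohortRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        pos_classes = [k for k, v in r.nipt_result.items() if v == "positive"]
        rows.append(
            dict(
                sample_id=r.sample_id, maternal_age=r.maternal_age,
                ga_weeks=r.ga_weeks, bmi=r.bmi, indication=r.indication,
                positive=bool(pos_classes),
                positive_classes=";".join(sorted(pos_classes)),
                confirmation=r.confirmation,
            )
        )
    return pd.DataFrame(rows)


@dataclass
class PerformanceTable:
    """Stratified screening performance plus headline rates."""

    by_class: pd.DataFrame          # per class: P, TP, FN, TN, PPV, sensitivity, ...
    by_indication: pd.DataFrame     # per indication x class: P, TP, PPV + demographics
    n_total: int
    n_positive: int
    positive_rate_pct: float        # P/N x 100, 2 dp
    confirmed_fraction_pct: float   # confirmed positives among positives, 2 dp


def stratified_report(records: list[CohortRecord]) -> PerformanceTable:
    """Per-class and per-indication screening performance tables.

    A record is screen-positive for a class if its ``nipt_result`` maps
    that class to "positive"; TP requires ``confirmation ==
    "confirmed_positive"``.  Declined/lost cases stay in P but cannot be
    TP; the followed-up negative pool per class is the count of records
    (screen-negative for that class) with ``confirmed_negative``.
    """
    n = len(records)
    if n == 0:
        empty = pd.DataFrame()
        return PerformanceTable(empty, empty, 0, 0, math.nan, math.nan)

    class_rows = []
    for cls in ABNORMALITY_CLASSES:
        pos = [r for r in records if r.nipt_result.get(cls) == "positive"]
        p = len(pos)
        tp = sum(r.confirmation == "confirmed_positive" for r in pos)
        neg = [r for r in records if r.nipt_result.get(cls, "negative") == "negative"]
        fn = sum(
            r.confirmation == "confirmed_positive" and cls in r.notes for r in neg
        )
        tn = sum(r.confirmation == "confirmed_negative" for r in neg)
        cs = confusion_stats(p, tp, fn, tn)
        class_rows.append(
            dict(
                abnormality=cls, P=p, TP=tp, FN=fn, TN=tn,
                PPV_pct=pct2(cs.ppv) if p > 0 else math.nan,
                sensitivity_pct=pct2(cs.sensitivity) if tp + fn > 0 else math.nan,
                specificity_pct=pct2(cs.specificity) if tn + cs.fp > 0 else math.nan,
                NPV_pct=pct2(cs.npv) if tn + fn > 0 else math.nan,
            )
        )
    by_class = pd.DataFrame(class_rows).set_index("abnormality")

    ind_rows = []
    for ind, group in _group_by_indication(records).items():
        row = dict(
            indication=ind,
            n=len(group),
            pct_of_cohort=pct2(len(group) / n),
            maternal_age_mean=float(np.mean([r.maternal_age for r in group])),
            maternal_age_sd=float(np.std([r.maternal_age for r in group], ddof=1))
            if len(group) > 1 else math.nan,
            ga_mean=float(np.mean([r.ga_weeks for r in group])),
            ga_sd=float(np.std([r.ga_weeks for r in group], ddof=1))
            if len(group) > 1 else math.nan,
        )
        pos = [r for r in group if any(v == "positive" for v in r.nipt_result.values())]
        row["P"] = len(pos)
        row["TP"] = sum(r.confirmation == "confirmed_positive" for r in pos)
        row["PPV_pct"] = pct2(row["TP"] / row["P"]) if row["P"] > 0 else math.nan
        for cls in ("T21", "T18", "T13"):
            cp = [r for r in group if r.nipt_result.get(cls) == "positive"]
            row[f"{cls}_P"] = len(cp)
            row[f"{cls}_TP"] = sum(r.confirmation == "confirmed_positive" for r in cp)
        sca_p = [
            r for r in group
            if any(r.nipt_result.get(c) == "positive" for c in SCA_CLASSES)
        ]
        row["SCA_P"] = len(sca_p)
        row["SCA_TP"] = sum(r.confirmation == "confirmed_positive" for r in sca_p)
        ind_rows.append(row)
    by_indication = pd.DataFrame(ind_rows).set_index("indication")

    positives = [r for r in records if any(v == "positive" for v in r.nipt_result.values())]
    n_pos = len(positives)
    n_conf = sum(r.confirmation == "confirmed_positive" for r in positives)
    return PerformanceTable(
        by_class=by_class,
        by_indication=by_indication,
        n_total=n,
        n_positive=n_pos,
        positive_rate_pct=pct2(n_pos / n),
        confirmed_fraction_pct=pct2(n_conf / n_pos) if n_pos > 0 else math.nan,
    )


def _group_by_indication(records: list[CohortRecord]) -> dict[str, list[CohortRecord]]:
    out: dict[str, list[CohortRecord]] = {}
    for r in records:
        out.setdefault(r.indication, []).append(r)
    return out


def records_from_counts(
    n_total: int,
    class_positives: dict[str, tuple[int, int]],
    indication: str = "voluntary",
) -> list[CohortRecord]:
    """Expand printed summary counts into an explicit record list.

    ``class_positives`` maps abnormality class to (P, TP); the remaining
    records are screen-negative with confirmed-negative follow-up.  This
    lets published tables be re-evaluated through the same code path as
    simulated cohorts.
    """
    records: list[CohortRecord] = []
    i = 0
    for cls, (p, tp) in class_positives.items():
        if tp > p:
            raise ValueError(f"{cls}: TP > P")
        for j in range(p):
            records.append(
                CohortRecord(
                    sample_id=f"P{i:05d}", maternal_age=30.0, ga_weeks=17.0,
                    bmi=22.5, indication=indication,
                    nipt_result={cls: "positive"},
                    confirmation="confirmed_positive" if j < tp else "declined",
                )
            )
            i += 1
    while i < n_total:
        records.append(
            CohortRecord(
                sample_id=f"P{i:05d}", maternal_age=30.0, ga_weeks=17.0,
                bmi=22.5, indication=indication, nipt_result={},
                confirmation="confirmed_negative",
            )
        )
        i += 1
    if i > n_total:
        raise ValueError("more positives than cohort size")
    return records
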