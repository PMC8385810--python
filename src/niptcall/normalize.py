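"""Three-step GC-bias elimination and chromosome proportions.

The chain is (1) per-sample LOESS of count against bin GC, rescaling each
bin by the ratio of the global median fit to its local fit; (2) intra-run
normalization, dividing each bin by its across-sample median within the
sequencing run to strip shared run artifacts; (3) a residual quadratic
regression on GC removing any trend LOESS left behind.  All steps operate
on counts (not log-counts or ratios).  Corrected values are then collapsed
to per-chromosome proportions p_c, the statistic the z-scores standardize.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .genome import BinCounts, GenomeBins

logger = logging.getLogger("niptcall.normalize")


@dataclass
class CorrectedProfile:
    """A sample's per-bin corrected values plus bookkeeping.

    ``values`` is aligned to the full bin table; only bins where
    ``usable`` is True enter proportions and downstream statistics.
    """

    sample_id: str
    values: np.ndarray
    usable: np.ndarray
    run_id: str = "run0"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.usable = np.asarray(self.usable, dtype=bool)
        if self.values.shape != self.usable.shape:
            raise ValueError("values/usable length mismatch")
        if (self.values[self.usable] < 0).any():
            raise ValueError("corrected values must be non-negative")


def loess_gc_correct(
    counts: BinCounts,
    bins: GenomeBins,
    span: float = 0.3,
) -> CorrectedProfile:
    """LOESS-correct raw counts for GC content.

    Fits count ~ gc by locally weighted regression (degree 1, 3
    robustness iterations) over usable bins and rescales each bin by
    median(fit)/fit(gc_b).  The global median count is preserved to
    within ~1%.  If all usable GC values coincide the correction
    degenerates to the identity (logged).
    """
    if not (0 < span <= 1):
        raise ValueError("span must be in (0, 1]")
    usable = bins.usable_mask.copy()
    if usable.sum() < 100:
        raise ValueError("need at least 100 usable bins for LOESS")
    if len(counts.counts) != len(bins):
        raise ValueError("counts length does not match bin model")
    gc = bins.gc
    y = counts.counts.astype(float)
    gcu = gc[usable]
    if np.ptp(gcu) == 0:
        logger.warning("degenerate GC track (all identical); LOESS correction is identity")
        return CorrectedProfile(
            counts.sample_id, y, usable, counts.run_id,
            meta={"loess_span": span, "degenerate_gc": True},
        )
    delta = 0.01 * np.ptp(gcu)
    fitted_u = lowess(
        y[usable], gcu, frac=span, it=3, delta=delta, return_sorted=False
    )
    # interpolate the fit onto non-usable bins so every bin gets a value
    order = np.argsort(gcu)
    fitted = np.interp(gc, gcu[order], fitted_u[order])
    fitted[usable] = fitted_u
    floor = 1e-3 * max(np.median(fitted_u), 1.0)
    bad = fitted <= floor
    if bad.any():
        usable = usable & ~bad
        fitted[bad] = floor
    ref = np.median(fitted_u)
    corrected = np.clip(y * (ref / fitted), 0.0, None)
    # pin the global median to the input's so correction changes shape, not scale
    med_in = np.median(y[usable])
    med_out = np.median(corrected[usable])
    if med_in > 0 and med_out > 0:
        corrected *= med_in / med_out
    return CorrectedProfile(
        counts.sample_id, corrected, usable, counts.run_id,
        meta={"loess_span": span},
    )


def intra_run_normalize(
    profiles: list[CorrectedProfile],
    bins: GenomeBins | None = None,
) -> list[CorrectedProfile]:
    """Remove per-bin artifacts shared by all samples of a sequencing run.

    Each bin is divided by its across-sample median within the run, then
    each sample is rescaled to unit mean over usable bins.  A
    single-sample run is returned unchanged.  Bins whose run median is
    zero are flagged unusable for all run members.

    When ``bins`` is supplied, the median step is restricted to
    autosomes: sex-chromosome dosage carries each sample's fetal sex and
    fetal fraction, so dividing chrX/chrY bins by a cross-sample median
    would cancel the very signal downstream calling measures.  X/Y bins
    are instead divided by the sample's own mean autosomal value, which
    leaves every sex-chromosome share (relative to the autosomal total)
    exactly as in the per-sample profile.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    if len(profiles) == 1:
        return list(profiles)
    mat = np.vstack([p.values for p in profiles])
    usable = np.logical_and.reduce([p.usable for p in profiles])
    sexchrom = (
        np.isin(bins.chrom, ("X", "Y")) if bins is not None
        else np.zeros(mat.shape[1], dtype=bool)
    )
    norm_mask = usable & ~sexchrom
    med = np.median(mat, axis=0)
    dead = norm_mask & (med == 0)
    if dead.any():
        logger.warning("%d bins with zero run median flagged unusable", int(dead.sum()))
        usable = usable & ~dead
        norm_mask = norm_mask & ~dead
    med_safe = np.where(med > 0, med, 1.0)
    out = []
    for p, row in zip(profiles, mat):
        v = row.copy()
        v[norm_mask] = row[norm_mask] / med_safe[norm_mask]
        scale = v[norm_mask].mean()
        if scale > 0:
            v[norm_mask] = v[norm_mask] / scale
        if sexchrom.any():
            raw_auto_mean = row[norm_mask].mean()
            if raw_auto_mean > 0:
                v[sexchrom] = row[sexchrom] / raw_auto_mean
        out.append(
            CorrectedProfile(
                p.sample_id, np.clip(v, 0, None), usable, p.run_id,
                meta={**p.meta, "intra_run": len(profiles)},
            )
        )
    return out


def residualize_linear(profile: CorrectedProfile, bins: GenomeBins) -> CorrectedProfile:
    """Regress corrected values on [gc, gc²] and keep residual + mean.

    Removes any smooth GC trend the earlier steps left; the output keeps
    the input's scale (same mean over the fitted bins).  The fit and the
    adjustment are restricted to autosomes: chrX/chrY values sit far
    from the autosomal level (dosage and, for chrY, near-zero counts),
    and an additive residual correction derived from autosomes would
    shift — or clip away — their small shares.  A rank-deficient design
    (constant GC) is skipped with a log notice.
    """
    mask = profile.usable & ~np.isin(bins.chrom, ("X", "Y"))
    gc = bins.gc[mask]
    y = profile.values[mask]
    X = np.column_stack([np.ones_like(gc), gc, gc**2])
    if np.linalg.matrix_rank(X) < 3:
        logger.warning("constant GC among usable bins; residualization skipped")
        return profile
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    out = profile.values.copy()
    out[mask] = np.clip(y - fitted + fitted.mean(), 0.0, None)
    return CorrectedProfile(
        profile.sample_id, out, profile.usable, profile.run_id,
        meta={**profile.meta, "residualized": True},
    )


def chromosome_proportions(
    profile: CorrectedProfile,
    bins: GenomeBins,
    denominator: str = "autosomal",
) -> pd.Series:
    """Per-chromosome share p_c of the corrected signal over usable bins.

    With ``denominator="autosomal"`` (the default used throughout the
    pipeline) every chromosome's total — including X and Y — is divided
    by the usable *autosomal* total, so autosomal z-scores are decoupled
    from fetal sex: a male fetus lowers the chrX share by ff/2, and with
    an all-chromosome denominator that deficit would leak into every
    autosome as a systematic positive shift of roughly half the fetal
    fraction's effect (~0.5 SD at ff = 0.10).
    ``denominator="all"`` gives shares of the grand total (summing to 1).
    """
    v = profile.values[profile.usable]
    if v.sum() <= 0:
        raise ValueError("all-zero corrected profile")
    chrom = bins.chrom[profile.usable]
    s = pd.Series(v).groupby(pd.Series(chrom)).sum()
    if denominator == "autosomal":
        denom = s[~s.index.isin(["X", "Y"])].sum()
    elif denominator == "all":
        denom = s.sum()
    else:
        raise ValueError("denominator must be 'autosomal' or 'all'")
    if denom <= 0:
        raise ValueError("zero denominator")
    p = s / denom
    p.name = profile.sample_id
    return p


def correct_run(
    counts: list[BinCounts],
    bins: GenomeBins,
    span: float = 0.3,
) -> list[CorrectedProfile]:
    """Full three-step chain for one sequencing run of samples.

    The intra-run median step is autosome-restricted (see
    :func:`intra_run_normalize`); sex-chromosome shares match the
    per-sample profile.
    """
    profiles = [loess_gc_correct(c, bins, span) for c in counts]
    profiles = intra_run_normalize(profiles, bins)
    return [residualize_linear(p, bins) for p in profiles]


def window_proportions(profile: CorrectedProfile, bins: GenomeBins) -> np.ndarray:
    """Per-bin share q_w of the corrected signal (NaN on unusable bins).

    Uses the autosomal denominator, matching chromosome proportions.
    """
    v = profile.values
    autosomal = ~np.isin(bins.chrom, ("X", "Y"))
    total = v[profile.usable & autosomal].sum()
    if total <= 0:
        raise ValueError("all-zero corrected profile")
    q = np.full(len(v), np.nan)
    q[profile.usable] = v[profile.usable] / total
    return q
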