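"""Reference panel, z-scores, fetal fraction, aneuploidy and CNV calls.

A chromosome's z-score is the number of panel standard deviations its
corrected proportion lies from the euploid panel mean.  Decisions follow
the screening rule: z > 3 with fetal fraction >= 4% is reported positive,
with 3 < z < 5 flagged as the gray zone (enriched for false positives);
z >= 5 is a firm positive.  Subchromosomal events are called by combining
consecutive 1-Mb window z-scores with Stouffer's method and requiring
|Z| > 5 (duplication if positive, deletion if negative).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .genome import GenomeBins
from .normalize import CorrectedProfile, chromosome_proportions, window_proportions

logger = logging.getLogger("niptcall.calling")

DECISIONS = ("no_call_low_ff", "negative", "gray_positive", "positive")


@dataclass
class ReferencePanel:
    """Euploid reference statistics for standardizing test samples.

    Per chromosome and per 1-Mb window: mean and (unbiased) SD of the
    corrected proportions across euploid female-fetus panel samples.
    ``r_y0`` is the female (maternal-background) chrY proportion;
    ``r_y`` the chrY proportion of a hypothetical fully fetal male
    sample, calibrated from male panel profiles: a male fetus at
    fraction f shows p_Y ≈ r_y0 + f·(r_y/2 − r_y0).
    """

    chrom_mean: dict[str, float]
    chrom_sd: dict[str, float]
    window_mean: np.ndarray
    window_sd: np.ndarray
    n_samples: int
    r_y0: float
    r_y: float
    sigma_y: float  # SD of male chrY proportion about the calibration line
    loo_z: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def to_json(self, path: str | Path) -> None:
        obj = {
            "chrom_mean": self.chrom_mean,
            "chrom_sd": self.chrom_sd,
            "window_mean": [None if np.isnan(x) else x for x in self.window_mean],
            "window_sd": [None if np.isnan(x) else x for x in self.window_sd],
            "n_samples": self.n_samples,
            "r_y0": self.r_y0,
            "r_y": self.r_y,
            "sigma_y": self.sigma_y,
        }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_json(cls, path: str | Path) -> "ReferencePanel":
        obj = json.loads(Path(path).read_text())
        wm = np.array([np.nan if x is None else x for x in obj["window_mean"]])
        ws = np.array([np.nan if x is None else x for x in obj["window_sd"]])
        return cls(
            chrom_mean=obj["chrom_mean"], chrom_sd=obj["chrom_sd"],
            window_mean=wm, window_sd=ws, n_samples=int(obj["n_samples"]),
            r_y0=float(obj["r_y0"]), r_y=float(obj["r_y"]),
            sigma_y=float(obj["sigma_y"]),
        )


def build_reference_panel(
    female_profiles: list[CorrectedProfile],
    bins: GenomeBins,
    male_profiles: list[CorrectedProfile] | None = None,
    male_ffs: list[float] | None = None,
    min_panel_size: int = 30,
) -> ReferencePanel:
    """Build panel statistics from corrected euploid profiles.

    Female-fetus profiles define the chromosome/window means and SDs and
    the chrY background ``r_y0``.  Male-fetus profiles calibrate the chrY
    fetal-fraction scale: with their externally known fetal fractions
    (``male_ffs``), ``r_y`` is fitted by least squares; without them a
    length-share approximation is used.  Leave-one-out z-scores of panel
    members are retained for QC.
    """
    if len(female_profiles) < min_panel_size:
        raise ValueError(
            f"panel too small: {len(female_profiles)} < min_panel_size={min_panel_size}"
        )
    props = pd.DataFrame([chromosome_proportions(p, bins) for p in female_profiles])
    chrom_mean = props.mean().to_dict()
    chrom_sd = props.std(ddof=1).to_dict()
    for c, s in chrom_sd.items():
        if not s > 0:
            raise ValueError(f"zero panel SD for chromosome {c}")

    # window statistics cover autosomes only: subchromosomal CNV scanning
    # is autosomal, and chrY windows are near-empty in a female panel
    q = np.vstack([window_proportions(p, bins) for p in female_profiles])
    autosomal = ~np.isin(bins.chrom, ("X", "Y"))
    window_mean = np.full(len(bins), np.nan)
    window_sd = np.full(len(bins), np.nan)
    cols = autosomal & ~np.isnan(q).any(axis=0)
    window_mean[cols] = q[:, cols].mean(axis=0)
    window_sd[cols] = q[:, cols].std(axis=0, ddof=1)
    if (window_sd[cols] == 0).any():
        w = int(np.flatnonzero(cols & (window_sd == 0))[0])
        raise ValueError(f"zero panel SD for window index {w}")

    # leave-one-out z per chromosome for panel QC
    n = len(female_profiles)
    loo = {}
    for c in props.columns:
        x = props[c].to_numpy()
        zs = np.empty(n)
        for i in range(n):
            rest = np.delete(x, i)
            zs[i] = (x[i] - rest.mean()) / rest.std(ddof=1)
        loo[c] = zs

    r_y0 = float(chrom_mean.get("Y", 0.0))
    lengths = bins.lengths[bins.usable_mask].astype(float)
    chroms = bins.chrom[bins.usable_mask]
    r_y_length = float(lengths[chroms == "Y"].sum() / lengths.sum())
    sigma_y = float(chrom_sd.get("Y", 0.0))
    if male_profiles:
        p_y = np.array(
            [chromosome_proportions(p, bins).get("Y", 0.0) for p in male_profiles]
        )
        if male_ffs is not None:
            ff = np.asarray(male_ffs, dtype=float)
            if len(ff) != len(p_y):
                raise ValueError("male_ffs length mismatch")
            slope = float(ff @ (p_y - r_y0) / (ff @ ff))
            r_y = 2.0 * (slope + r_y0)
            sigma_y = float(np.std(p_y - r_y0 - slope * ff, ddof=1))
        else:
            r_y = r_y_length
            logger.info("no male fetal fractions supplied; using length-share r_Y")
    else:
        r_y = r_y_length
    return ReferencePanel(
        chrom_mean=chrom_mean, chrom_sd=chrom_sd,
        window_mean=window_mean, window_sd=window_sd,
        n_samples=n, r_y0=r_y0, r_y=r_y, sigma_y=sigma_y, loo_z=loo,
    )


def zscore_chromosomes(profile: CorrectedProfile, bins: GenomeBins, panel: ReferencePanel) -> pd.Series:
    """z_c = (p_c − μ_c)/σ_c for every chromosome present in the panel."""
    p = chromosome_proportions(profile, bins)
    out = {}
    for c, val in p.items():
        if c not in panel.chrom_mean:
            logger.info("chromosome %s absent from panel; omitted", c)
            continue
        out[c] = (val - panel.chrom_mean[c]) / panel.chrom_sd[c]
    return pd.Series(out, name=profile.sample_id)


def zscore_windows(
    profile: CorrectedProfile,
    bins: GenomeBins,
    panel: ReferencePanel,
    within_sample_scaling: bool = True,
) -> np.ndarray:
    """Per-1-Mb-window z (NaN where the window is unusable).

    With ``within_sample_scaling`` (default) the raw panel z track is
    rescaled by the sample's own robust spread (1.4826·MAD over all
    scored windows): libraries sequenced shallower or with stronger GC
    bias than the panel average are noisier window-by-window, and
    without this rescaling their genome-wide z tails trigger spurious
    segment calls.  A real focal event spans too few of the ~2800
    scored windows to move the MAD.
    """
    q = window_proportions(profile, bins)
    z = np.full(len(q), np.nan)
    ok = ~np.isnan(q) & ~np.isnan(panel.window_mean) & (panel.window_sd > 0)
    z[ok] = (q[ok] - panel.window_mean[ok]) / panel.window_sd[ok]
    if within_sample_scaling and ok.sum() >= 100:
        med = np.median(z[ok])
        mad = np.median(np.abs(z[ok] - med))
        scale = 1.4826 * mad
        if scale > 0:
            z[ok] = (z[ok] - med) / scale
    return z


def estimate_fetal_fraction(
    profile: CorrectedProfile,
    bins: GenomeBins,
    panel: ReferencePanel,
    fetal_sex: str,
    override: float | None = None,
) -> float | None:
    """Estimate fetal fraction; chrY-based for male fetuses.

    A male fetus at fraction f contributes f/2 of the fully-male chrY
    share, so f = (p_Y − r_Y0)/(r_Y/2 − r_Y0), clipped to [0, 1].  For a
    female fetus the chrY signal is maternal background only: the
    supplied ``override`` (an external estimate) is returned, or ``None``
    ("ff unavailable") without one.
    """
    if override is not None:
        return float(override)
    if fetal_sex != "male":
        logger.info("%s: female fetus without external ff; ff unavailable", profile.sample_id)
        return None
    p_y = float(chromosome_proportions(profile, bins).get("Y", 0.0))
    denom = panel.r_y / 2 - panel.r_y0
    if denom <= 0:
        raise ValueError("invalid panel chrY calibration (r_Y/2 <= r_Y0)")
    ff = (p_y - panel.r_y0) / denom
    if ff < 0:
        logger.warning("%s: chrY below female background; ff clipped to 0", profile.sample_id)
    return float(np.clip(ff, 0.0, 1.0))


def decide(z: float, ff: float | None, config: RunConfig) -> str:
    """Decision for one target chromosome."""
    if ff is None or ff < config.ff_min:
        return "no_call_low_ff"
    if z >= config.z_gray_upper:
        return "positive"
    if z > config.z_positive_cutoff:
        return "gray_positive"
    return "negative"


def call_aneuploidy(
    z: pd.Series, ff: float | None, config: RunConfig
) -> dict[str, str]:
    """Per-target decisions for the configured target chromosomes."""
    return {c: decide(float(z[c]), ff, config) for c in config.target_chromosomes if c in z}


def classify_sex_karyotype(
    z_x: float,
    z_y: float,
    p_y: float,
    ff: float,
    panel: ReferencePanel,
    x_sd_ratio: float | None = None,
    z_cut: float = 3.0,
) -> str:
    """Classify the fetal sex karyotype (XX/XY/XO/XXY/XXX/XYY).

    Y presence: p_Y above the midpoint between the female background and
    the male expectation at the gating fetal fraction.  Without Y the
    female-panel z_X decides XO (< −z_cut) / XXX (> +z_cut) / XX.  With Y
    the X expectation shifts to μ_X·(1 − ff/2), so z_X is re-centred by
    Δ = (ff/2)·μ_X/σ_X before applying the same ±z_cut rule (XXY restores
    a second X; an extra Y roughly doubles p_Y).  ``ff`` must be at least
    the reporting gate; for XYY it must come from a chrY-independent
    estimate.
    """
    mu_x = panel.chrom_mean["X"]
    sd_x = panel.chrom_sd["X"]
    male_expect = panel.r_y0 + ff * (panel.r_y / 2 - panel.r_y0)
    has_y = p_y > (panel.r_y0 + male_expect) / 2
    if not has_y:
        if z_x < -z_cut:
            return "XO"
        if z_x > z_cut:
            return "XXX"
        return "XX"
    # male fetus: recentre z_X on the XY expectation
    shift = (ff / 2) * mu_x / sd_x
    z_x_male = z_x + shift
    sigma_y = panel.sigma_y if panel.sigma_y > 0 else panel.chrom_sd.get("Y", 1.0)
    z_y_male = (p_y - male_expect) / sigma_y
    xxy = z_x_male > z_cut
    xyy = z_y_male > z_cut
    if xxy and xyy:
        return "undetermined"
    if xxy:
        return "XXY"
    if xyy:
        return "XYY"
    return "XY"


def stouffer_region_z(z_values: np.ndarray) -> float:
    """Stouffer's combined Z of k window z-scores: Σz_i / √k."""
    z = np.asarray(z_values, dtype=float)
    if z.size == 0:
        raise ValueError("empty window set")
    if not np.isfinite(z).all():
        raise ValueError("non-finite window z")
    return float(z.sum() / np.sqrt(z.size))


@dataclass
class CnvSegment:
    """A called microduplication/microdeletion (0-based half-open)."""

    chrom: str
    start: int
    end: int
    combined_z: float
    k: int
    type: str

    def __post_init__(self) -> None:
        if self.end <= self.start or self.k < 1:
            raise ValueError("invalid segment extent")
        expected = "microduplication" if self.combined_z > 0 else "microdeletion"
        if self.type != expected:
            raise ValueError("segment type inconsistent with combined Z sign")


def call_cnv_segments(
    window_z: np.ndarray,
    bins: GenomeBins,
    config: RunConfig,
) -> list[CnvSegment]:
    """Scan per-window z for subchromosomal events.

    Per chromosome, maximal runs of consecutive usable windows with
    single-window |z| above the seed threshold (same sign) are combined
    by Stouffer's method; a segment is emitted iff |Z| exceeds
    ``cnv_z_cutoff`` (> +5 microduplication, < −5 microdeletion).
    Same-sign runs separated by exactly one sub-threshold usable window
    are merged (gap included) when the merged Z still passes.  Runs
    shorter than ``cnv_min_windows`` (default 2) are not emitted: at 1-Mb
    resolution a reportable event spans several windows, and a
    single-window rule converts ordinary z-tail excursions (~2800
    windows scanned per genome) into spurious calls.
    """
    segments: list[CnvSegment] = []
    df = bins.df
    for chrom in bins.chromosomes():
        idx = np.flatnonzero((bins.chrom == chrom) & ~np.isnan(window_z))
        if idx.size == 0:
            continue
        z = window_z[idx]
        runs = _seed_runs(z, config.cnv_seed_z)
        runs = _merge_runs(z, runs, config)
        for lo, hi, sign in runs:
            if hi - lo < config.cnv_min_windows:
                continue
            zz = stouffer_region_z(z[lo:hi])
            if abs(zz) > config.cnv_z_cutoff:
                rows = idx[lo:hi]
                segments.append(
                    CnvSegment(
                        chrom=chrom,
                        start=int(df["start"].iloc[rows[0]]),
                        end=int(df["end"].iloc[rows[-1]]),
                        combined_z=zz,
                        k=hi - lo,
                        type="microduplication" if zz > 0 else "microdeletion",
                    )
                )
    return segments


def _seed_runs(z: np.ndarray, seed_z: float) -> list[tuple[int, int, int]]:
    """Maximal runs (lo, hi, sign) of consecutive same-sign |z| > seed_z."""
    runs = []
    i = 0
    while i < len(z):
        if abs(z[i]) > seed_z:
            sign = 1 if z[i] > 0 else -1
            j = i
            while j < len(z) and abs(z[j]) > seed_z and (z[j] > 0) == (sign > 0):
                j += 1
            runs.append((i, j, sign))
            i = j
        else:
            i += 1
    return runs


def _merge_runs(
    z: np.ndarray, runs: list[tuple[int, int, int]], config: RunConfig
) -> list[tuple[int, int, int]]:
    """Merge same-sign runs separated by one sub-threshold window."""
    if not runs:
        return runs
    merged = [runs[0]]
    for run in runs[1:]:
        lo_p, hi_p, sign_p = merged[-1]
        lo, hi, sign = run
        if sign == sign_p and lo - hi_p == 1:
            candidate = stouffer_region_z(z[lo_p:hi])
            if abs(candidate) > config.cnv_z_cutoff:
                merged[-1] = (lo_p, hi, sign)
                continue
        merged.append(run)
    return merged


@dataclass
class AneuploidyCall:
    """Full per-sample calling result."""

    sample_id: str
    z: pd.Series
    ff: float | None
    decisions: dict[str, str]
    sex_karyotype: str
    cnv_segments: list[CnvSegment] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "z": {k: float(v) for k, v in self.z.items()},
            "ff": self.ff,
            "decisions": self.decisions,
            "sex_karyotype": self.sex_karyotype,
            "cnv_segments": [
                dict(chrom=s.chrom, start=s.start, end=s.end,
                     combined_z=s.combined_z, k=s.k, type=s.type)
                for s in self.cnv_segments
            ],
        }


def call_sample(
    profile: CorrectedProfile,
    bins: GenomeBins,
    panel: ReferencePanel,
    config: RunConfig,
    ff_override: float | None = None,
    call_cnv: bool = True,
) -> AneuploidyCall:
    """End-to-end calling of one corrected profile.

    Fetal sex is inferred from the chrY share, fetal fraction from chrY
    (males) or ``ff_override`` (an external estimate, required for
    female fetuses), then aneuploidy, sex-karyotype and CNV rules apply.
    """
    z = zscore_chromosomes(profile, bins, panel)
    p = chromosome_proportions(profile, bins)
    p_y = float(p.get("Y", 0.0))
    male_expect_gate = panel.r_y0 + config.ff_min * (panel.r_y / 2 - panel.r_y0)
    has_y = p_y > (panel.r_y0 + male_expect_gate) / 2
    sex = "male" if has_y else "female"
    ff = estimate_fetal_fraction(profile, bins, panel, sex, override=ff_override)
    decisions = call_aneuploidy(z, ff, config)
    if ff is not None and ff >= config.ff_min:
        sex_karyotype = classify_sex_karyotype(
            float(z.get("X", 0.0)), float(z.get("Y", 0.0)), p_y, ff, panel
        )
    else:
        sex_karyotype = "undetermined"
    segments = []
    if call_cnv and ff is not None and ff >= config.ff_min:
        wz = zscore_windows(profile, bins, panel)
        segments = call_cnv_segments(wz, bins, config)
    return AneuploidyCall(
        sample_id=profile.sample_id, z=z, ff=ff, decisions=decisions,
        sex_karyotype=sex_karyotype, cnv_segments=segments,
    )
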