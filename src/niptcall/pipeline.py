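"""End-to-end drivers and calibration/power experiments.

Every quantitative claim the package makes about itself (simulator
calibration, euploid z-score behaviour, detection power, false-positive
rate, fetal-fraction recovery, CNV boundary recovery, variance reduction
by GC correction) is computed here, from scratch, by running the
simulator through the correction and calling stages.  Tests, the
analysis scripts and the acceptance script all call these functions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calling import (
    ReferencePanel,
    build_reference_panel,
    call_cnv_segments,
    estimate_fetal_fraction,
    zscore_chromosomes,
    zscore_windows,
)
from .config import RunConfig
from .genome import BinCounts, GenomeBins, default_genome_bins
from .normalize import (
    CorrectedProfile,
    chromosome_proportions,
    loess_gc_correct,
    residualize_linear,
)
from .simulate import (
    FetalFractionModel,
    GcBiasCurve,
    SampleTruth,
    simulate_ff,
    simulate_sample,
)


def process_single(
    counts: BinCounts, bins: GenomeBins, span: float = 0.3
) -> CorrectedProfile:
    """Canonical per-sample correction: LOESS then residual GC regression.

    The intra-run median step applies only when samples are processed as
    a run (see :func:`niptcall.normalize.correct_run`); panel and test
    samples must always share one processing mode, and the per-sample
    mode is the default throughout.
    """
    return residualize_linear(loess_gc_correct(counts, bins, span), bins)


def _draw_curve(rng: np.random.Generator) -> GcBiasCurve:
    """Library-to-library GC bias, varying in amplitude and centre."""
    return GcBiasCurve(
        amplitude=float(rng.normal(0.4, 0.12)),
        center=float(rng.normal(0.42, 0.015)),
        width=0.07,
    )


def simulate_processed(
    truth: SampleTruth,
    bins: GenomeBins,
    depth: int,
    rng: np.random.Generator,
    dispersion: float = 2e-4,
    gc_bias: GcBiasCurve | None = None,
    span: float = 0.3,
) -> CorrectedProfile:
    """Simulate one sample (random library GC bias) and GC-correct it."""
    curve = gc_bias if gc_bias is not None else _draw_curve(rng)
    bc = simulate_sample(truth, bins, depth, gc_bias=curve, rng=rng,
                         dispersion=dispersion)
    return process_single(bc, bins, span)


def build_panel_from_sims(
    bins: GenomeBins,
    seed: int,
    n_female: int = 160,
    n_male: int = 60,
    depth: int = 3_000_000,
    depth_cv: float = 0.15,
    dispersion: float = 2e-4,
    run_size: int | None = None,
    config: RunConfig | None = None,
) -> ReferencePanel:
    """Simulate euploid pregnancies and build the reference panel.

    Panel samples mirror the screening population: per-library GC bias
    and lognormal depth variation (``depth_cv``), so the panel SDs
    calibrate the z-scores of samples sequenced under the same
    conditions.  Panel male fetal fractions are passed to the chrY
    calibration as the externally known values they would be in
    production (orthogonal assay); here they are the simulator's truth.

    With ``run_size`` the panel is processed in mixed-sex batches
    through the full three-step chain (including intra-run
    normalization); panels and test samples must always share one
    processing mode.
    """
    from .simulate import simulate_sample

    config = config or RunConfig()
    rng = np.random.default_rng(seed)

    def _depth() -> int:
        if depth_cv <= 0:
            return int(depth)
        sigma = np.sqrt(np.log(1 + depth_cv**2))
        return max(10_000, int(rng.lognormal(np.log(depth) - 0.5 * sigma**2, sigma)))

    # interleave sexes so run batches are mixed like real runs
    sex_list: list[str] = []
    nf = nm = 0
    for i in range(n_female + n_male):
        if (i % 2 == 0 and nf < n_female) or nm >= n_male:
            sex_list.append("female"); nf += 1
        else:
            sex_list.append("male"); nm += 1
    truths: list[SampleTruth] = []
    ffs: dict[str, float] = {}
    for i, sex in enumerate(sex_list):
        ga = float(np.clip(rng.normal(17.0, 2.8), 10, 30))
        ff = float(simulate_ff(ga, rng=rng))
        t = SampleTruth(sample_id=f"panel{i:03d}", fetal_sex=sex, ff=ff, ga_weeks=ga)
        truths.append(t)
        ffs[t.sample_id] = ff
    sexes = {t.sample_id: t.fetal_sex for t in truths}
    if run_size:
        from .normalize import correct_run

        raw = [
            simulate_sample(t, bins, _depth(), gc_bias=_draw_curve(rng), rng=rng,
                            dispersion=dispersion)
            for t in truths
        ]
        profiles = []
        for lo in range(0, len(raw), run_size):
            profiles.extend(correct_run(raw[lo : lo + run_size], bins))
    else:
        profiles = [
            simulate_processed(t, bins, _depth(), rng, dispersion) for t in truths
        ]
    females = [p for p in profiles if sexes[p.sample_id] == "female"]
    males = [p for p in profiles if sexes[p.sample_id] == "male"]
    male_ffs = [ffs[p.sample_id] for p in males]
    return build_reference_panel(
        females, bins, male_profiles=males, male_ffs=male_ffs,
        min_panel_size=config.min_panel_size,
    )


# ---------------------------------------------------------------------------
# calibration / power experiments
# ---------------------------------------------------------------------------


def ff_ga_correlation(n: int = 5000, seed: int = 0,
                      model: FetalFractionModel | None = None) -> float:
    """Pearson r between gestational age and simulated fetal fraction."""
    from .evaluate import pearson_r

    rng = np.random.default_rng(seed)
    ga = np.clip(rng.normal(16.99, 2.82, size=n), 9, 36)
    ff = simulate_ff(ga, model, rng)
    return pearson_r(ga, ff)


def euploid_z_stats(
    panel: ReferencePanel,
    bins: GenomeBins,
    seed: int,
    n: int = 100,
    depth: int = 3_000_000,
    chrom: str = "21",
) -> tuple[float, float]:
    """Mean and SD of held-out euploid z for one chromosome."""
    rng = np.random.default_rng(seed)
    zs = np.empty(n)
    for i in range(n):
        sex = "female" if i % 2 == 0 else "male"
        t = SampleTruth(sample_id=f"eu{i:03d}", fetal_sex=sex, ff=0.10)
        prof = simulate_processed(t, bins, depth, rng)
        zs[i] = float(zscore_chromosomes(prof, bins, panel)[chrom])
    return float(zs.mean()), float(zs.std(ddof=1))


def trisomy_detection_rate(
    panel: ReferencePanel,
    bins: GenomeBins,
    seed: int,
    karyotype: str = "T21",
    ff: float = 0.10,
    n: int = 200,
    depth: int = 3_000_000,
    z_cutoff: float = 3.0,
) -> float:
    """Fraction of simulated trisomy samples with target-chromosome z above cutoff."""
    rng = np.random.default_rng(seed)
    chrom = karyotype[1:]
    hits = 0
    for i in range(n):
        sex = "female" if i % 2 == 0 else "male"
        t = SampleTruth(sample_id=f"tri{i:03d}", karyotype=karyotype,
                        fetal_sex=sex, ff=ff)
        prof = simulate_processed(t, bins, depth, rng)
        z = float(zscore_chromosomes(prof, bins, panel)[chrom])
        hits += z > z_cutoff
    return hits / n


def euploid_false_positive_rate(
    panel: ReferencePanel,
    bins: GenomeBins,
    seed: int,
    n: int = 500,
    depth: int = 3_000_000,
    z_cutoff: float = 3.0,
    targets: tuple[str, ...] = ("21", "18", "13"),
) -> float:
    """Fraction of euploid samples (ff >= 4%) positive for any target trisomy."""
    rng = np.random.default_rng(seed)
    fp = 0
    for i in range(n):
        sex = "female" if i % 2 == 0 else "male"
        ff = float(np.clip(rng.uniform(0.04, 0.20), 0.04, 1))
        t = SampleTruth(sample_id=f"fp{i:03d}", fetal_sex=sex, ff=ff)
        prof = simulate_processed(t, bins, depth, rng)
        z = zscore_chromosomes(prof, bins, panel)
        fp += any(float(z[c]) > z_cutoff for c in targets)
    return fp / n


def ff_recovery(
    panel: ReferencePanel,
    bins: GenomeBins,
    seed: int,
    true_ff: float = 0.10,
    n: int = 200,
    depth: int = 3_000_000,
) -> tuple[float, float]:
    """Mean and SD of the chrY fetal-fraction estimate on male-fetus sims."""
    rng = np.random.default_rng(seed)
    est = np.empty(n)
    for i in range(n):
        t = SampleTruth(sample_id=f"ffm{i:03d}", fetal_sex="male", ff=true_ff)
        prof = simulate_processed(t, bins, depth, rng)
        est[i] = estimate_fetal_fraction(prof, bins, panel, "male")
    return float(est.mean()), float(est.std(ddof=1))


@dataclass
class CnvRecoveryResult:
    n: int
    detected: int
    boundary_ok: int  # detected with both boundaries within +-1 window

    @property
    def recovery_rate(self) -> float:
        return self.boundary_ok / self.n


def cnv_recovery(
    panel: ReferencePanel,
    bins: GenomeBins,
    seed: int,
    ff: float = 0.15,
    n: int = 100,
    depth: int = 15_000_000,
    chrom: str = "4",
    start: int = 60_000_000,
    size: int = 3_000_000,
    delta: int = -1,
    config: RunConfig | None = None,
) -> CnvRecoveryResult:
    """Recovery of a fixed fetal CNV with +-1-window boundary tolerance.

    The panel must be built at the same depth as the test samples.
    """
    config = config or RunConfig()
    rng = np.random.default_rng(seed)
    bin_size = bins.bin_size
    detected = boundary_ok = 0
    want_type = "microduplication" if delta > 0 else "microdeletion"
    for i in range(n):
        t = SampleTruth(
            sample_id=f"cnv{i:03d}", fetal_sex="female", ff=ff,
            cnv_events=[(chrom, start, start + size, delta)],
        )
        prof = simulate_processed(t, bins, depth, rng)
        wz = zscore_windows(prof, bins, panel)
        segs = [
            s for s in call_cnv_segments(wz, bins, config)
            if s.chrom == chrom and s.type == want_type
        ]
        if not segs:
            continue
        best = max(segs, key=lambda s: min(s.end, start + size) - max(s.start, start))
        if min(best.end, start + size) <= max(best.start, start):
            continue
        detected += 1
        if (abs(best.start - start) <= bin_size
                and abs(best.end - (start + size)) <= bin_size):
            boundary_ok += 1
    return CnvRecoveryResult(n=n, detected=detected, boundary_ok=boundary_ok)


def gc_correction_sd_reduction(
    bins: GenomeBins,
    seed: int,
    n: int = 50,
    depth: int = 3_000_000,
) -> tuple[int, int]:
    """Paired comparison of per-chromosome proportion SD, corrected vs raw.

    Simulates euploid samples whose library GC bias varies sample to
    sample, computes autosomal proportion SDs across samples from raw
    and from GC-corrected values, and returns (number of autosomes with
    reduced SD, number of autosomes compared).
    """
    rng = np.random.default_rng(seed)
    raw_props, cor_props = [], []
    for i in range(n):
        sex = "female" if i % 2 == 0 else "male"
        t = SampleTruth(sample_id=f"gc{i:03d}", fetal_sex=sex, ff=0.10)
        curve = _draw_curve(rng)
        bc = simulate_sample(t, bins, depth, gc_bias=curve, rng=rng, dispersion=2e-4)
        raw = CorrectedProfile(bc.sample_id, bc.counts.astype(float), bins.usable_mask)
        raw_props.append(chromosome_proportions(raw, bins))
        cor_props.append(chromosome_proportions(process_single(bc, bins), bins))
    import pandas as pd

    raw_df = pd.DataFrame(raw_props)
    cor_df = pd.DataFrame(cor_props)
    autosomes = [c for c in raw_df.columns if c not in ("X", "Y")]
    reduced = sum(
        cor_df[c].std(ddof=1) < raw_df[c].std(ddof=1) for c in autosomes
    )
    return int(reduced), len(autosomes)


def sex_karyotype_recovery(
    panel: ReferencePanel,
    bins: GenomeBins,
    seed: int,
    karyotype: str = "XO",
    ff: float = 0.10,
    n: int = 100,
    depth: int = 3_000_000,
) -> float:
    """Fraction of simulated sex-aneuploidy samples classified correctly."""
    from .calling import classify_sex_karyotype

    rng = np.random.default_rng(seed)
    hits = 0
    for i in range(n):
        t = SampleTruth(sample_id=f"sk{i:03d}", karyotype=karyotype, ff=ff)
        prof = simulate_processed(t, bins, depth, rng)
        z = zscore_chromosomes(prof, bins, panel)
        p_y = float(chromosome_proportions(prof, bins).get("Y", 0.0))
        call = classify_sex_karyotype(
            float(z["X"]), float(z["Y"]), p_y, ff, panel
        )
        hits += call == karyotype
    return hits / n


def default_setup(bin_size: int = 1_000_000) -> tuple[GenomeBins, RunConfig]:
    return default_genome_bins(bin_size), RunConfig(bin_size=bin_size)


# ---------------------------------------------------------------------------
# cohort end-to-end
# ---------------------------------------------------------------------------


def screen_cohort(
    records,
    counts,
    truths,
    bins: GenomeBins,
    panel: ReferencePanel,
    config: RunConfig | None = None,
    call_cnv: bool = True,
    by_run: bool = True,
):
    """Run correction + calling over a simulated cohort and fill records.

    With ``by_run`` (default) each sequencing run is corrected with the
    full three-step chain, so shared run artifacts are removed before
    calling; the panel must then be built in the same mode
    (``build_panel_from_sims(..., run_size=...)``).  Fetal fraction
    comes from chrY for male fetuses; for female fetuses the simulator's
    truth stands in for the external estimate a production lab would
    use.  A record is positive for a class when the corresponding rule
    fires (trisomy decisions count gray-zone calls as positive).
    Confirmation outcomes are drawn from the truth for willing
    participants, declined otherwise.
    """
    from .calling import call_sample
    from .genome import AUTOSOMES
    from .normalize import correct_run

    config = config or RunConfig()
    truth_by_id = {t.sample_id: t for t in truths}
    if by_run:
        prof_by_id = {}
        groups: dict[str, list] = {}
        for bc in counts:
            groups.setdefault(bc.run_id, []).append(bc)
        for run_counts in groups.values():
            for p in correct_run(run_counts, bins, span=config.loess_span):
                prof_by_id[p.sample_id] = p
    else:
        prof_by_id = {
            bc.sample_id: process_single(bc, bins, span=config.loess_span)
            for bc in counts
        }
    calls = []
    for rec, bc in zip(records, counts):
        truth = truth_by_id[rec.sample_id]
        prof = prof_by_id[rec.sample_id]
        override = truth.ff if truth.fetal_sex == "female" else None
        call = call_sample(prof, bins, panel, config,
                           ff_override=override, call_cnv=call_cnv)
        calls.append(call)
        positives: set[str] = set()
        for chrom, decision in call.decisions.items():
            if decision in ("positive", "gray_positive"):
                positives.add("T" + chrom)
        if call.ff is not None and call.ff >= config.ff_min:
            # rare (non-target) autosomal trisomies are reported only at
            # the firm threshold: they have no gray-zone workflow, and at
            # z > 3 the 19-chromosome multiplicity alone would flag ~2.5%
            # of euploid pregnancies
            for chrom in AUTOSOMES:
                if chrom in config.target_chromosomes or chrom not in call.z:
                    continue
                if float(call.z[chrom]) >= config.z_gray_upper:
                    positives.add("other_autosomal")
        if call.sex_karyotype in ("XO", "XXY", "XXX", "XYY"):
            positives.add(call.sex_karyotype)
        if call.cnv_segments:
            positives.add("CNV")
        rec.nipt_result = {cls: "positive" for cls in positives}
        truth_cls = truth.abnormality_class
        if positives:
            if rec.confirm_willing:
                rec.confirmation = (
                    "confirmed_positive" if truth_cls in positives
                    else "confirmed_negative"
                )
            else:
                rec.confirmation = "declined"
        else:
            if rec.confirm_willing:
                rec.confirmation = "confirmed_negative"
                if truth_cls != "negative":
                    # missed abnormality surfaced by follow-up diagnosis
                    rec.confirmation = "confirmed_positive"
                    rec.notes = truth_cls
            else:
                rec.confirmation = "lost"
    return calls
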