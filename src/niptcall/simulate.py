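"""Forward simulation of maternal-plasma cfDNA bin counts with known truth.

A plasma sample is a mixture of maternal DNA (fraction ``1 - ff``) and
placental/fetal DNA (fetal fraction ``ff``).  Each bin's expected count is

    lambda_b  ∝  length_b · gc_bias(gc_b) · dosage_b

where ``dosage_b`` is the copy-number dosage of the mixture relative to a
diploid genome: on a fetal event region it is
``1 + ff · mosaic · (copies − 2)/2``; on chrX/chrY the maternal XX
background and the fetal sex karyotype contribute at half weight per
haploid copy.  Counts are drawn total-conserving as a multinomial whose
bin weights carry gamma (negative-binomial) overdispersion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genome import BinCounts, GenomeBins

TRISOMY_TARGETS = ("21", "18", "13")
SEX_KARYOTYPES = {"XO", "XXY", "XXX", "XYY"}

#: Cohort indication mix and per-indication maternal/gestational age
#: (mean, SD), matching a large referral-hospital screening population:
#: abnormal serum screening dominates, then advanced maternal age and
#: voluntary testing.  Proportions sum to 1.
INDICATION_TABLE: dict[str, dict[str, float]] = {
    "AMA":                      dict(prop=0.2302, age=37.39, age_sd=2.37, ga=16.54, ga_sd=2.58),
    "aMSS":                     dict(prop=0.5314, age=28.06, age_sd=3.52, ga=17.40, ga_sd=2.83),
    "thickened_NT":             dict(prop=0.0084, age=27.58, age_sd=3.54, ga=15.32, ga_sd=2.17),
    "aUS":                      dict(prop=0.0078, age=27.69, age_sd=3.22, ga=22.69, ga_sd=3.04),
    "twin_IVF":                 dict(prop=0.0300, age=28.81, age_sd=3.27, ga=15.26, ga_sd=2.05),
    "missed_screening":         dict(prop=0.0003, age=25.80, age_sd=2.99, ga=25.40, ga_sd=0.49),
    "voluntary":                dict(prop=0.1763, age=27.59, age_sd=3.68, ga=16.03, ga_sd=2.23),
    "surgery_contraindication": dict(prop=0.0010, age=27.64, age_sd=2.12, ga=16.29, ga_sd=1.39),
    "other_risk":               dict(prop=0.0146, age=28.44, age_sd=3.41, ga=15.35, ga_sd=2.35),
}

#: Default truth prevalences per abnormality class (fractions of the
#: cohort), on the scale of the confirmed rates observed in large Chinese
#: referral cohorts (~0.3% T21, rarer T18/T13, ~0.3% combined SCA).
DEFAULT_PREVALENCES: dict[str, float] = {
    "T21": 0.0034, "T18": 0.0008, "T13": 0.0005,
    "XO": 0.0016, "XXY": 0.0006, "XXX": 0.0003, "XYY": 0.0004,
    "CNV": 0.0003, "other_autosomal": 0.0004,
}

#: Fraction of screen-positive carriers per class who accept invasive
#: confirmation (48/49 for T21-like classes down to ~42% for CNV).
DEFAULT_CONFIRM_UPTAKE: dict[str, float] = {
    "T21": 48 / 49, "T18": 13 / 16, "T13": 12 / 16,
    "XO": 44 / 63, "XXY": 44 / 63, "XXX": 44 / 63, "XYY": 44 / 63,
    "CNV": 19 / 45, "other_autosomal": 19 / 45, "negative": 0.95,
}


@dataclass
class GcBiasCurve:
    """Smooth unimodal multiplicative library bias: 1 + amp·exp(−(gc−center)²/2w²)."""

    amplitude: float = 0.4
    center: float = 0.42
    width: float = 0.07

    def __call__(self, gc: np.ndarray) -> np.ndarray:
        gc = np.asarray(gc, dtype=float)
        return 1.0 + self.amplitude * np.exp(-((gc - self.center) ** 2) / (2 * self.width**2))


@dataclass
class FetalFractionModel:
    """Linear gestational-age model of fetal fraction with Gaussian noise.

    Defaults give ~10.5% mean ff at 17 weeks rising ~0.5 percentage
    points per week, with noise sized so that ff and gestational age
    correlate at r ≈ 0.70 over a screening cohort.
    """

    intercept: float = 0.020
    slope: float = 0.005  # per gestational week
    noise_sd: float = 0.0145
    lo: float = 0.01
    hi: float = 0.40


@dataclass
class SampleTruth:
    """Ground truth of one simulated pregnancy."""

    sample_id: str
    karyotype: str = "euploid"  # euploid | T<chrom> | M<chrom> | XO/XXY/XXX/XYY | cnv
    fetal_sex: str | None = None  # male | female (implied by sex karyotypes)
    ff: float = 0.10
    mosaic_fraction: float = 1.0
    ga_weeks: float = 17.0
    cnv_events: list[tuple[str, int, int, int]] = field(default_factory=list)
    # each event: (chrom, start, end, delta_copies), fetal copies = 2 + delta
    maternal_abnormality: str | None = None  # e.g. "47,XXX"
    indication: str = "voluntary"

    def __post_init__(self) -> None:
        if not (0 <= self.ff <= 1):
            raise ValueError("ff must be in [0, 1]")
        if not (0 <= self.mosaic_fraction <= 1):
            raise ValueError("mosaic_fraction must be in [0, 1]")
        if not (9 <= self.ga_weeks <= 36):
            raise ValueError("ga_weeks must be in [9, 36]")
        if self.karyotype in SEX_KARYOTYPES:
            implied = "male" if self.karyotype in ("XXY", "XYY") else "female"
            if self.fetal_sex is None:
                self.fetal_sex = implied
        if self.ff > 0 and self.fetal_sex not in ("male", "female"):
            raise ValueError("fetal_sex required when ff > 0")

    @property
    def abnormality_class(self) -> str:
        if self.karyotype in SEX_KARYOTYPES:
            return self.karyotype
        if self.karyotype in ("T21", "T18", "T13"):
            return self.karyotype
        if self.karyotype == "euploid":
            return "CNV" if self.cnv_events else "negative"
        return "other_autosomal"

    def sex_chromosome_copies(self) -> tuple[int, int]:
        """Fetal (X, Y) copy numbers."""
        table = {"XO": (1, 0), "XXY": (2, 1), "XXX": (3, 0), "XYY": (1, 2)}
        if self.karyotype in table:
            return table[self.karyotype]
        return (1, 1) if self.fetal_sex == "male" else (2, 0)


def _autosome_copies(karyotype: str, chrom: str) -> int:
    """Fetal copy number of ``chrom`` under a whole-chromosome karyotype."""
    if karyotype.startswith("T") and karyotype[1:] == chrom:
        return 3
    if karyotype.startswith("M") and karyotype[1:] == chrom:
        return 1
    return 2


def expected_bin_weights(
    truth: SampleTruth,
    bins: GenomeBins,
    gc_bias: GcBiasCurve | None = None,
    y_noise_floor: float = 0.002,
) -> np.ndarray:
    """Deterministic expected multinomial weight per bin (unnormalized).

    ``y_noise_floor`` is the small apparent chrY dosage from misaligned
    reads, present regardless of fetal sex; it sets the female chrY
    baseline used by the chrY fetal-fraction estimator.
    """
    if truth.ff > 0 and truth.fetal_sex is None:
        raise ValueError("fetal_sex required when ff > 0")
    chrom = bins.chrom
    starts = bins.df["start"].to_numpy()
    ends = bins.df["end"].to_numpy()
    f, mos = truth.ff, truth.mosaic_fraction

    # maternal dosage (relative to diploid)
    maternal = np.ones(len(bins))
    maternal[chrom == "Y"] = 0.0
    if truth.maternal_abnormality == "47,XXX":
        maternal[chrom == "X"] = 1.5

    # fetal dosage under the aberrant and the matched normal karyotype
    cx, cy = truth.sex_chromosome_copies()
    nx, ny = (1, 1) if truth.fetal_sex == "male" else (2, 0)
    fetal_ab = np.ones(len(bins))
    fetal_no = np.ones(len(bins))
    for c in set(np.unique(chrom)) - {"X", "Y"}:
        k = _autosome_copies(truth.karyotype, c)
        if k != 2:
            fetal_ab[chrom == c] = k / 2
    fetal_ab[chrom == "X"] = cx / 2
    fetal_no[chrom == "X"] = nx / 2
    fetal_ab[chrom == "Y"] = cy / 2
    fetal_no[chrom == "Y"] = ny / 2
    for ev_chrom, ev_start, ev_end, delta in truth.cnv_events:
        m = (chrom == ev_chrom) & (starts < ev_end) & (ends > ev_start)
        fetal_ab[m] = fetal_ab[m] + delta / 2

    fetal = mos * fetal_ab + (1 - mos) * fetal_no
    dosage = (1 - f) * maternal + f * fetal
    dosage[chrom == "Y"] += y_noise_floor

    bias = gc_bias(bins.gc) if gc_bias is not None else 1.0
    w = bins.lengths.astype(float) * bias * dosage
    return w


def simulate_sample(
    truth: SampleTruth,
    bins: GenomeBins,
    depth: int,
    gc_bias: GcBiasCurve | None = None,
    rng: np.random.Generator | int | None = None,
    dispersion: float = 2e-4,
    y_noise_floor: float = 0.002,
    extra_bias: np.ndarray | None = None,
) -> BinCounts:
    """Draw one sample's bin counts (sum exactly ``depth``).

    Overdispersion: each bin weight is multiplied by an independent
    Gamma(1/dispersion) variate with unit mean before the multinomial
    draw, giving negative-binomial-like marginal counts
    (Var ≈ mu·(1 + dispersion·mu)); ``dispersion = 0`` is multinomial.
    ``extra_bias`` multiplies bin weights (e.g. a shared run artifact).
    """
    if depth < 10_000:
        raise ValueError("depth must be at least 10,000 fragments")
    rng = np.random.default_rng(rng)
    w = expected_bin_weights(truth, bins, gc_bias, y_noise_floor)
    if extra_bias is not None:
        w = w * np.asarray(extra_bias, dtype=float)
    if dispersion > 0:
        shape = 1.0 / dispersion
        w = w * rng.gamma(shape, 1.0 / shape, size=len(w))
    counts = rng.multinomial(int(depth), w / w.sum())
    return BinCounts(sample_id=truth.sample_id, counts=counts)


def simulate_ff(
    ga_weeks: float | np.ndarray,
    model: FetalFractionModel | None = None,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw fetal fraction(s) given gestational age (weeks, in [9, 36])."""
    model = model or FetalFractionModel()
    ga = np.atleast_1d(np.asarray(ga_weeks, dtype=float))
    if ((ga < 9) | (ga > 36)).any():
        raise ValueError("ga_weeks must be in [9, 36]")
    rng = np.random.default_rng(rng)
    noise = rng.normal(0.0, model.noise_sd, size=ga.shape) if model.noise_sd > 0 else 0.0
    ff = np.clip(model.intercept + model.slope * ga + noise, model.lo, model.hi)
    return ff if np.ndim(ga_weeks) else float(ff[0])


@dataclass
class CohortSpec:
    """Parameters of a simulated screening cohort."""

    n_samples: int = 500
    indication_mix: dict[str, float] = field(
        default_factory=lambda: {k: v["prop"] for k, v in INDICATION_TABLE.items()}
    )
    prevalences: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PREVALENCES))
    confirm_uptake: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONFIRM_UPTAKE)
    )
    ff_model: FetalFractionModel = field(default_factory=FetalFractionModel)
    mean_depth: float = 3_000_000.0
    depth_cv: float = 0.15
    gc_amplitude_mean: float = 0.4
    gc_amplitude_sd: float = 0.12  # library-to-library GC-bias variation
    gc_center_mean: float = 0.42
    gc_center_sd: float = 0.015
    gc_width: float = 0.07
    dispersion: float = 2e-4
    y_noise_floor: float = 0.002
    maternal_xxx_rate: float = 0.00015
    mosaic_prob: float = 0.04  # P(trisomy is mosaic)
    run_size: int = 48
    run_artifact_sd: float = 0.01  # per-run shared per-bin lognormal artifact
    cnv_size_mb: tuple[int, int] = (3, 10)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.indication_mix.values()) - 1.0) > 1e-9:
            raise ValueError("indication mix must sum to 1")
        for k, p in self.prevalences.items():
            if not (0 <= p <= 1):
                raise ValueError(f"prevalence {k} out of [0, 1]")
        if self.n_samples < 0:
            raise ValueError("n_samples must be non-negative")


@dataclass
class CohortRecord:
    """One pregnancy's screening record (results filled by the caller stage)."""

    sample_id: str
    maternal_age: float
    ga_weeks: float
    bmi: float
    indication: str
    nipt_result: dict[str, str] = field(default_factory=dict)  # class -> positive|negative
    confirmation: str = "pending"  # confirmed_positive|confirmed_negative|declined|lost
    confirm_willing: bool = True
    notes: str = ""


def _draw_truth(
    i: int, spec: CohortSpec, bins: GenomeBins, rng: np.random.Generator
) -> SampleTruth:
    inds = list(spec.indication_mix)
    probs = np.array([spec.indication_mix[k] for k in inds])
    indication = inds[rng.choice(len(inds), p=probs / probs.sum())]
    row = INDICATION_TABLE.get(indication, INDICATION_TABLE["voluntary"])
    ga = float(np.clip(rng.normal(row["ga"], row["ga_sd"]), 9, 36))
    ff = float(simulate_ff(ga, spec.ff_model, rng))

    classes = list(spec.prevalences)
    p = np.array([spec.prevalences[k] for k in classes])
    u = rng.random()
    cum = np.cumsum(p)
    idx = int(np.searchsorted(cum, u))
    cls = classes[idx] if idx < len(classes) else "negative"

    sex = "male" if rng.random() < 0.5 else "female"
    karyotype, cnv_events, mosaic = "euploid", [], 1.0
    if cls in ("T21", "T18", "T13"):
        karyotype = cls
        if rng.random() < spec.mosaic_prob:
            mosaic = float(rng.uniform(0.2, 0.8))
    elif cls in SEX_KARYOTYPES:
        karyotype = cls
        sex = "male" if cls in ("XXY", "XYY") else "female"
    elif cls == "other_autosomal":
        karyotype = "T" + str(rng.choice(["7", "8", "9", "10", "16", "20", "22"]))
    elif cls == "CNV":
        chrom = str(rng.choice([str(c) for c in range(1, 23)]))
        size = int(rng.integers(spec.cnv_size_mb[0], spec.cnv_size_mb[1] + 1)) * 1_000_000
        chrom_len = int(bins.df.loc[bins.chrom_mask(chrom), "end"].max())
        start = int(rng.integers(0, max(1, chrom_len - size)))
        delta = int(rng.choice([-1, 1]))
        cnv_events = [(chrom, start, start + size, delta)]

    maternal = "47,XXX" if rng.random() < spec.maternal_xxx_rate else None
    return SampleTruth(
        sample_id=f"S{i:05d}", karyotype=karyotype, fetal_sex=sex, ff=ff,
        mosaic_fraction=mosaic, ga_weeks=ga, cnv_events=cnv_events,
        maternal_abnormality=maternal, indication=indication,
    )


def simulate_cohort(
    spec: CohortSpec,
    bins: GenomeBins,
    generate_counts: bool = True,
) -> tuple[list[CohortRecord], list[BinCounts], list[SampleTruth]]:
    """Simulate a cohort: records, bin counts (optional) and ground truth.

    Truth labels and records are in bijection by ``sample_id``.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[CohortRecord] = []
    counts_list: list[BinCounts] = []
    truths: list[SampleTruth] = []
    run_artifacts: dict[str, np.ndarray] = {}
    for i in range(spec.n_samples):
        truth = _draw_truth(i, spec, bins, rng)
        row = INDICATION_TABLE.get(truth.indication, INDICATION_TABLE["voluntary"])
        if truth.indication == "AMA":
            age = float(np.clip(rng.normal(row["age"], row["age_sd"]), 35, 51))
        else:
            age = float(np.clip(rng.normal(row["age"], row["age_sd"]), 16, 34.9))
        bmi = float(np.clip(rng.normal(22.52, 3.16), 13.67, 42.36))
        uptake = spec.confirm_uptake.get(
            truth.abnormality_class, spec.confirm_uptake.get("negative", 1.0)
        )
        rec = CohortRecord(
            sample_id=truth.sample_id, maternal_age=age, ga_weeks=truth.ga_weeks,
            bmi=bmi, indication=truth.indication,
            confirm_willing=bool(rng.random() < uptake),
        )
        if generate_counts:
            run_id = f"run{i // spec.run_size}"
            if spec.run_artifact_sd > 0:
                if run_id not in run_artifacts:
                    run_artifacts[run_id] = rng.lognormal(
                        0.0, spec.run_artifact_sd, size=len(bins)
                    )
                artifact = run_artifacts[run_id]
            else:
                artifact = None
            depth = max(10_000, int(rng.lognormal(
                math.log(spec.mean_depth) - 0.5 * math.log(1 + spec.depth_cv**2),
                math.sqrt(math.log(1 + spec.depth_cv**2)),
            )))
            curve = GcBiasCurve(
                amplitude=float(rng.normal(spec.gc_amplitude_mean, spec.gc_amplitude_sd)),
                center=float(rng.normal(spec.gc_center_mean, spec.gc_center_sd)),
                width=spec.gc_width,
            )
            bc = simulate_sample(
                truth, bins, depth, gc_bias=curve, rng=rng,
                dispersion=spec.dispersion, y_noise_floor=spec.y_noise_floor,
                extra_bias=artifact,
            )
            bc.run_id = run_id
            counts_list.append(bc)
        records.append(rec)
        truths.append(truth)
    return records, counts_list, truths
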