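# Methods

## The screen being modelled

Maternal plasma cell-free DNA is a mixture: a fraction 1 − f maternal, a
fraction f (the fetal fraction) placental. Shallow whole-genome
sequencing (~0.1×, here a mean of 3 million fragments) is counted in
1-Mb bins; after bias correction, each chromosome's share p_c of the
autosomal signal is standardized against a euploid reference panel,
z_c = (p_c − μ_c)/σ_c. A fetal trisomy of chromosome c multiplies its
dosage by 1 + f/2 (a mosaic with aberrant-cell fraction m by
1 + f·m/2), so at f = 0.10 the expected chr21 excess is ~5 % — around
nine panel SDs at this depth. The decision rule is: positive when
z > 3 **and** f ≥ 4 %; calls with 3 < z < 5 are flagged *gray zone*
(retained as positives but known to be enriched for false positives);
f below 4 % (or unknown) yields a no-call rather than a guess.
Subchromosomal events are scanned per chromosome: runs of consecutive
1-Mb windows with single-window |z| above a seed threshold of 2 are
combined with Stouffer's method, Z = Σzᵢ/√k, and emitted as
microduplication (Z > +5) or microdeletion (Z < −5).

## Forward model

Expected count per bin: λ_b ∝ length_b · gcbias(gc_b) · dosage_b, with
dosage_b = (1 − f)·maternal_b + f·fetal_b on the diploid scale. Sex
chromosomes: the maternal background is XX (47,XXX mothers get 1.5× on
chrX — the mechanism behind the classic sex-chromosome false positive);
a male fetus contributes one X and one Y at half weight each; chrY
additionally carries a small constant mapping-noise floor (default
0.002 diploid-equivalents) that sets the female chrY baseline. Counts
are drawn total-conserving: each bin weight is multiplied by a
unit-mean Gamma variate with dispersion φ (Var ≈ μ(1 + φμ)) and a
single multinomial draw distributes the sample's depth — marginally
negative-binomial, exactly depth-conserving, multinomial as φ → 0.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| bin size | 1 Mb | the window size of the CNV rule; exposed in config |
| mean depth | 3 × 10⁶ fragments | ~0.1× coverage |
| depth CV | 0.15 (lognormal) | typical library-yield spread |
| dispersion φ | 2 × 10⁻⁴ | var/mean ≈ 1.2 at ~1000 reads/bin — residual overdispersion after bias correction in shallow WGS |
| GC bias | 1 + a·exp(−(gc−c)²/2w²), a ~ N(0.4, 0.12), c ~ N(0.42, 0.015), w = 0.07 | smooth unimodal library bias, varying per library so correction has real work |
| run artifact | lognormal σ = 0.01 per bin, shared within a run of 48 | what intra-run normalization exists to remove |
| ff model | f = clip(0.02 + 0.005·GA + ε, 0.01, 0.40), ε ~ N(0, 0.0145) | ~10.5 % at 17 weeks rising ~0.5 pp/week; the noise SD is set so that corr(f, GA) ≈ 0.70 over a cohort with GA ~ N(16.99, 2.82), the correlation strength reported for such cohorts. The ff distribution itself is not published; this is a calibration choice |
| GC track | AR(1) (ρ = 0.6, ±0.045) around each chromosome's characteristic mean GC | chromosome-level GC structure is what couples library GC bias to chromosome representation; bins outside [0.30, 0.60] GC are unusable |
| cohort | indication mix, per-indication maternal/gestational age (mean ± SD), abnormality prevalences, per-class confirmation uptake | taken from the composition of a 14,316-pregnancy referral cohort (abnormal serum screening 53.1 %, advanced maternal age 23.0 %, voluntary 17.6 %, …) |

The simulator does **not** model: read-level data, mappability or
blacklist structure, confined placental mosaicism, vanishing twins,
maternal tumors, or wave artifacts beyond the smooth GC curve. Passing
tests therefore demonstrate correctness of the method under the stated
statistical model, not robustness to every biological confounder — the
absence of placental/fetal discordance in particular means simulated
PPVs for rare autosomal trisomies and CNVs run higher than clinical
experience, where those classes are dominated by placental artifacts.

## Correction chain

1. **LOESS** (span 0.3, degree 1, 3 robustness iterations, `delta`
   interpolation for speed): fit count vs GC over usable bins, rescale
   each bin by median(fit)/fit(gc_b), then pin the global median to the
   input's. All usable bins enter unweighted (at 1 Mb all non-terminal
   bins have equal length). Degenerate constant-GC input returns the
   identity, logged.
2. **Intra-run normalization**: each autosomal bin divided by its
   across-sample median within the sequencing run, samples rescaled to
   unit autosomal mean; zero-median bins are flagged unusable run-wide.
   The median step is deliberately restricted to autosomes: chrX/chrY
   dosage carries each sample's fetal sex and fetal fraction, and a
   cross-sample median would cancel exactly the signal being measured
   (and jump between the female and male clusters with run
   composition). X/Y bins are instead divided by the sample's own mean
   autosomal value, which preserves every sex-chromosome share exactly.
   A single-sample run is returned unchanged.
3. **Residual GC regression**: ordinary least squares of value on
   [1, gc, gc²] over usable autosomal bins; values are replaced by
   residual + fitted mean (scale preserved). Restricted to autosomes
   because an additive correction derived from autosome-level values
   would shift, or clip to zero, the small chrY shares.

The chain operates on counts (not log-counts or ratios). The names of
steps 2 and 3 follow the production pipelines this mirrors; their exact
definitions are not published, so the forms above are this package's
interpretations, stated here prominently.

**Proportion convention.** p_c divides each chromosome's corrected
total (including X and Y) by the usable *autosomal* total. With an
all-chromosome denominator, a male fetus's chrX deficit (−f/2 of the
chrX share) leaks into every autosome as a systematic positive shift —
measured at ±0.45 SD on euploid simulations at f = 0.10, enough to
distort the false-positive rate. The autosomal denominator decouples
autosomal z-scores from fetal sex; `denominator="all"` is available
where true genome shares are wanted.

**Processing modes must match.** After intra-run normalization the
expected autosomal profile is flat (bin-shares); without it,
proportions are length-shares. Panel and test samples therefore always
go through the same mode: the cohort analysis uses the full per-run
chain for both, the calibration experiments the per-sample chain
(LOESS + residual fit) for both.

## Reference panel and calling

The panel (default 160 female-fetus + 60 male-fetus euploid
pregnancies, simulated under the same depth distribution and GC-bias
spread as the cohort; minimum size 30 enforced) stores per-chromosome
and per-autosomal-window mean and unbiased SD of corrected proportions,
leave-one-out z of each member for QC, the female chrY background r_Y0,
and the chrY scale r_Y. Window statistics cover autosomes only (CNV
scanning is autosomal; chrY windows are nearly empty in a female
panel). Any zero panel SD is a hard error naming the unit.

**Fetal fraction** is estimated from chrY for male fetuses:
f = clip((p_Y − r_Y0)/(r_Y/2 − r_Y0), 0, 1). The scale r_Y is
calibrated by regressing male panel members' p_Y on their externally
known fetal fractions (in production an orthogonal assay; in simulation
the truth), falling back to the usable-length share when no such values
exist. Female-fetus fetal fraction cannot come from chrY; an external
estimate must be supplied or the sample is a no-call — a documented
limitation of chrY-based estimation, not of the implementation.

**Sex karyotype.** Y presence is decided by p_Y against the midpoint
between r_Y0 and the male expectation at the gating fetal fraction.
Without Y, the female-panel z_X classifies XO (z_X < −3) / XXX
(z_X > +3) / XX. With Y, the XY expectation μ_X(1 − f/2) replaces the
female mean before the same ±3 rule (an XY male sits ~18 SD below the
female chrX mean at f = 0.10, so the unadjusted rule would be
meaningless), and z_Y against the male expectation at f flags XYY.
XYY detection therefore needs a fetal-fraction estimate independent of
chrY; with chrY-only estimation it is structurally confounded (an XYY
fetus reads as an XY fetus at twice the fetal fraction).

**CNV segments** require at least 2 consecutive seed windows
(configurable): at ~2800 scanned windows per genome, single-window
|Z| > 5 excursions are dominated by z-tail noise. Window z-scores are
rescaled within-sample by 1.4826·MAD over all scored windows before
scanning — libraries sequenced shallower or with stronger GC bias than
the panel average are noisier window-by-window, and without the
rescaling their tails generate spurious segments. A real focal event
(a handful of windows in ~2800) cannot move the MAD. Same-sign runs
separated by one sub-threshold window merge when the merged Z still
passes. Even so, ~1–2 % of simulated euploid genomes at 0.1× carry one
just-over-threshold segment; production screens that report fewer
evidently apply review or recurrence filters beyond the published ±5
rule, consistent with the low clinical PPV of NIPT CNV calls.

The CNV recovery experiment (3-Mb deletion, f = 0.15, boundaries within
±1 window) runs at 15 million fragments (~0.5×): at the 0.1× screening
depth a 3-Mb event at f = 0.15 yields per-window z ≈ 2 and the ±5 rule
has little power — the package treats CNV-grade sequencing as a
deeper-coverage mode, matching how such events are pursued in practice.

**Rare (non-target) autosomal trisomies** are reported only at the firm
z ≥ 5 threshold. The gray zone exists for chromosomes 21/18/13, which
have a confirmatory workflow; applying z > 3 across the other 19
autosomes would flag ~2.5 % of euploid pregnancies on multiplicity
alone.

## Evaluation conventions

P = screen positives, TP = positives confirmed by invasive diagnosis;
PPV = TP/P, sensitivity = TP/(TP + FN). Specificity and NPV use the
followed-up pool as the negative denominator; declined/lost cases stay
in P (they cannot be TP) and are excluded from the negative pool —
mirroring follow-up-questionnaire practice, where incomplete pregnancies
and cases without a genetic diagnosis drop out of the performance
calculation. Which denominator a given published table used is often
not recoverable from its printed counts, so the pool is an explicit
input here, never an assumption. χ² is the uncorrected Pearson
statistic on the 2×2 (the continuity-corrected value would not
reproduce standard published comparisons). Display rounding is half-up
to 2 decimals; internal values keep full precision. PPV of an empty
positive set renders NA.

## Numerical and design notes

- All randomness flows through `numpy.random.Generator`; every
  experiment takes an explicit seed, and cohort simulation is
  bit-reproducible for a given spec.
- LOESS uses `statsmodels` lowess with `delta` = 1 % of the GC range
  (interpolation between close points), keeping a full-genome fit ~6 ms.
- Corrected values are clipped at 0 (profile invariant); the residual
  step preserves the autosomal mean, so clipping is rare in practice.
- Problem sizes in the test suite and acceptance script (panel 160+60,
  100-sample null checks, 200-rep power/recovery runs, 500-sample
  false-positive screens, 100-rep CNV recovery) were chosen to give
  Monte-Carlo standard errors comfortably inside the asserted bands
  while keeping the whole suite under a minute.
- Decisions are order-invariant in chromosome processing; the Stouffer
  reduction equals its closed form by construction and is cross-checked
  against a direct-sum oracle in the tests, as is χ² against the
  textbook (ad − bc)²n/∏margins formula.

## What the simulated cohort shows

Running the full 14,316-pregnancy cohort (analysis/02–03) reproduces
the *structure* of clinical screening results, not their exact rates:
T21 calling is high-PPV and fully sensitive at the simulated fetal
fractions; false positives for the trisomy targets concentrate almost
entirely in the 3 < z < 5 gray zone, the same pattern clinical cohorts
report; and the 45,X/47,XXX classes pick up designed maternal-origin
false positives. Two rates run above clinical experience and are worth
understanding. First, the per-chromosome euploid rate of z > 3 is
~0.2–0.4 % rather than the nominal 0.13 %: with a 160-sample panel the
per-chromosome SD estimate carries ~6 % error, and a chromosome whose
σ̂ ran low has all its z-scores inflated — a panel-size effect
(z-spread ≈ √(1 + 1/n) times σ̂ error) that shrinks with panels in the
hundreds-to-thousands used by production labs. Second, ~2 % of euploid
genomes carry one just-over-threshold CNV segment (see above). Both
excesses land in low-confidence calls; both are reported as measured.

## Known limitations

- Fetal-fraction estimation is chrY-based: female-fetus samples need an
  external estimate (the cohort driver uses the simulator's truth as
  that stand-in, marked as such).
- The simulator's clean statistical structure means specificity-side
  results (false-positive rates, gray-zone composition) reflect
  counting noise and library variation only, not placental biology.
- Bin usability is GC-band-only; no mappability or blacklist tracks.
- The 45,X/47,XXX/47,XXY/47,XYY thresholds reuse the ±3 convention for
  symmetry; published screens do not state theirs.
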