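# niptcall

Noninvasive prenatal testing (NIPT) screens pregnancies for fetal
chromosomal abnormality by shallow whole-genome sequencing (~0.1×) of
cell-free DNA from maternal plasma. A small fraction of that DNA — the
*fetal fraction*, f — is placental: a fetal trisomy therefore raises the
read share of the affected chromosome by roughly f/2, and the screen
reduces to detecting sub-percent shifts in chromosome representation.

`niptcall` is an analysis pipeline and simulation laboratory for this
screen, written for people who want to study how the standard z-score
method behaves — its calibration, power, gray zone, and failure modes —
without access to patient data. It provides:

- a **forward simulator** of maternal-plasma cfDNA bin counts (1-Mb
  windows, negative-binomial noise, library GC bias, lognormal depth,
  cohort structure with clinical indications, trisomies, sex-chromosome
  aneuploidies, mosaics, CNVs, and maternal confounders), with the truth
  retained for evaluation;
- the **three-step GC-bias correction**: per-sample LOESS of count vs GC,
  intra-run per-bin median normalization, and a residual quadratic GC
  regression;
- **calling**: a euploid reference panel (per-chromosome and per-window
  mean/SD of corrected proportions), chromosome z-scores
  z_c = (p_c − μ_c)/σ_c, chrY-based fetal-fraction estimation,
  the decision rule *positive if z > 3 and f ≥ 4 %* with the gray zone
  3 < z < 5 flagged, sex-karyotype classification (XX/XY/XO/XXY/XXX/XYY),
  and subchromosomal CNV calling by Stouffer-combined 1-Mb window
  z-scores (Z = Σzᵢ/√k, |Z| > 5, duplication/deletion by sign);
- **screening-performance evaluation**: PPV/NPV/sensitivity/specificity
  from followed-up counts, uncorrected Pearson χ² group comparisons,
  Pearson correlations, and indication-stratified tables.

## Worked example

```python
import numpy as np
from niptcall import SampleTruth, simulate_sample, zscore_chromosomes, RunConfig
from niptcall.calling import call_aneuploidy, estimate_fetal_fraction
from niptcall.pipeline import build_panel_from_sims, default_setup, process_single

bins, config = default_setup()                       # hg19-scale 1-Mb bins
panel = build_panel_from_sims(bins, seed=11)         # 160F + 60M euploid panel

truth = SampleTruth(sample_id="demo", karyotype="T21", fetal_sex="male", ff=0.10)
counts = simulate_sample(truth, bins, depth=3_000_000, rng=5)
profile = process_single(counts, bins)               # LOESS + residual GC fit
z = zscore_chromosomes(profile, bins, panel)
ff = estimate_fetal_fraction(profile, bins, panel, "male")
print(f"z21={z['21']:.2f} z18={z['18']:.2f} ff={ff:.3f}")
print(call_aneuploidy(z, ff, config))
```

Output:

```
z21=9.36 z18=0.16 ff=0.102
{'21': 'positive', '18': 'negative', '13': 'negative'}
```

A trisomy 21 pregnancy at 10 % fetal fraction sits ~9 panel SDs above
the euploid chr21 mean — called firmly positive (z ≥ 5) — while chr18
stays within the negative range; the chrY estimator recovers the true
fetal fraction.

The numbered scripts under `analysis/` run the full study: `01` builds
the reference panels, `02` simulates and screens a 14,316-pregnancy
cohort (writes its record table to `scratch/`, summaries to `results/`),
`03` produces the per-class and per-indication performance tables and χ²
comparisons, `04` the calibration and power experiments. A thin CLI
(`niptcall simulate-cohort | correct | call | evaluate`) exposes the same
stages for shell use.

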