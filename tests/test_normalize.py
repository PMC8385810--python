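"""GC-correction chain behavior and chromosome proportions."""

import numpy as np
import pandas as pd
import pytest

from niptcall import (
    BinCounts,
    CorrectedProfile,
    SampleTruth,
    chromosome_proportions,
    intra_run_normalize,
    loess_gc_correct,
    make_genome_bins,
    residualize_linear,
    simulate_sample,
)
from niptcall.genome import GenomeBins
from niptcall.normalize import window_proportions
from niptcall.pipeline import gc_correction_sd_reduction, process_single
from niptcall.simulate import GcBiasCurve


class TestLoessGcCorrect:
    def test_constant_counts_are_a_fixed_point(self, toy_bins):
        bc = BinCounts("s", np.full(len(toy_bins), 200))
        prof = loess_gc_correct(bc, toy_bins)
        np.testing.assert_allclose(prof.values[prof.usable], 200.0, rtol=1e-6)

    def test_exponential_gc_bias_removed(self, toy_bins):
        """After correction, log(corrected) has no GC slope (|b| < 0.05)."""
        rng = np.random.default_rng(4)
        beta = 1.0
        lam = 500 * np.exp(beta * toy_bins.gc)
        bc = BinCounts("s", rng.poisson(lam))
        prof = loess_gc_correct(bc, toy_bins)
        m = prof.usable & (prof.values > 0)
        slope = np.polyfit(toy_bins.gc[m], np.log(prof.values[m]), 1)[0]
        raw_slope = np.polyfit(toy_bins.gc[m], np.log(np.maximum(bc.counts[m], 1)), 1)[0]
        assert abs(slope) < 0.05
        assert abs(raw_slope) > 0.5  # the bias really was there

    def test_unbiased_sample_nearly_unchanged(self, bins):
        t = SampleTruth(sample_id="s", fetal_sex="female", ff=0.1)
        bc = simulate_sample(t, bins, 3_000_000, gc_bias=None, rng=8, dispersion=0.0)
        prof = loess_gc_correct(bc, bins)
        m = prof.usable & (bc.counts > 100)
        rel = np.abs(prof.values[m] / bc.counts[m] - 1)
        assert rel.max() < 0.05

    def test_median_preserved_within_one_percent(self, toy_bins):
        rng = np.random.default_rng(5)
        lam = 400 * GcBiasCurve()(toy_bins.gc)
        bc = BinCounts("s", rng.poisson(lam))
        prof = loess_gc_correct(bc, toy_bins)
        med_in = np.median(bc.counts[toy_bins.usable_mask].astype(float))
        med_out = np.median(prof.values[prof.usable])
        assert abs(med_out / med_in - 1) < 0.01

    def test_degenerate_constant_gc_is_identity(self):
        gb = make_genome_bins({"1": 150_000_000}, 10**6, gc=np.full(150, 0.45))
        bc = BinCounts("s", np.arange(150) + 10)
        prof = loess_gc_correct(bc, gb)
        assert prof.meta.get("degenerate_gc") is True
        np.testing.assert_allclose(prof.values, bc.counts.astype(float))

    def test_too_few_usable_bins_rejected(self):
        gb = make_genome_bins({"1": 50_000_000}, 10**6, gc=np.full(50, 0.4))
        with pytest.raises(ValueError, match="100 usable"):
            loess_gc_correct(BinCounts("s", np.full(50, 10)), gb)


class TestIntraRunNormalize:
    def _profiles(self, toy_bins, values_list):
        return [
            CorrectedProfile(f"s{i}", v.astype(float), toy_bins.usable_mask)
            for i, v in enumerate(values_list)
        ]

    def test_identical_samples_normalize_to_unity(self, toy_bins):
        profs = self._profiles(toy_bins, [np.full(len(toy_bins), 50.0)] * 4)
        out = intra_run_normalize(profs)
        for p in out:
            np.testing.assert_allclose(p.values[p.usable], 1.0)

    def test_single_sample_run_is_identity(self, toy_bins):
        profs = self._profiles(toy_bins, [np.arange(len(toy_bins)) + 5.0])
        out = intra_run_normalize(profs)
        np.testing.assert_array_equal(out[0].values, profs[0].values)

    def test_shared_doubled_bin_removed(self, toy_bins):
        rng = np.random.default_rng(1)
        base = rng.uniform(80, 120, len(toy_bins))
        vals = []
        for _ in range(5):
            v = base * rng.normal(1, 0.01, len(toy_bins))
            v[37] *= 2.0  # same artifact bin in every sample
            vals.append(v)
        out = intra_run_normalize(self._profiles(toy_bins, vals))
        for p in out:
            ratio = p.values[37] / np.median(p.values[p.usable])
            assert abs(ratio - 1) < 0.05

    def test_zero_median_bin_flagged_unusable(self, toy_bins):
        vals = [np.full(len(toy_bins), 10.0) for _ in range(3)]
        for v in vals:
            v[12] = 0.0
        out = intra_run_normalize(self._profiles(toy_bins, vals))
        assert not out[0].usable[12]

    def test_sex_chromosome_shares_preserved_with_bin_model(self, bins):
        """With a bin model, chrX/chrY shares match the per-sample profile."""
        rng = np.random.default_rng(3)
        profs = [
            CorrectedProfile(f"s{i}", rng.uniform(900, 1100, len(bins)), bins.usable_mask)
            for i in range(6)
        ]
        before = [chromosome_proportions(p, bins) for p in profs]
        out = intra_run_normalize(profs, bins)
        after = [chromosome_proportions(p, bins) for p in out]
        for b, a in zip(before, after):
            assert a["X"] == pytest.approx(b["X"], rel=1e-9)
            assert a["Y"] == pytest.approx(b["Y"], rel=1e-9)


class TestResidualizeLinear:
    def test_orthogonal_values_unchanged(self, toy_bins):
        rng = np.random.default_rng(2)
        gc = toy_bins.gc
        X = np.column_stack([np.ones_like(gc), gc, gc**2])
        y = rng.uniform(50, 150, len(gc))
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta + 100.0  # orthogonal to the design, positive
        prof = CorrectedProfile("s", resid, np.ones(len(toy_bins), dtype=bool))
        out = residualize_linear(prof, toy_bins)
        np.testing.assert_allclose(out.values, resid, atol=1e-9)

    def test_pure_quadratic_trend_removed(self, toy_bins):
        gc = toy_bins.gc
        y = 100 + 400 * (gc - 0.42) ** 2
        prof = CorrectedProfile("s", y, np.ones(len(toy_bins), dtype=bool))
        out = residualize_linear(prof, toy_bins)
        assert np.ptp(out.values) < 1e-6

    def test_constant_gc_skipped(self):
        gb = make_genome_bins({"1": 120_000_000}, 10**6, gc=np.full(120, 0.45))
        prof = CorrectedProfile("s", np.arange(120) + 1.0, np.ones(120, dtype=bool))
        out = residualize_linear(prof, gb)
        np.testing.assert_array_equal(out.values, prof.values)


class TestChromosomeProportions:
    def test_uniform_single_bin_genome_shares(self):
        lengths = {c: 10**6 for c in list(map(str, range(1, 23))) + ["X", "Y"]}
        gb = make_genome_bins(lengths, 10**6, gc=np.full(24, 0.4))
        prof = CorrectedProfile("s", np.full(24, 7.0), np.ones(24, dtype=bool))
        p_all = chromosome_proportions(prof, gb, denominator="all")
        np.testing.assert_allclose(p_all.to_numpy(), 1 / 24)
        assert p_all.sum() == pytest.approx(1.0, abs=1e-9)
        p_auto = chromosome_proportions(prof, gb)
        assert p_auto[[str(c) for c in range(1, 23)]].sum() == pytest.approx(1.0, abs=1e-9)
        assert p_auto["X"] == pytest.approx(1 / 22)

    def test_all_zero_profile_rejected(self, toy_bins):
        prof = CorrectedProfile("s", np.zeros(len(toy_bins)), toy_bins.usable_mask)
        with pytest.raises(ValueError, match="all-zero"):
            chromosome_proportions(prof, toy_bins)

    def test_scale_invariance(self, bins):
        rng = np.random.default_rng(6)
        t = SampleTruth(sample_id="s", fetal_sex="female", ff=0.1)
        bc = simulate_sample(t, bins, 500_000, rng=rng)
        p1 = chromosome_proportions(process_single(bc, bins), bins)
        bc10 = BinCounts("s", bc.counts * 10)
        p2 = chromosome_proportions(process_single(bc10, bins), bins)
        pd.testing.assert_series_equal(p1, p2, rtol=1e-9)

    def test_chromosome_order_invariance(self, bins):
        """Reordering whole chromosomes leaves every p_c unchanged."""
        rng = np.random.default_rng(13)
        t = SampleTruth(sample_id="s", fetal_sex="female", ff=0.1)
        bc = simulate_sample(t, bins, 500_000, rng=rng)
        p1 = chromosome_proportions(process_single(bc, bins), bins)
        order = ["13", "X", "2", "21", "1", "Y"] + [
            c for c in bins.chromosomes() if c not in ("13", "X", "2", "21", "1", "Y")
        ]
        parts = [bins.df[bins.df["chrom"] == c] for c in order]
        shuffled = GenomeBins(pd.concat(parts, ignore_index=True), bins.bin_size)
        idx = np.concatenate([np.flatnonzero(bins.chrom == c) for c in order])
        bc2 = BinCounts("s", bc.counts[idx])
        p2 = chromosome_proportions(process_single(bc2, shuffled), shuffled)
        for c in p1.index:
            assert p2[c] == pytest.approx(p1[c], rel=1e-6)

    def test_euploid_share_matches_usable_length_share(self, bins):
        """p_21 over euploid sims ~ usable chr21 length / usable autosomal length."""
        m = bins.usable_mask
        auto = m & ~np.isin(bins.chrom, ("X", "Y"))
        expected = bins.lengths[m & (bins.chrom == "21")].sum() / bins.lengths[auto].sum()
        rng = np.random.default_rng(17)
        t = SampleTruth(sample_id="s", fetal_sex="female", ff=0.1)
        vals = []
        for _ in range(200):
            bc = simulate_sample(t, bins, 300_000, rng=rng)
            prof = loess_gc_correct(bc, bins)
            vals.append(float(chromosome_proportions(prof, bins)["21"]))
        vals = np.array(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - expected) < 3 * se + 1e-4

    def test_window_proportions_nan_on_unusable(self, bins):
        prof = CorrectedProfile("s", np.full(len(bins), 5.0), bins.usable_mask)
        q = window_proportions(prof, bins)
        assert np.isnan(q[~bins.usable_mask]).all()
        auto = bins.usable_mask & ~np.isin(bins.chrom, ("X", "Y"))
        assert np.nansum(q[auto]) == pytest.approx(1.0)


class TestFullChain:
    def test_correction_reduces_proportion_sd_for_every_autosome(self, bins):
        reduced, total = gc_correction_sd_reduction(bins, seed=101, n=50)
        assert total == 22
        assert reduced == total
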