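"""Reference panel, z-scores, decisions, sex karyotypes and CNV segments."""

import numpy as np
import pandas as pd
import pytest

from niptcall import (
    CorrectedProfile,
    ReferencePanel,
    RunConfig,
    SampleTruth,
    build_reference_panel,
    call_aneuploidy,
    call_cnv_segments,
    classify_sex_karyotype,
    estimate_fetal_fraction,
    stouffer_region_z,
    zscore_chromosomes,
)
from niptcall.calling import CnvSegment, decide
from niptcall.normalize import chromosome_proportions
from niptcall.pipeline import (
    sex_karyotype_recovery,
    simulate_processed,
    trisomy_detection_rate,
)
from niptcall.simulate import expected_bin_weights


def _profile_with_proportions(bins, panel, scale_chrom=None, scale_sd=0.0):
    """Synthetic profile whose p_c equal the panel means, optionally with
    one chromosome moved to mu + scale_sd * sigma (exactly)."""
    values = np.zeros(len(bins))
    m = bins.usable_mask
    for c in set(bins.chrom[m]):
        sel = m & (bins.chrom == c)
        values[sel] = panel.chrom_mean[c] / sel.sum()
    if scale_chrom is not None:
        c = scale_chrom
        target = panel.chrom_mean[c] + scale_sd * panel.chrom_sd[c]
        # p_c = (mu_c + x)/(1 + x) for autosomes; solve for the additive mass x
        x = (target - panel.chrom_mean[c]) / (1 - target)
        sel = m & (bins.chrom == c)
        values[sel] += x / sel.sum()
    return CorrectedProfile("synthetic", values, m)


class TestReferencePanel:
    def test_identical_profiles_rejected(self, toy_bins):
        prof = CorrectedProfile("a", np.full(len(toy_bins), 10.0), toy_bins.usable_mask)
        profiles = [
            CorrectedProfile(f"s{i}", prof.values.copy(), prof.usable.copy())
            for i in range(31)
        ]
        with pytest.raises(ValueError, match="zero panel SD"):
            build_reference_panel(profiles, toy_bins, min_panel_size=30)

    def test_undersized_panel_rejected(self, toy_bins):
        rng = np.random.default_rng(0)
        profiles = [
            CorrectedProfile(f"s{i}", rng.uniform(9, 11, len(toy_bins)), toy_bins.usable_mask)
            for i in range(10)
        ]
        with pytest.raises(ValueError, match="too small"):
            build_reference_panel(profiles, toy_bins, min_panel_size=30)

    def test_leave_one_out_qc_z_behaves_like_standard_normal(self, panel):
        """LOO z of panel members centers near 0 (O(1/sqrt(n)), not exactly:
        the exact-zero centering identity holds for full-panel z only) with
        roughly unit spread on every chromosome."""
        n = panel.n_samples
        for c, zs in panel.loo_z.items():
            assert np.isfinite(zs).all()
            assert abs(zs.mean()) < 3 / np.sqrt(n)
            assert zs.std(ddof=1) == pytest.approx(1.0, abs=0.35)

    def test_json_roundtrip(self, panel, tmp_path):
        path = tmp_path / "panel.json"
        panel.to_json(path)
        back = ReferencePanel.from_json(path)
        assert back.chrom_mean == pytest.approx(panel.chrom_mean)
        assert back.chrom_sd == pytest.approx(panel.chrom_sd)
        np.testing.assert_allclose(back.window_sd, panel.window_sd, equal_nan=True)
        assert back.r_y == pytest.approx(panel.r_y)
        assert back.n_samples == panel.n_samples


class TestZScores:
    def test_proportion_at_panel_mean_gives_zero(self, bins, panel):
        prof = _profile_with_proportions(bins, panel)
        z = zscore_chromosomes(prof, bins, panel)
        assert z["21"] == pytest.approx(0.0, abs=1e-9)

    def test_three_sigma_shift_gives_z_of_three(self, bins, panel):
        prof = _profile_with_proportions(bins, panel, scale_chrom="21", scale_sd=3.0)
        z = zscore_chromosomes(prof, bins, panel)
        assert z["21"] == pytest.approx(3.0, abs=1e-9)

    def test_t21_mean_z_matches_analytic_oracle(self, bins, panel):
        """Mean simulated T21 z vs the copy-factor expectation / panel SD."""
        ff = 0.10
        w_t = expected_bin_weights(
            SampleTruth(sample_id="t", karyotype="T21", fetal_sex="female", ff=ff), bins
        )
        m = bins.usable_mask
        auto = m & ~np.isin(bins.chrom, ("X", "Y"))
        p_t21 = w_t[m & (bins.chrom == "21")].sum() / w_t[auto].sum()
        oracle = (p_t21 - panel.chrom_mean["21"]) / panel.chrom_sd["21"]
        rng = np.random.default_rng(23)
        zs = []
        for i in range(100):
            t = SampleTruth(sample_id=f"t{i}", karyotype="T21", fetal_sex="female", ff=ff)
            prof = simulate_processed(t, bins, 3_000_000, rng)
            zs.append(float(zscore_chromosomes(prof, bins, panel)["21"]))
        zs = np.array(zs)
        se = zs.std(ddof=1) / 10
        assert abs(zs.mean() - oracle) < max(0.05 * abs(oracle), 3 * se)

    def test_detection_rate_monotone_in_fetal_fraction(self, bins, panel):
        rates = [
            trisomy_detection_rate(panel, bins, seed=31, ff=ff, n=40)
            for ff in (0.04, 0.08, 0.12)
        ]
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] >= 0.95


class TestFetalFraction:
    def test_maternal_background_only_gives_zero(self, bins, panel):
        values = np.zeros(len(bins))
        m = bins.usable_mask
        auto = m & ~np.isin(bins.chrom, ("X", "Y"))
        values[auto] = 1.0 / auto.sum()
        sel = m & (bins.chrom == "Y")
        values[sel] = panel.r_y0 / sel.sum()
        prof = CorrectedProfile("s", values, m)
        ff = estimate_fetal_fraction(prof, bins, panel, "male")
        assert ff == pytest.approx(0.0, abs=1e-9)

    def test_chry_below_background_clipped_to_zero(self, bins, panel):
        values = np.zeros(len(bins))
        m = bins.usable_mask
        auto = m & ~np.isin(bins.chrom, ("X", "Y"))
        values[auto] = 1.0 / auto.sum()
        prof = CorrectedProfile("s", values, m)
        assert estimate_fetal_fraction(prof, bins, panel, "male") == 0.0

    def test_female_without_override_is_unavailable(self, bins, panel):
        prof = _profile_with_proportions(bins, panel)
        assert estimate_fetal_fraction(prof, bins, panel, "female") is None
        assert estimate_fetal_fraction(prof, bins, panel, "female", override=0.07) == 0.07


class TestDecisions:
    @pytest.mark.parametrize(
        "z, ff, expected",
        [
            (2.99, 0.08, "negative"),
            (3.0, 0.08, "negative"),       # the rule is z > 3, strictly
            (4.2, 0.05, "gray_positive"),
            (5.0, 0.05, "positive"),
            (7.0, 0.03, "no_call_low_ff"),
            (7.0, None, "no_call_low_ff"),
            (-4.0, 0.08, "negative"),
        ],
    )
    def test_decision_rule(self, z, ff, expected, config):
        assert decide(z, ff, config) == expected

    def test_call_aneuploidy_covers_target_chromosomes(self, config):
        z = pd.Series({"21": 6.0, "18": 2.0, "13": 3.5, "X": 0.0})
        out = call_aneuploidy(z, 0.08, config)
        assert out == {"21": "positive", "18": "negative", "13": "gray_positive"}


class TestSexKaryotype:
    def test_euploid_male_called_xy(self, bins, panel):
        rng = np.random.default_rng(41)
        t = SampleTruth(sample_id="m", fetal_sex="male", ff=0.10)
        prof = simulate_processed(t, bins, 3_000_000, rng)
        z = zscore_chromosomes(prof, bins, panel)
        p_y = float(chromosome_proportions(prof, bins)["Y"])
        assert classify_sex_karyotype(float(z["X"]), float(z["Y"]), p_y, 0.10, panel) == "XY"

    def test_euploid_female_called_xx(self, bins, panel):
        rng = np.random.default_rng(43)
        t = SampleTruth(sample_id="f", fetal_sex="female", ff=0.10)
        prof = simulate_processed(t, bins, 3_000_000, rng)
        z = zscore_chromosomes(prof, bins, panel)
        p_y = float(chromosome_proportions(prof, bins)["Y"])
        assert classify_sex_karyotype(float(z["X"]), float(z["Y"]), p_y, 0.10, panel) == "XX"

    @pytest.mark.parametrize("karyotype", ["XO", "XXY", "XXX", "XYY"])
    def test_sex_aneuploidies_recovered(self, bins, panel, karyotype):
        rate = sex_karyotype_recovery(panel, bins, seed=47, karyotype=karyotype, n=30)
        assert rate >= 0.9

    def test_maternal_xxx_produces_designed_false_positive(self, bins, panel):
        """A 47,XXX mother with a euploid female fetus screens as XXX."""
        rng = np.random.default_rng(53)
        t = SampleTruth(
            sample_id="mx", fetal_sex="female", ff=0.10,
            maternal_abnormality="47,XXX",
        )
        prof = simulate_processed(t, bins, 3_000_000, rng)
        z = zscore_chromosomes(prof, bins, panel)
        p_y = float(chromosome_proportions(prof, bins)["Y"])
        assert classify_sex_karyotype(float(z["X"]), float(z["Y"]), p_y, 0.10, panel) == "XXX"


class TestStouffer:
    def test_single_window_identity(self):
        assert stouffer_region_z(np.array([2.4])) == pytest.approx(2.4)

    def test_four_windows_of_three_combine_to_six(self):
        assert stouffer_region_z(np.full(4, 3.0)) == pytest.approx(6.0)

    def test_null_distribution_is_standard_normal(self):
        rng = np.random.default_rng(3)
        z = rng.standard_normal((10_000, 25))
        combined = z.sum(axis=1) / np.sqrt(25)
        # implementation agrees with the closed form row by row
        sample = [stouffer_region_z(row) for row in z[:50]]
        np.testing.assert_allclose(sample, combined[:50], atol=1e-12)
        assert abs(combined.mean()) < 0.05
        assert combined.std() == pytest.approx(1.0, abs=0.05)

    def test_empty_window_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            stouffer_region_z(np.array([]))


class TestCnvSegments:
    def _window_z(self, bins, assignments):
        z = np.zeros(len(bins))
        z[~bins.usable_mask] = np.nan
        z[np.isin(bins.chrom, ("X", "Y"))] = np.nan
        for idx, val in assignments.items():
            z[idx] = val
        return z

    def test_null_track_yields_no_segments(self, bins, config):
        assert call_cnv_segments(self._window_z(bins, {}), bins, config) == []

    def test_three_window_run_called_with_direct_formula(self, bins, config):
        idx = np.flatnonzero((bins.chrom == "4") & bins.usable_mask)[10:13]
        z = self._window_z(bins, dict(zip(idx, [4.0, 5.0, 4.0])))
        segs = call_cnv_segments(z, bins, config)
        assert len(segs) == 1
        s = segs[0]
        assert s.type == "microduplication"
        assert s.k == 3
        assert s.combined_z == pytest.approx(13 / np.sqrt(3))
        assert s.start == bins.df["start"].iloc[idx[0]]
        assert s.end == bins.df["end"].iloc[idx[-1]]

    def test_deletion_sign_convention(self, bins, config):
        idx = np.flatnonzero((bins.chrom == "7") & bins.usable_mask)[5:8]
        z = self._window_z(bins, dict(zip(idx, [-4.0, -5.0, -4.0])))
        segs = call_cnv_segments(z, bins, config)
        assert [s.type for s in segs] == ["microdeletion"]

    def test_one_gap_merge_rule(self, bins, config):
        idx = np.flatnonzero((bins.chrom == "9") & bins.usable_mask)[20:25]
        z = self._window_z(bins, dict(zip(idx, [4.0, 4.0, 1.5, 4.0, 4.0])))
        segs = call_cnv_segments(z, bins, config)
        assert len(segs) == 1
        assert segs[0].k == 5
        assert segs[0].combined_z == pytest.approx(17.5 / np.sqrt(5))

    def test_minimum_window_support_required(self, bins, config):
        idx = np.flatnonzero((bins.chrom == "11") & bins.usable_mask)[3:4]
        z = self._window_z(bins, {idx[0]: 6.0})
        assert call_cnv_segments(z, bins, config) == []
        permissive = RunConfig(cnv_min_windows=1)
        segs = call_cnv_segments(z, bins, permissive)
        assert len(segs) == 1 and segs[0].k == 1

    def test_below_cutoff_run_not_emitted(self, bins, config):
        idx = np.flatnonzero((bins.chrom == "2") & bins.usable_mask)[0:2]
        z = self._window_z(bins, dict(zip(idx, [3.0, 3.0])))  # Z = 4.24 < 5
        assert call_cnv_segments(z, bins, config) == []

    def test_segment_type_must_match_sign(self):
        with pytest.raises(ValueError, match="inconsistent"):
            CnvSegment("1", 0, 10**6, combined_z=6.0, k=2, type="microdeletion")
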