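"""Normalization, dispersion, BH, and the NB Wald test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from drms_scan.diffacc import (
    bh_adjust,
    cpm_normalize,
    estimate_dispersion,
    nb_wald_test,
    replicate_correlation,
    signal_track,
    size_factors,
    subtract_tracks,
)
from drms_scan.simulate import SimDesign, make_truth, simulate_counts


def _counts(mat, samples=None):
    mat = np.asarray(mat)
    cols = samples or [f"s{i}" for i in range(mat.shape[1])]
    return pd.DataFrame(mat, columns=cols)


class TestSizeFactors:
    def test_identical_samples_unit_factors(self):
        c = _counts([[10, 10], [3, 3], [7, 7]])
        assert size_factors(c).tolist() == [1.0, 1.0]

    def test_doubled_sample_factor_ratio_two(self):
        a = np.array([10, 20, 30, 40])
        c = _counts(np.column_stack([a, 2 * a]))
        f = size_factors(c)
        assert f["s1"] / f["s0"] == pytest.approx(2.0)

    def test_scale_invariance_of_factor_ratios(self):
        # factors are defined up to overall scale (the geometric-mean
        # reference moves too), so the invariant is on ratios: scaling one
        # sample by c scales its factor relative to any other sample by c
        rng = np.random.default_rng(0)
        mat = rng.poisson(50, size=(200, 4)) + 1
        f0 = size_factors(_counts(mat))
        mat2 = mat.copy().astype(float)
        mat2[:, 2] *= 3.0
        f1 = size_factors(_counts(mat2))
        assert (f1["s2"] / f1["s0"]) / (f0["s2"] / f0["s0"]) == pytest.approx(3.0)

    def test_recovers_simulated_depths(self):
        design = SimDesign(n_peaks=5000, seed=21, label_fractions={})
        truth = make_truth(design)
        counts, _ = simulate_counts(design, truth)
        rng = np.random.default_rng(np.random.SeedSequence([21, 1]))
        depth = rng.lognormal(0.0, design.depth_sdlog, size=counts.shape[1])
        f = size_factors(counts)
        assert np.corrcoef(f.to_numpy(), depth)[0, 1] > 0.99

    def test_fallback_when_no_all_positive_row(self, caplog):
        c = _counts([[5, 0], [0, 5]])
        f = size_factors(c)
        assert (f > 0).all()


class TestCpmNormalize:
    def test_single_peak_is_one_million(self):
        c = _counts([[10]])
        assert cpm_normalize(c).iloc[0, 0] == pytest.approx(1e6)

    def test_column_sums_one_million(self):
        rng = np.random.default_rng(1)
        c = _counts(rng.poisson(30, size=(50, 3)))
        np.testing.assert_allclose(cpm_normalize(c).sum(axis=0), 1e6)

    def test_zero_total_sample_named(self):
        c = _counts([[1, 0], [2, 0]])
        with pytest.raises(ValueError, match="s1"):
            cpm_normalize(c)


class TestReplicateCorrelation:
    def test_duplicate_columns_r_one(self):
        c = _counts([[1, 1], [5, 5], [9, 9]]).astype(float)
        assert replicate_correlation(c).loc["s0", "s1"] == pytest.approx(1.0)

    def test_constant_column_reported_missing(self):
        c = _counts([[1.0, 3.0], [1.0, 5.0], [1.0, 9.0]])
        corr = replicate_correlation(c)
        assert np.isnan(corr.loc["s0", "s1"])

    def test_replicates_cluster_by_stage_then_damage(self):
        design = SimDesign(n_peaks=5000, seed=13)
        truth = make_truth(design)
        counts, table = simulate_counts(design, truth)
        corr = replicate_correlation(cpm_normalize(counts))
        meta = table.set_index("sample")
        within_stage, between_stage = [], []
        for a in meta.index:
            for b in meta.index:
                if a >= b:
                    continue
                (within_stage if meta.loc[a, "stage"] == meta.loc[b, "stage"]
                 else between_stage).append(corr.loc[a, b])
        assert np.mean(within_stage) > np.mean(between_stage)


class TestEstimateDispersion:
    def _run(self, alpha, seed, n=3000):
        design = SimDesign(
            n_peaks=n, seed=seed, dispersion=alpha, label_fractions={}
        )
        truth = make_truth(design)
        counts, table = simulate_counts(design, truth)
        f = size_factors(counts)
        return estimate_dispersion(counts, f, table)

    def test_nb_truth_recovered_within_band(self):
        est = self._run(alpha=0.05, seed=31)
        assert 0.02 <= est.median() <= 0.10

    def test_poisson_counts_give_small_alpha(self):
        est = self._run(alpha=0.0, seed=32)
        assert est.median() < 0.02

    def test_constant_replicates_raw_zero(self):
        counts = _counts(np.full((5, 4), 7))
        table = pd.DataFrame(
            {"sample": [f"s{i}" for i in range(4)],
             "stage": ["earlyL3"] * 2 + ["lateL3"] * 2,
             "damage": ["damaged"] * 4, "replicate": [1, 2, 1, 2]}
        )
        est = estimate_dispersion(counts, size_factors(counts), table, shrink=0.0)
        assert (est == 0).all()

    def test_all_zero_peak_flagged_nan(self):
        mat = np.vstack([np.zeros(4, dtype=int), np.full(4, 9)])
        table = pd.DataFrame(
            {"sample": [f"s{i}" for i in range(4)],
             "stage": ["earlyL3"] * 4, "damage": ["damaged"] * 2 + ["undamaged"] * 2,
             "replicate": [1, 2, 1, 2]}
        )
        est = estimate_dispersion(_counts(mat), pd.Series(1.0, index=[f"s{i}" for i in range(4)]), table)
        assert np.isnan(est.iloc[0]) and not np.isnan(est.iloc[1])


class TestBHAdjust:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_statsmodels_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(rng.integers(1, 200))
        expected = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_adjust(p), expected)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    def test_order_invariant_and_monotone(self, ps):
        p = np.array(ps)
        adj = bh_adjust(p)
        perm = np.random.default_rng(0).permutation(len(p))
        np.testing.assert_allclose(bh_adjust(p[perm]), adj[perm])
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert (adj >= p - 1e-12).all() and (adj <= 1).all()


class TestNBWaldTest:
    CONTRAST = (("earlyL3", "damaged"), ("earlyL3", "undamaged"))

    def test_identical_groups_lfc_near_zero(self):
        design = SimDesign(
            n_peaks=2000, seed=41, label_fractions={}, dispersion=0.0,
            base_sdlog=0.0, depth_sdlog=0.0, base_mean=5000.0,
        )
        truth = make_truth(design)
        counts, table = simulate_counts(design, truth)
        res = nb_wald_test(counts, table, self.CONTRAST)
        assert abs(res["log2FoldChange"].mean()) < 0.01

    def test_planted_unit_lfc_recovered(self):
        # f=1, delta=1 responders embedded among nulls: mean estimate near 1
        design = SimDesign(
            n_peaks=5000, seed=42, dilution_fraction=1.0, effect_lfc=1.0,
            strong_fraction=0.0, base_sdlog=0.0,
            label_fractions={"damage_responsive_early": 0.1},
        )
        truth = make_truth(design)
        counts, table = simulate_counts(design, truth)
        res = nb_wald_test(
            counts, table, self.CONTRAST,
            dispersion=pd.Series(design.dispersion, index=counts.index),
        )
        lab = truth.labels()
        mean_lfc = res.loc[lab == "damage_responsive_early", "log2FoldChange"].mean()
        assert 0.8 <= mean_lfc <= 1.2

    def test_type_one_error_calibrated(self):
        design = SimDesign(n_peaks=10_000, seed=43, label_fractions={})
        truth = make_truth(design)
        counts, table = simulate_counts(design, truth)
        res = nb_wald_test(
            counts, table, self.CONTRAST,
            dispersion=pd.Series(design.dispersion, index=counts.index),
        )
        p = res["pvalue"].to_numpy()
        n = len(p)
        for nominal in (0.01, 0.05, 0.1):
            emp = (p < nominal).mean()
            mc_sd = np.sqrt(nominal * (1 - nominal) / n)
            assert abs(emp - nominal) < 3 * mc_sd

    def test_power_monotone_in_effect_and_dilution(self):
        def detection_rate(f, delta):
            design = SimDesign(
                n_peaks=2000, seed=44, dilution_fraction=f, effect_lfc=delta,
                strong_fraction=0.0,
                label_fractions={"damage_responsive_early": 0.05},
            )
            truth = make_truth(design)
            counts, table = simulate_counts(design, truth)
            res = nb_wald_test(counts, table, self.CONTRAST)
            lab = truth.labels()
            sub = res.loc[lab == "damage_responsive_early"]
            return ((sub["padj"] < 0.1) & (sub["log2FoldChange"] > 0.5)).mean()

        by_delta = [detection_rate(0.15, d) for d in (2.0, 4.0, 6.0)]
        assert by_delta == sorted(by_delta)
        by_f = [detection_rate(f, 3.0) for f in (0.05, 0.3, 1.0)]
        assert by_f == sorted(by_f)

    def test_missing_contrast_group_rejected(self):
        design = SimDesign(n_peaks=10, seed=1, conditions=[("earlyL3", "damaged")])
        truth = make_truth(design)
        counts, table = simulate_counts(design, truth)
        with pytest.raises(ValueError, match="undamaged"):
            nb_wald_test(counts, table, self.CONTRAST)

    def test_padj_invariants(self, default_run):
        res = default_run["results"]["dr_early"].dropna()
        assert ((res["pvalue"] >= 0) & (res["pvalue"] <= 1)).all()
        assert (res["padj"] >= res["pvalue"] - 1e-12).all()


class TestSignalTracks:
    SIZES = {"chrT": 100}

    def test_uniform_coverage_zero_track(self):
        frags = pd.DataFrame({"chrom": ["chrT"], "start": [0], "end": [100]})
        track = signal_track(frags, self.SIZES, bin_size=10)
        assert (track["z"] == 0).all()

    def test_self_subtraction_zero(self):
        rng = np.random.default_rng(2)
        frags = pd.DataFrame(
            {"chrom": "chrT", "start": (s := rng.integers(0, 90, 30)), "end": s + 5}
        )
        track = signal_track(frags, self.SIZES)
        assert (subtract_tracks(track, track)["z"] == 0).all()

    def test_planted_drms_peak_positive_in_both_differences(self):
        # pooled coverage fixture: a damage-responsive region at 40-60 and a
        # constant reference feature at 70-90 (z-scores are standardized per
        # condition, so a varying peak only stands out relative to stable
        # features)
        def cov(n_at_peak):
            rows = (
                [("chrT", 40, 60)] * n_at_peak
                + [("chrT", 70, 90)] * 10
                + [("chrT", 0, 100)] * 2
            )
            return pd.DataFrame(rows, columns=["chrom", "start", "end"])

        z_ed = signal_track(cov(8), self.SIZES)
        z_eu = signal_track(cov(0), self.SIZES)
        z_ld = signal_track(cov(1), self.SIZES)
        at_peak = lambda t: t[(t["start"] >= 40) & (t["end"] <= 60)]["z"].mean()
        assert at_peak(subtract_tracks(z_ed, z_eu)) > 0
        assert at_peak(subtract_tracks(z_ed, z_ld)) > 0

    def test_mismatched_bins_rejected(self):
        frags = pd.DataFrame({"chrom": ["chrT"], "start": [0], "end": [50]})
        a = signal_track(frags, self.SIZES, bin_size=10)
        b = signal_track(frags, self.SIZES, bin_size=20)
        with pytest.raises(ValueError):
            subtract_tracks(a, b)
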