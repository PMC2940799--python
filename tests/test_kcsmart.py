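"""Kernel smoothing, permutation thresholds, region and peak calling."""

import math
from itertools import permutations

import numpy as np
import pandas as pd
import pytest

import crosscna as c
from crosscna.kcsmart import probe_aggregates

from .oracles import brute_kse_values, scan_runs


def make_curve(sign, grid_mb, values):
    grid = np.asarray(grid_mb, dtype=float) * 1e6
    return c.KSECurve(sign, ["1"], {"1": grid}, {"1": np.asarray(values, dtype=float)})


class TestGroupKSE:
    def test_zero_matrix_zero_curve(self, probe_map, fast_params):
        grp = c.simulate_group(probe_map, c.GroupSpec("g", 3, 0.0), seed=0)
        assert c.group_kse(grp, "gains", fast_params).max_abs() == 0.0

    def test_single_probe_closed_form(self, fast_params):
        genome = c.uniform_genome(1, 40_000_000)
        pm = c.build_probe_map(genome, 1, seed=1)
        q = pm.positions("1")[0]
        ids = pd.Index(["s0"], name="sample_id")
        values = pd.DataFrame([[0.7]], index=ids, columns=pm.table["probe_id"])
        samples = pd.DataFrame({"group": "g", "tumor_type": "u"}, index=ids)
        grp = c.ACGHGroup(pm, values, samples)

        gains = c.group_kse(grp, "gains", fast_params)
        sigma = fast_params.resolved_sigma
        radius = fast_params.resolved_truncation
        grid = gains.grid["1"]
        expected = np.where(np.abs(grid - q) <= radius,
                            0.7 * np.exp(-((grid - q) ** 2) / (2 * sigma**2)), 0.0)
        np.testing.assert_allclose(gains.values["1"], expected, atol=1e-12)
        assert c.group_kse(grp, "losses", fast_params).max_abs() == 0.0

    def test_matches_brute_force_double_sum(self, fast_params):
        from .conftest import random_cohort
        rng = np.random.default_rng(123)
        for _ in range(5):
            grp = random_cohort(rng)
            for sign in ("gains", "losses", "combined"):
                curve = c.group_kse(grp, sign, fast_params)
                agg = probe_aggregates(grp, sign)
                for chrom in curve.chroms:
                    expected = brute_kse_values(
                        grp.probes.positions(chrom).astype(float),
                        agg[grp.probes.probe_indices(chrom)],
                        curve.grid[chrom],
                        fast_params.resolved_sigma, fast_params.resolved_truncation)
                    assert np.max(np.abs(curve.values[chrom] - expected)) < 1e-9

    def test_additivity_combined_is_gains_plus_losses(self, noisy_cohort, fast_params):
        gains = c.group_kse(noisy_cohort, "gains", fast_params)
        losses = c.group_kse(noisy_cohort, "losses", fast_params)
        combined = c.group_kse(noisy_cohort, "combined", fast_params)
        for chrom in combined.chroms:
            np.testing.assert_allclose(
                combined.values[chrom],
                gains.values[chrom] + losses.values[chrom], atol=1e-10)

    def test_linearity_over_samples(self, noisy_cohort, fast_params):
        two = c.ACGHGroup(noisy_cohort.probes, noisy_cohort.values.iloc[:2],
                          noisy_cohort.samples.iloc[:2])
        singles = [c.ACGHGroup(noisy_cohort.probes, noisy_cohort.values.iloc[[i]],
                               noisy_cohort.samples.iloc[[i]]) for i in range(2)]
        pair_curve = c.group_kse(two, "gains", fast_params)
        solo = [c.group_kse(s, "gains", fast_params) for s in singles]
        for chrom in pair_curve.chroms:
            np.testing.assert_allclose(
                pair_curve.values[chrom],
                solo[0].values[chrom] + solo[1].values[chrom], atol=1e-10)

    def test_kernels_do_not_cross_chromosomes(self, fast_params):
        genome = c.uniform_genome(2, 30_000_000)
        pm = c.build_probe_map(genome, 10, seed=2)
        ids = pd.Index(["s0"], name="sample_id")
        mat = np.zeros((1, 10))
        mat[0, pm.probe_indices("1")] = 1.0  # signal only on chromosome 1
        values = pd.DataFrame(mat, index=ids, columns=pm.table["probe_id"])
        samples = pd.DataFrame({"group": "g", "tumor_type": "u"}, index=ids)
        curve = c.group_kse(c.ACGHGroup(pm, values, samples), "gains", fast_params)
        assert np.all(curve.values["2"] == 0.0)


class TestSignificanceThreshold:
    def test_all_zero_data_degenerate_null(self, probe_map, fast_params):
        grp = c.simulate_group(probe_map, c.GroupSpec("g", 3, 0.0), seed=0)
        with pytest.warns(UserWarning, match="degenerate"):
            thr = c.significance_threshold(grp, "gains", fast_params, n_perm=30, seed=1)
        assert thr.value == 0.0

    def test_quantile_convention_kth_largest(self, noisy_cohort, fast_params):
        thr = c.significance_threshold(noisy_cohort, "gains", fast_params,
                                       n_perm=100, alpha=0.05, seed=5)
        k = math.floor(0.05 * 100) + 1
        assert thr.value == np.sort(thr.null_maxima)[::-1][k - 1]
        assert len(thr.null_maxima) == 100

    def test_matches_exhaustive_enumeration(self):
        """Two unit aggregates on four close probes: the null max depends only
        on whether they land adjacent, so all 4! assignments enumerate the
        exact null distribution; sampled permutations hit its quantile."""
        genome = c.uniform_genome(1, 4_000_000)
        pm = c.ProbeMap(pd.DataFrame({
            "probe_id": [f"p{i}" for i in range(4)],
            "chrom": "1",
            "mid_bp": [0, 1_000_000, 2_000_000, 3_000_000]}),
            chrom_lengths=genome.lengths)
        params = c.KSEParams(kernel_width=4e6, grid_step=500_000)
        agg = np.array([1.0, 1.0, 0.0, 0.0])

        maxima = []
        for perm in permutations(range(4)):
            h = agg[list(perm)]
            vals = brute_kse_values(pm.positions("1").astype(float), h,
                                    np.arange(0, 4_000_001, 100_000, dtype=float),
                                    params.resolved_sigma, params.resolved_truncation)
            maxima.append(np.max(np.abs(vals)))
        maxima = np.sort(maxima)[::-1]
        alpha, n_perm = 0.25, 2000
        k_exact = math.floor(alpha * len(maxima)) + 1
        exact = maxima[k_exact - 1]

        ids = pd.Index(["s0"], name="sample_id")
        values = pd.DataFrame(agg[None, :], index=ids, columns=pm.table["probe_id"])
        samples = pd.DataFrame({"group": "g", "tumor_type": "u"}, index=ids)
        grp = c.ACGHGroup(pm, values, samples)
        thr = c.significance_threshold(grp, "gains", params, n_perm=n_perm,
                                       alpha=alpha, seed=3)
        assert thr.value == pytest.approx(exact, rel=1e-6)

    def test_nperm_floor(self, noisy_cohort, fast_params):
        with pytest.raises(ValueError, match="n_perm"):
            c.significance_threshold(noisy_cohort, "gains", fast_params, n_perm=5)


class TestCallRegions:
    def test_below_threshold_empty(self):
        curve = make_curve("gains", [0, 1, 2, 3], [0.0, 0.5, 0.5, 0.0])
        thr = c.Threshold(1.0, 0.05, 100, "gains")
        assert c.call_regions(curve, thr) == []

    def test_linear_interpolated_bounds(self):
        curve = make_curve("gains", [0, 1, 2, 3], [0.0, 2.0, 2.0, 0.0])
        thr = c.Threshold(1.0, 0.05, 100, "gains")
        (region,) = c.call_regions(curve, thr)
        assert region.start == pytest.approx(0.5e6)
        assert region.end == pytest.approx(2.5e6)
        assert region.direction == "gain"
        assert region.peak_height == 2.0

    def test_losses_mirror_gains(self):
        curve = make_curve("losses", [0, 1, 2, 3], [0.0, -2.0, -2.0, 0.0])
        thr = c.Threshold(1.0, 0.05, 100, "losses")
        (region,) = c.call_regions(curve, thr)
        assert region.start == pytest.approx(0.5e6)
        assert region.end == pytest.approx(2.5e6)
        assert region.direction == "loss"
        assert region.peak_height == -2.0

    def test_matches_run_scan_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            n = int(rng.integers(5, 40))
            grid = np.sort(rng.choice(np.arange(0, 100), size=n, replace=False)) * 1e6
            vals = rng.normal(0, 1, size=n)
            cutoff = float(rng.uniform(0.2, 1.0))
            curve = make_curve("gains", grid / 1e6, vals)
            got = c.call_regions(curve, c.Threshold(cutoff, 0.05, 100, "gains"))
            want = scan_runs(grid, vals, cutoff, above=True)
            assert len(got) == len(want)
            for g, w in zip(got, want):
                assert g.start == pytest.approx(w["start"])
                assert g.end == pytest.approx(w["end"])
                assert g.peak_pos == pytest.approx(w["peak_pos"])
                assert g.peak_height == pytest.approx(w["peak_height"])

    def test_sign_mismatch_rejected(self):
        curve = make_curve("gains", [0, 1, 2], [0, 1, 0])
        with pytest.raises(ValueError, match="sign"):
            c.call_regions(curve, c.Threshold(0.5, 0.05, 100, "losses"))


class TestFindPeaks:
    def test_monotone_curve_no_peaks(self):
        assert c.find_peaks(make_curve("gains", [0, 1, 2, 3], [0, 1, 2, 3])) == []

    def test_simple_peak(self):
        (peak,) = c.find_peaks(make_curve("gains", [0, 1, 2], [0, 1, 0]))
        assert peak.pos == 1e6 and peak.height == 1.0

    def test_plateau_reports_leftmost(self):
        (peak,) = c.find_peaks(make_curve("gains", [0, 1, 2, 3], [0, 1, 1, 0]))
        assert peak.pos == 1e6

    def test_losses_are_minima(self):
        (peak,) = c.find_peaks(make_curve("losses", [0, 1, 2], [0, -1, 0]))
        assert peak.height == -1.0

    def test_combined_reports_both(self):
        peaks = c.find_peaks(make_curve("combined", [0, 1, 2, 3, 4], [0, 1, 0, -1, 0]))
        assert sorted(p.height for p in peaks) == [-1.0, 1.0]

    def test_endpoints_excluded(self):
        assert c.find_peaks(make_curve("gains", [0, 1, 2], [2, 1, 0])) == []

    def test_too_few_grid_points(self):
        with pytest.raises(ValueError, match="fewer than 3"):
            c.find_peaks(make_curve("gains", [0, 1], [0, 1]))


class TestScaleCurve:
    def test_division(self):
        curve = make_curve("gains", [0, 1, 2], [0.0, 2.4, 1.2])
        scaled = c.scale_curve(curve, c.Threshold(1.2, 0.05, 100, "gains"))
        np.testing.assert_allclose(scaled.values["1"], [0.0, 2.0, 1.0])

    def test_losses_cutoff_maps_to_minus_one(self):
        curve = make_curve("losses", [0, 1, 2], [0.0, -1.2, -0.6])
        scaled = c.scale_curve(curve, c.Threshold(1.2, 0.05, 100, "losses"))
        assert scaled.values["1"][1] == pytest.approx(-1.0)

    def test_zero_threshold_rejected(self):
        curve = make_curve("gains", [0, 1, 2], [0, 1, 0])
        with pytest.raises(ValueError, match="zero"):
            c.scale_curve(curve, c.Threshold(0.0, 0.05, 100, "gains"))

    def test_commutes_with_region_calling(self, noisy_cohort, fast_params):
        curve = c.group_kse(noisy_cohort, "gains", fast_params)
        thr = c.significance_threshold(noisy_cohort, "gains", fast_params,
                                       n_perm=50, seed=2)
        direct = c.call_regions(curve, thr)
        scaled = c.scale_curve(curve, thr)
        unit = c.call_regions(scaled, c.Threshold(1.0, thr.alpha, thr.n_perm, "gains"))
        assert len(direct) == len(unit)
        for d, u in zip(direct, unit):
            assert d.start == pytest.approx(u.start)
            assert d.end == pytest.approx(u.end)
            assert d.peak_height == pytest.approx(u.peak_height * thr.value)
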