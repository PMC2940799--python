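"""Per-sample KSE curves, SNR contrast, and class-label permutation FDR."""

import numpy as np
import pandas as pd
import pytest

import crosscna as c
from crosscna.kcsmart import probe_aggregates

from .oracles import brute_kse_values, exhaustive_fdr_cutoffs, snr_1d


def two_group_cohort(probe_map, cna_a=None, cna_b=None, n=6, noise=0.2,
                     seed_a=1, seed_b=2):
    a = c.simulate_group(probe_map, c.GroupSpec("A", n, noise, cnas=cna_a or ()), seed_a)
    b = c.simulate_group(probe_map, c.GroupSpec("B", n, noise, cnas=cna_b or ()), seed_b)
    return c.merge_groups([a, b])


def toy_matrix(values, labels):
    """SampleKSEMatrix on a bare 1-chromosome grid, one position per column."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    ids = [f"s{i}" for i in range(n)]
    grid = np.arange(m, dtype=float) * 1e6
    return c.SampleKSEMatrix(["1"], {"1": grid}, {"1": slice(0, m)}, values,
                             ids, pd.Series(labels, index=ids))


class TestSampleKSEMatrix:
    def test_zero_data_zero_matrix(self, probe_map, fast_params):
        cohort = two_group_cohort(probe_map, noise=0.0)
        m = c.sample_kse_matrix(cohort, fast_params)
        assert np.all(m.values == 0.0)

    def test_rows_are_combined_single_sample_curves(self, noisy_cohort, fast_params):
        m = c.sample_kse_matrix(noisy_cohort, fast_params, normalized=False)
        sid = noisy_cohort.sample_ids[0]
        single = c.ACGHGroup(noisy_cohort.probes, noisy_cohort.values.loc[[sid]],
                             noisy_cohort.samples.loc[[sid]])
        gains = c.group_kse(single, "gains", fast_params)
        losses = c.group_kse(single, "losses", fast_params)
        row = m.sample_curve(sid)
        for chrom in row.chroms:
            np.testing.assert_allclose(
                row.values[chrom], gains.values[chrom] + losses.values[chrom],
                atol=1e-10)

    def test_row_matches_brute_force_convolution(self, noisy_cohort, fast_params):
        m = c.sample_kse_matrix(noisy_cohort, fast_params, normalized=False)
        sid = noisy_cohort.sample_ids[2]
        single = c.ACGHGroup(noisy_cohort.probes, noisy_cohort.values.loc[[sid]],
                             noisy_cohort.samples.loc[[sid]])
        agg = probe_aggregates(single, "combined")
        row = m.sample_curve(sid)
        for chrom in row.chroms:
            expected = brute_kse_values(
                noisy_cohort.probes.positions(chrom).astype(float),
                agg[noisy_cohort.probes.probe_indices(chrom)],
                row.grid[chrom], fast_params.resolved_sigma,
                fast_params.resolved_truncation)
            assert np.max(np.abs(row.values[chrom] - expected)) < 1e-9

    def test_normalized_rows_divide_by_kernel_mass(self, noisy_cohort, fast_params):
        from crosscna.kcsmart import KernelDesign
        design = KernelDesign(noisy_cohort.probes, fast_params)
        raw = c.sample_kse_matrix(noisy_cohort, fast_params, normalized=False)
        norm = c.sample_kse_matrix(noisy_cohort, fast_params, normalized=True)
        for chrom in norm.chroms:
            wsum = design.weight_sums[chrom]
            np.testing.assert_allclose(norm.values[:, norm.offsets[chrom]] * wsum,
                                       raw.values[:, raw.offsets[chrom]], atol=1e-10)

    def test_snr_invariant_under_normalization(self, noisy_cohort, fast_params):
        """Per-position scaling cancels in the SNR, so normalized and raw
        per-sample curves give identical comparative results."""
        cohort = noisy_cohort
        labels = ["A"] * 4 + ["B"] * 4
        cohort.samples["group"] = labels
        raw = c.sample_kse_matrix(cohort, fast_params, normalized=False)
        norm = c.sample_kse_matrix(cohort, fast_params, normalized=True)
        np.testing.assert_allclose(c.snr_curve(raw, "A", "B").values,
                                   c.snr_curve(norm, "A", "B").values, atol=1e-9)

    def test_mismatched_probe_maps_rejected(self, fast_params):
        g1 = c.uniform_genome(2, 40_000_000)
        pm1 = c.build_probe_map(g1, 20, seed=1)
        pm2 = c.build_probe_map(g1, 20, seed=2)
        a = c.simulate_group(pm1, c.GroupSpec("A", 3, 0.1), 1)
        b = c.simulate_group(pm2, c.GroupSpec("B", 3, 0.1), 2)
        with pytest.raises(ValueError, match="probe map"):
            c.sample_kse_matrix([a, b], fast_params)


class TestSNRCurve:
    def test_identical_constant_rows_zero_by_convention(self):
        m = toy_matrix(np.ones((6, 4)), ["A"] * 3 + ["B"] * 3)
        snr = c.snr_curve(m, "A", "B")
        assert np.all(snr.values == 0.0)

    def test_closed_form_value(self):
        col = np.array([[1.0], [2.0], [3.0], [0.0], [0.0], [0.0]])
        m = toy_matrix(col, ["A"] * 3 + ["B"] * 3)
        snr = c.snr_curve(m, "A", "B")
        assert snr.values[0] == pytest.approx(2.0)  # (2-0)/(1+0)

    def test_antisymmetry_under_group_swap(self, probe_map, fast_params):
        cohort = two_group_cohort(
            probe_map, cna_a=(c.CNASpec("1", 0, 20_000_000, "gain", 0.8, 0.9),))
        m = c.sample_kse_matrix(cohort, fast_params)
        ab = c.snr_curve(m, "A", "B")
        ba = c.snr_curve(m, "B", "A")
        np.testing.assert_allclose(ab.values, -ba.values, atol=1e-12)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(0, 1, size=(7, 5))
        m = toy_matrix(vals, ["A"] * 4 + ["B"] * 3)
        snr = c.snr_curve(m, "A", "B")
        for j in range(5):
            assert snr.values[j] == pytest.approx(
                snr_1d(list(vals[:4, j]), list(vals[4:, j])))

    def test_small_group_rejected(self):
        m = toy_matrix(np.zeros((3, 2)), ["A", "B", "B"])
        with pytest.raises(ValueError, match=">= 2 samples"):
            c.snr_curve(m, "A", "B")


class TestFDRCutoffs:
    def test_exhaustive_equivalence_on_toy(self):
        """3-vs-3 toy: all C(6,3)=20 assignments enumerate the exact FDR
        curve; the library must reproduce the brute-force cutoffs."""
        rng = np.random.default_rng(11)
        vals = rng.normal(0, 0.3, size=(6, 30))
        vals[:3, 5:9] += 2.0   # one strongly A-specific stretch
        vals[3:, 20:22] += 1.5  # and a weaker B-specific one
        m = toy_matrix(vals, ["A"] * 3 + ["B"] * 3)
        cuts = c.snr_fdr_cutoffs(m, "A", "B", n_perm=100, q=0.05, seed=0)
        assert cuts.exhaustive and cuts.n_perm == 20
        want_pos, want_neg = exhaustive_fdr_cutoffs(vals, 3, 0.05)
        if want_pos is None:
            assert cuts.positive is None
        else:
            assert cuts.positive == pytest.approx(want_pos)
        if want_neg is None:
            assert cuts.negative is None
        else:
            assert cuts.negative == pytest.approx(want_neg)

    def test_null_data_rarely_calls(self, fast_params):
        """Same-null groups: no positions pass at q=0.05 in >= 90% of runs."""
        genome = c.uniform_genome(2, 50_000_000)
        pm = c.build_probe_map(genome, 100, seed=21)
        n_called = 0
        for rep in range(50):
            cohort = two_group_cohort(pm, n=8, noise=0.2,
                                      seed_a=1000 + rep, seed_b=5000 + rep)
            m = c.sample_kse_matrix(cohort, fast_params)
            cuts = c.snr_fdr_cutoffs(m, "A", "B", n_perm=200, q=0.05, seed=rep)
            snr = c.snr_curve(m, "A", "B")
            if c.differential_regions(snr, cuts):
                n_called += 1
        assert n_called <= 5

    def test_identical_labels_rejected(self):
        m = toy_matrix(np.zeros((4, 2)), ["A", "A", "B", "B"])
        with pytest.raises(ValueError, match="labels"):
            c.snr_fdr_cutoffs(m, "A", "A")


class TestDifferentialRegions:
    def test_inside_cutoffs_empty(self):
        m = toy_matrix(np.zeros((4, 3)), ["A", "A", "B", "B"])
        snr = c.snr_curve(m, "A", "B")
        cuts = c.FDRCutoffs(1.0, 1.0, 0.05, 20, True, ("A", "B"))
        assert c.differential_regions(snr, cuts) == []

    def test_triangular_excursion_interpolated(self):
        grid = np.arange(4, dtype=float) * 1e6
        snr = c.SNRCurve(["1"], {"1": grid}, {"1": slice(0, 4)},
                         np.array([0.0, 2.0, 2.0, 0.0]), ("A", "B"))
        cuts = c.FDRCutoffs(1.0, None, 0.05, 20, True, ("A", "B"))
        (region,) = c.differential_regions(snr, cuts)
        assert region.start == pytest.approx(0.5e6)
        assert region.end == pytest.approx(2.5e6)
        assert region.direction == "A>B"

    def test_negative_tail_labeled_b_over_a(self):
        grid = np.arange(3, dtype=float) * 1e6
        snr = c.SNRCurve(["1"], {"1": grid}, {"1": slice(0, 3)},
                         np.array([0.0, -2.0, 0.0]), ("A", "B"))
        cuts = c.FDRCutoffs(None, 1.0, 0.05, 20, True, ("A", "B"))
        (region,) = c.differential_regions(snr, cuts)
        assert region.direction == "B>A"
        assert region.peak_height == -2.0

    def test_mismatched_pair_rejected(self):
        grid = np.arange(3, dtype=float) * 1e6
        snr = c.SNRCurve(["1"], {"1": grid}, {"1": slice(0, 3)},
                         np.zeros(3), ("A", "B"))
        cuts = c.FDRCutoffs(1.0, 1.0, 0.05, 20, True, ("A", "C"))
        with pytest.raises(ValueError, match="pair"):
            c.differential_regions(snr, cuts)

    def test_region_mirror_under_group_swap(self, probe_map, fast_params):
        # 5-vs-5 keeps C(10,5)=252 <= n_perm, so enumeration is exhaustive
        # and the two orderings see exactly mirrored permutation tails
        cohort = two_group_cohort(
            probe_map, cna_a=(c.CNASpec("1", 0, 25_000_000, "gain", 0.9, 1.0),),
            n=5)
        m = c.sample_kse_matrix(cohort, fast_params)
        ab_cuts = c.snr_fdr_cutoffs(m, "A", "B", n_perm=300, q=0.05, seed=1)
        ba_cuts = c.snr_fdr_cutoffs(m, "B", "A", n_perm=300, q=0.05, seed=1)
        ab = c.differential_regions(c.snr_curve(m, "A", "B"), ab_cuts)
        ba = c.differential_regions(c.snr_curve(m, "B", "A"), ba_cuts)
        assert [(r.chrom, r.start, r.end, r.direction) for r in ab] == \
               [(r.chrom, r.start, r.end, r.direction) for r in ba]
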