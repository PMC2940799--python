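"""Simulation studies that calibrate and stress the pipeline end to end.

Each study simulates cohorts with the synthetic generator, runs the full
analysis path, and reports a single operating characteristic: familywise
error on null data, power to recover a planted gain, sensitivity and
shared-aberration suppression of the comparative analysis, cross-species
recovery of planted syntenic events, and the type-I error of the Welch
contrast.

Default problem sizes (1 Gb genome of 8 equal chromosomes, 1,000 probes,
30 samples per group, log2 noise sd 0.2, 500 kb evaluation grid) keep each
study in the seconds-to-minutes range on one CPU while preserving the probe
density and kernel-to-chromosome proportions of BAC-array data.
"""

from __future__ import annotations

import numpy as np

from . import comparative as comp
from . import kcsmart as kc
from .genome import GenomeSpec, uniform_genome
from .io import ACGHGroup
from .regions import Region
from .simulate import CNASpec, GroupSpec, SyntenyBlockSpec, build_ortholog_table, \
    build_probe_map, merge_groups, simulate_group
from .synteny import map_regions


def _default_genome() -> GenomeSpec:
    return uniform_genome(8, 125_000_000)


def _default_params() -> kc.KSEParams:
    return kc.KSEParams(kernel_width=20e6, grid_step=500_000)


def _seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def fwer_null_study(n_datasets: int = 200, n_probes: int = 1000, n_samples: int = 30,
                    noise_sd: float = 0.2, alpha: float = 0.05, n_perm: int = 200,
                    seed: int = 0, genome: GenomeSpec | None = None,
                    params: kc.KSEParams | None = None) -> dict:
    """Fraction of pure-noise datasets with at least one called gain region.

    The max-peak permutation threshold makes region calling a genome-wide
    maximum test per sign, so this fraction should sit near *alpha*.
    """
    genome = genome or _default_genome()
    params = params or _default_params()
    seeds = _seeds(seed, 3 * n_datasets).reshape(n_datasets, 3)
    n_called = 0
    for s_map, s_grp, s_thr in seeds:
        pm = build_probe_map(genome, n_probes, int(s_map))
        grp = simulate_group(pm, GroupSpec("null", n_samples, noise_sd), int(s_grp))
        design = kc.KernelDesign(pm, params)
        curve = kc.group_kse(grp, "gains", params, design=design)
        thr = kc.significance_threshold(grp, "gains", params, n_perm=n_perm,
                                        alpha=alpha, seed=int(s_thr), design=design)
        if kc.call_regions(curve, thr):
            n_called += 1
    return {"fwer": n_called / n_datasets, "n_datasets": n_datasets,
            "n_called": n_called}


def gain_recovery_study(n_runs: int = 100, frequency: float = 0.6,
                        amplitude: float = 0.8, event_start: float = 40e6,
                        event_end: float = 70e6, n_probes: int = 1000,
                        n_samples: int = 30, noise_sd: float = 0.2,
                        n_perm: int = 200, alpha: float = 0.05, seed: int = 0,
                        peak_tolerance: float = 10e6,
                        genome: GenomeSpec | None = None,
                        params: kc.KSEParams | None = None) -> dict:
    """How often a planted 30 Mb gain yields an overlapping called region
    with a KSE peak within *peak_tolerance* of the event center.

    Peaks are local maxima of the gains curve (an event wider than the
    kernel produces a broad top carrying several local peaks, all part of
    the recovered signal); the peak must fall inside the called region.
    """
    genome = genome or _default_genome()
    params = params or _default_params()
    cna = CNASpec("1", int(event_start), int(event_end), "gain", frequency, amplitude)
    center = (event_start + event_end) / 2
    seeds = _seeds(seed, 3 * n_runs).reshape(n_runs, 3)
    n_recovered = 0
    for s_map, s_grp, s_thr in seeds:
        pm = build_probe_map(genome, n_probes, int(s_map))
        grp = simulate_group(pm, GroupSpec("g", n_samples, noise_sd, cnas=(cna,)),
                             int(s_grp))
        design = kc.KernelDesign(pm, params)
        curve = kc.group_kse(grp, "gains", params, design=design)
        thr = kc.significance_threshold(grp, "gains", params, n_perm=n_perm,
                                        alpha=alpha, seed=int(s_thr), design=design)
        peaks = [p for p in kc.find_peaks(curve) if p.chrom == "1"]
        for region in kc.call_regions(curve, thr):
            if region.overlaps("1", event_start, event_end) and any(
                    region.start <= p.pos <= region.end
                    and abs(p.pos - center) <= peak_tolerance for p in peaks):
                n_recovered += 1
                break
    return {"recovery_rate": n_recovered / n_runs, "n_runs": n_runs,
            "n_recovered": n_recovered}


def comparative_power_study(n_runs: int = 100, shared: bool = False,
                            frequency: float = 0.7, amplitude: float = 0.8,
                            event_start: float = 40e6, event_end: float = 70e6,
                            n_probes: int = 1000, n_samples: int = 30,
                            noise_sd: float = 0.2, n_perm: int = 500,
                            q: float = 0.05, seed: int = 0,
                            genome: GenomeSpec | None = None,
                            params: kc.KSEParams | None = None) -> dict:
    """Comparative calling rate for a planted event.

    With ``shared=False`` the event exists only in group A and the reported
    rate is the sensitivity of an A>B call overlapping the event; with
    ``shared=True`` the event sits at equal frequency in both groups and the
    rate counts runs where any differential region falsely overlaps it.
    """
    genome = genome or _default_genome()
    params = params or _default_params()
    cna = CNASpec("1", int(event_start), int(event_end), "gain", frequency, amplitude)
    seeds = _seeds(seed, 4 * n_runs).reshape(n_runs, 4)
    n_called = 0
    for s_map, s_a, s_b, s_perm in seeds:
        pm = build_probe_map(genome, n_probes, int(s_map))
        a = simulate_group(pm, GroupSpec("A", n_samples, noise_sd, cnas=(cna,)),
                           int(s_a))
        b_cnas = (cna,) if shared else ()
        b = simulate_group(pm, GroupSpec("B", n_samples, noise_sd, cnas=b_cnas),
                           int(s_b))
        matrix = comp.sample_kse_matrix(merge_groups([a, b]), params)
        snr = comp.snr_curve(matrix, "A", "B")
        cuts = comp.snr_fdr_cutoffs(matrix, "A", "B", n_perm=n_perm, q=q,
                                    seed=int(s_perm))
        regions = comp.differential_regions(snr, cuts)
        if shared:
            hit = any(r.overlaps("1", event_start, event_end) for r in regions)
        else:
            hit = any(r.direction == "A>B" and r.overlaps("1", event_start, event_end)
                      for r in regions)
        n_called += hit
    return {"call_rate": n_called / n_runs, "n_runs": n_runs, "n_called": n_called}


def _called_regions(group: ACGHGroup, params: kc.KSEParams, n_perm: int,
                    seed: int) -> list[Region]:
    design = kc.KernelDesign(group.probes, params)
    out: list[Region] = []
    for i, sign in enumerate(("gains", "losses")):
        curve = kc.group_kse(group, sign, params, design=design)
        thr = kc.significance_threshold(group, sign, params, n_perm=n_perm,
                                        seed=seed + i, design=design)
        out.extend(kc.call_regions(curve, thr))
    return out


def synteny_recovery_study(n_runs: int = 10, noise_sd: float = 0.0,
                           frequency: float = 0.8, n_samples: int = 20,
                           n_probes: int = 300, n_perm: int = 100,
                           seed: int = 0) -> dict:
    """End-to-end cross-species recovery of two planted conserved events.

    Each run simulates two species sharing a conserved gain over a plain
    synteny block and a conserved loss over an inverted block, calls regions
    in both species, and maps them through the ortholog table. A run counts
    as recovered only if both overlaps appear with the correct direction,
    bounds spanning exactly first-gene-start to last-gene-end, and the
    correct inversion flag.
    """
    genome_a = uniform_genome(3, 100_000_000, "A")
    genome_b = uniform_genome(3, 100_000_000, "B")
    gain_block = SyntenyBlockSpec("1", 35_000_000, "2", 45_000_000, 6)
    loss_block = SyntenyBlockSpec("2", 20_000_000, "3", 60_000_000, 5, inverted=True)
    orthologs = build_ortholog_table(genome_a, genome_b, [gain_block, loss_block])
    params = kc.KSEParams(kernel_width=20e6, grid_step=500_000)

    cnas_a = (CNASpec("1", 30_000_000, 50_000_000, "gain", frequency, 0.8),
              CNASpec("2", 15_000_000, 35_000_000, "loss", frequency, -0.8))
    cnas_b = (CNASpec("2", 40_000_000, 60_000_000, "gain", frequency, 0.8),
              CNASpec("3", 55_000_000, 75_000_000, "loss", frequency, -0.8))

    def block_bounds(block):
        return (block.start_A, block.start_A + block.span,
                block.start_B, block.start_B + block.span)

    seeds = _seeds(seed, 4 * n_runs).reshape(n_runs, 4)
    n_ok = 0
    for s_ma, s_a, s_mb, s_b in seeds:
        pm_a = build_probe_map(genome_a, n_probes, int(s_ma))
        pm_b = build_probe_map(genome_b, n_probes, int(s_mb))
        grp_a = simulate_group(pm_a, GroupSpec("A", n_samples, noise_sd, cnas=cnas_a),
                               int(s_a))
        grp_b = simulate_group(pm_b, GroupSpec("B", n_samples, noise_sd, cnas=cnas_b),
                               int(s_b))
        regions_a = _called_regions(grp_a, params, n_perm, int(s_a))
        regions_b = _called_regions(grp_b, params, n_perm, int(s_b))
        overlaps = map_regions(orthologs, regions_a, regions_b)

        gain_ok = loss_ok = False
        for ov in overlaps:
            if ov.direction == "gain" and ov.n_pairs == 6:
                a0, a1, b0, b1 = block_bounds(gain_block)
                gain_ok = (ov.start_a == a0 and ov.end_a == a1
                           and ov.start_b == b0 and ov.end_b == b1
                           and ov.inversion == 1)
            if ov.direction == "loss" and ov.n_pairs == 5:
                a0, a1, b0, b1 = block_bounds(loss_block)
                loss_ok = (ov.start_a == a0 and ov.end_a == a1
                           and ov.start_b == b0 and ov.end_b == b1
                           and ov.inversion == -1)
        n_ok += gain_ok and loss_ok
    return {"recovery_rate": n_ok / n_runs, "n_runs": n_runs, "n_recovered": n_ok}


def welch_type1_study(n_draws: int = 2000, n_per_group: int = 10,
                      alpha: float = 0.05, seed: int = 0) -> dict:
    """Empirical type-I error of the Welch contrast on equal-null groups."""
    from .instability import welch_test

    rng = np.random.default_rng(seed)
    n_reject = 0
    for _ in range(n_draws):
        a = rng.normal(0, 1, n_per_group)
        b = rng.normal(0, 1, n_per_group)
        n_reject += welch_test(a, b)[1] < alpha
    return {"type1_error": n_reject / n_draws, "n_draws": n_draws}
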