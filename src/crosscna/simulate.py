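"""Synthetic two-species aCGH cohorts with known, planted copy-number events.

The generator emulates BAC-array cohorts: ~3,080 probes for a mouse-like
genome, log2-ratio Gaussian noise per probe per sample, and recurrent focal
or whole-chromosome gains/losses planted at a chosen carrier frequency and
amplitude. Ortholog tables are built from explicit synteny blocks, optionally
inverted, so cross-species mapping has exact ground truth.

Randomness contract
-------------------
All draws come from ``numpy.random.default_rng(seed)`` and are consumed in a
fixed order so a (spec, seed) pair is fully reproducible:

1. probe placement (``build_probe_map``): per chromosome in genome order,
   uniform integer positions, deduplicated, sorted;
2. ``simulate_group``: for each CNA in list order — carrier Bernoulli draws
   (one per sample, sample order), then amplitude draws (one per carrier,
   sample order); then the per-probe-per-sample noise matrix in one block
   (sample-major); then tumor-type assignment (one categorical draw per
   sample).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeSpec
from .io import ACGHGroup, OrthologTable, ProbeMap

log = logging.getLogger(__name__)

EVENT_COLUMNS = ["sample_id", "chrom", "start", "end", "direction", "amplitude"]


@dataclass(frozen=True)
class CNASpec:
    """One recurrent copy-number event planted in a cohort.

    ``frequency`` is the independent per-sample carrier probability; a
    carrier's probes inside ``[start, end)`` are shifted by one amplitude
    drawn from Normal(``amplitude_mean``, ``amplitude_sd``) — constant across
    the event's probes, matching segment-level biology. ``amplitude_mean``
    must be positive for gains and negative for losses.
    """

    chrom: str
    start: int
    end: int
    direction: str
    frequency: float
    amplitude_mean: float
    amplitude_sd: float = 0.0
    whole_chromosome: bool = False

    def __post_init__(self) -> None:
        if self.direction not in ("gain", "loss"):
            raise ValueError(f"direction must be 'gain' or 'loss', got {self.direction!r}")
        if not self.whole_chromosome and not 0 <= self.start < self.end:
            raise ValueError("CNA must have 0 <= start < end")
        if not 0 <= self.frequency <= 1:
            raise ValueError("frequency must be in [0, 1]")
        if self.amplitude_sd < 0:
            raise ValueError("amplitude_sd must be >= 0")
        if self.direction == "gain" and self.amplitude_mean <= 0:
            raise ValueError("gain requires amplitude_mean > 0")
        if self.direction == "loss" and self.amplitude_mean >= 0:
            raise ValueError("loss requires amplitude_mean < 0")

    @staticmethod
    def whole_chrom(chrom: str, length: int, direction: str, frequency: float,
                    amplitude_mean: float, amplitude_sd: float = 0.0) -> "CNASpec":
        return CNASpec(chrom, 0, length, direction, frequency,
                       amplitude_mean, amplitude_sd, whole_chromosome=True)


@dataclass(frozen=True)
class GroupSpec:
    """A simulated tumor group: size, noise level, events, tumor-type mix."""

    label: str
    n_samples: int
    noise_sd: float
    cnas: tuple[CNASpec, ...] = ()
    tumor_type_mix: tuple[tuple[str, float], ...] = (("unknown", 1.0),)

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("a group needs n_samples >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        object.__setattr__(self, "cnas", tuple(self.cnas))
        mix = tuple(self.tumor_type_mix)
        total = sum(f for _, f in mix)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"tumor_type_mix fractions must sum to 1, got {total}")
        object.__setattr__(self, "tumor_type_mix", mix)


@dataclass(frozen=True)
class SyntenyBlockSpec:
    """A run of ortholog pairs contiguous in both species.

    Genes are laid out head-to-tail (``gene_length`` bp each, ``gene_gap``
    between) from ``start_A``/``start_B``. When ``inverted`` the species-B
    gene order is reversed and strands flipped.
    """

    chrom_A: str
    start_A: int
    chrom_B: str
    start_B: int
    n_genes: int
    inverted: bool = False
    gene_length: int = 50_000
    gene_gap: int = 150_000

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("a synteny block needs n_genes >= 1")
        if self.gene_length <= 0 or self.gene_gap < 0:
            raise ValueError("gene_length must be > 0 and gene_gap >= 0")

    @property
    def span(self) -> int:
        return self.n_genes * self.gene_length + (self.n_genes - 1) * self.gene_gap


def build_probe_map(genome: GenomeSpec, n_probes: int, seed: int) -> ProbeMap:
    """Place probes uniformly at random, proportionally to chromosome length.

    Each chromosome receives at least one probe; remaining probes go by
    largest-remainder apportionment on length. Positions are uniform random
    integers, unique and sorted within each chromosome.
    """
    n_chroms = len(genome.chromosomes)
    if n_probes < n_chroms:
        raise ValueError(
            f"cannot place {n_probes} probes on {n_chroms} chromosomes (need >= 1 each)")
    lengths = np.array([l for _, l in genome.chromosomes], dtype=float)
    quota = n_probes * lengths / lengths.sum()
    counts = np.maximum(np.floor(quota).astype(int), 1)
    # largest-remainder top-up / trim to hit n_probes exactly
    while counts.sum() < n_probes:
        counts[np.argmax(quota - counts)] += 1
    while counts.sum() > n_probes:
        over = np.where(counts > 1, counts - quota, -np.inf)
        counts[np.argmax(over)] -= 1

    rng = np.random.default_rng(seed)
    rows = []
    for (chrom, length), k in zip(genome.chromosomes, counts):
        pos = np.unique(rng.integers(0, length, size=int(k)))
        while len(pos) < k:  # rare collision top-up
            extra = rng.integers(0, length, size=int(k - len(pos)))
            pos = np.unique(np.concatenate([pos, extra]))
        rows.append(pd.DataFrame({
            "probe_id": [f"{genome.species}_chr{chrom}_p{i:04d}" for i in range(int(k))],
            "chrom": chrom,
            "mid_bp": np.sort(pos),
        }))
    table = pd.concat(rows, ignore_index=True)
    return ProbeMap(table, chrom_lengths=genome.lengths)


def simulate_group(probe_map: ProbeMap, spec: GroupSpec, seed: int) -> ACGHGroup:
    """Simulate one cohort on *probe_map*; ground truth lands in ``.events``.

    Each sample independently carries each CNA with probability
    ``frequency``; carried events add one Normal(amplitude_mean,
    amplitude_sd) draw to every probe in the event interval. Independent
    Normal(0, noise_sd) noise is added per probe per sample. A CNA interval
    containing no probes triggers a warning but its carrier events are still
    recorded in the ground-truth log.
    """
    chroms = set(probe_map.chroms)
    for cna in spec.cnas:
        if cna.chrom not in chroms:
            raise ValueError(f"CNA chromosome {cna.chrom!r} not in probe map")

    rng = np.random.default_rng(seed)
    n = spec.n_samples
    p = probe_map.n_probes
    sample_ids = [f"{spec.label}_s{i:03d}" for i in range(n)]
    mat = np.zeros((n, p))
    chrom_arr = probe_map.table["chrom"].to_numpy()
    pos_arr = probe_map.table["mid_bp"].to_numpy()

    events = []
    for cna in spec.cnas:
        if cna.whole_chromosome:
            start, end = 0, probe_map.chrom_extent(cna.chrom) + 1
        else:
            start, end = cna.start, cna.end
        in_event = (chrom_arr == cna.chrom) & (pos_arr >= start) & (pos_arr < end)
        carriers = rng.random(n) < cna.frequency
        amps = rng.normal(cna.amplitude_mean, cna.amplitude_sd, size=int(carriers.sum()))
        if not in_event.any():
            warnings.warn(
                f"CNA {cna.chrom}:{start}-{end} contains no probes; "
                "events recorded but invisible in the data", stacklevel=2)
        for s_idx, amp in zip(np.flatnonzero(carriers), amps):
            mat[s_idx, in_event] += amp
            events.append({"sample_id": sample_ids[s_idx], "chrom": cna.chrom,
                           "start": start, "end": end, "direction": cna.direction,
                           "amplitude": amp})

    if spec.noise_sd > 0:
        mat += rng.normal(0.0, spec.noise_sd, size=(n, p))

    labels, fracs = zip(*spec.tumor_type_mix)
    types = rng.choice(len(labels), size=n, p=np.asarray(fracs))
    samples = pd.DataFrame({
        "group": spec.label,
        "tumor_type": [labels[t] for t in types],
    }, index=pd.Index(sample_ids, name="sample_id"))
    values = pd.DataFrame(mat, index=samples.index, columns=probe_map.table["probe_id"])
    event_log = pd.DataFrame(events, columns=EVENT_COLUMNS)
    return ACGHGroup(probe_map, values, samples, events=event_log)


def merge_groups(groups: list[ACGHGroup]) -> ACGHGroup:
    """Stack cohorts that share one probe map into a single annotated cohort."""
    first = groups[0]
    for g in groups[1:]:
        if not g.probes.table.equals(first.probes.table):
            raise ValueError("groups do not share one probe map")
    values = pd.concat([g.values for g in groups])
    samples = pd.concat([g.samples for g in groups])
    ev = [g.events for g in groups if g.events is not None and len(g.events)]
    events = pd.concat(ev, ignore_index=True) if ev else pd.DataFrame(columns=EVENT_COLUMNS)
    return ACGHGroup(first.probes, values, samples, events=events)


def build_ortholog_table(genome_A: GenomeSpec, genome_B: GenomeSpec,
                         blocks: list[SyntenyBlockSpec], seed: int = 0) -> OrthologTable:
    """Emit ortholog pairs from explicit synteny blocks.

    Within a block, species-A genes are laid out left to right; species-B
    genes occupy the mirrored layout in reverse order with flipped strand
    when the block is inverted. Genes may not overlap within one species.
    The layout is deterministic; *seed* is accepted for interface symmetry.
    """
    del seed  # layout is fully determined by the block specs
    rows = []
    for b_idx, blk in enumerate(blocks):
        if blk.chrom_A not in genome_A:
            raise ValueError(f"block {b_idx}: chromosome {blk.chrom_A!r} not in {genome_A.species}")
        if blk.chrom_B not in genome_B:
            raise ValueError(f"block {b_idx}: chromosome {blk.chrom_B!r} not in {genome_B.species}")
        if blk.start_A + blk.span > genome_A.lengths[blk.chrom_A]:
            raise ValueError(f"block {b_idx} does not fit in species A chromosome {blk.chrom_A}")
        if blk.start_B + blk.span > genome_B.lengths[blk.chrom_B]:
            raise ValueError(f"block {b_idx} does not fit in species B chromosome {blk.chrom_B}")
        step = blk.gene_length + blk.gene_gap
        for g in range(blk.n_genes):
            start_a = blk.start_A + g * step
            rank_b = blk.n_genes - 1 - g if blk.inverted else g
            start_b = blk.start_B + rank_b * step
            rows.append({
                "pair_id": f"blk{b_idx}_pair{g}",
                "geneA_id": f"{genome_A.species}_blk{b_idx}_g{g}",
                "chromA": blk.chrom_A,
                "startA": start_a,
                "endA": start_a + blk.gene_length,
                "strandA": "+",
                "geneB_id": f"{genome_B.species}_blk{b_idx}_g{g}",
                "chromB": blk.chrom_B,
                "startB": start_b,
                "endB": start_b + blk.gene_length,
                "strandB": "-" if blk.inverted else "+",
            })
    df = pd.DataFrame(rows)
    for side in "AB":
        sub = df[[f"chrom{side}", f"start{side}", f"end{side}"]].sort_values(
            [f"chrom{side}", f"start{side}"])
        same_chrom = sub[f"chrom{side}"].to_numpy()[1:] == sub[f"chrom{side}"].to_numpy()[:-1]
        overlap = sub[f"start{side}"].to_numpy()[1:] < sub[f"end{side}"].to_numpy()[:-1]
        if np.any(same_chrom & overlap):
            raise ValueError(f"overlapping genes within species {side}")
    return OrthologTable(df)


def write_events(events: pd.DataFrame, path) -> None:
    """Write the simulator's ground-truth event log as TSV."""
    events.to_csv(path, sep="\t", index=False)
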