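# Methods

## Model and assumptions

`crosscna` treats an aCGH cohort as a samples × probes matrix of log2
tumor/reference ratios, each probe reduced to a single genomic midposition.
Recurrence within a group is estimated non-parametrically: no segmentation
of individual profiles, no per-probe error model — upstream normalization
(dye-swap combination, median centering) is assumed done. The smoothing
view deliberately trades base-pair precision for robustness at the
multi-megabase scale where BAC arrays are informative.

### Within-group recurrence (KSE + max-peak null)

Per probe *p*, the aggregate H(p) is the sum over samples of the positive
parts (gains), negative parts (losses) or raw values (combined) of its
log2 ratios; missing cells contribute zero. The kernel smoothed estimate at
grid position *x* on chromosome *c* is the truncated-Gaussian convolution

KSE(x) = Σ over probes *p* on *c* with |x − x\_p| ≤ R of
exp(−(x − x\_p)²/2σ²) · H(p).

Kernels never cross chromosome boundaries. The gains curve is ≥ 0
everywhere, the losses curve ≤ 0, and combined = gains + losses exactly
(positive and negative parts sum to the raw value) — both enforced by
tests.

Significance: the H(p) values are permuted uniformly across all probe
positions genome-wide (destroying spatial clustering while preserving the
aggregate distribution), the KSE recomputed, and the genome-wide maximum
|KSE| recorded per permutation. The threshold is the k-th largest null
maximum with k = ⌊α·n\_perm⌋ + 1 — a conservative empirical (1 − α)
quantile. Because the null statistic is a genome-wide maximum, calling any
region whose curve crosses the threshold is a familywise test: on pure
noise, ≈ α of datasets produce any call per sign (measured 0.05 on 200 null
cohorts at α = 0.05). Regions are maximal grid runs beyond the threshold;
bounds are placed by linear interpolation between the bounding grid points;
a run touching a chromosome end keeps the endpoint. Peaks are interior grid
points strictly exceeding both neighbors (strictly below, for losses);
plateaus report their leftmost point. An event wider than the kernel
produces a broad-topped curve carrying several local peaks — all are
reported, since any of them may mark a driver locus inside the larger
aberration.

### Differential recurrence (SNR + permutation FDR)

Each sample gets its own combined-sign KSE curve on the shared grid. Groups
A and B are contrasted per position by SNR(x) = (mean\_A − mean\_B)/(sd\_A +
sd\_B) with sample (n−1) standard deviations and 0/0 defined as 0. The SNR
was chosen over a t statistic to match field convention for group
comparisons of genomic profiles; the definition is isolated in one function
so a pooled-σ or t-like variant can be swapped in.

Cutoffs per tail come from class-label permutations: labels are permuted
across the pooled samples (exhaustively when the number of distinct
assignments is ≤ n\_perm, otherwise by independent random draws), the SNR
recomputed, and for candidate cutoff c ≥ 0

FDR⁺(c) = mean over permutations of #{x : SNR\_perm(x) ≥ c} / max(1, #{x :
SNR\_obs(x) ≥ c}),

with the positive cutoff the smallest observed SNR value achieving FDR⁺ ≤
q (negative tail mirrored). Candidates are restricted to observed SNR
values because the empirical FDR curve is a step function changing only
there. Permuted SNRs are pooled across positions; the FDR is one-tailed per
direction. Defaults: n\_perm = 6,000, q = 0.05.

### Per-sample curve scale

Group-level curves are plain kernel-weighted sums — their scale cancels in
the permutation threshold. Per-sample curves default to density-normalized
(Nadaraya-Watson) smoothing: the kernel sum at each grid point is divided
by the local kernel mass, leaving values on the log2-ratio scale. This is
what makes fixed thresholds on individual smoothed profiles (the
conventional 0.15 cutoff, sweep grids of 0.02–0.8) interpretable: a plain
sum runs an order of magnitude higher and a fixed small threshold would
mostly count noise crossings. The comparative SNR is invariant to any
per-position scaling (numerator and denominator scale identically), so this
choice affects only the instability sweep; both behaviors are available via
the `normalized` flag on `group_kse` and `sample_kse_matrix`.

### Instability metrics

Aberrant fraction: probes strictly beyond ±cutoff over non-missing probes,
gains and losses separately. The default cutoff is platform configuration:
0.3 for mouse BAC arrays, 0.2 for the human platform whose ratios compress
toward zero. CNA counts: per sample and threshold t, the number of maximal
grid runs with KSE > t plus runs with KSE < −t (runs reset at chromosome
boundaries); a peak-counting mode (local extrema beyond the threshold) is
available since run counts and peak counts are both defensible readings of
"number of CNAs". Group contrasts use Welch's unequal-variance two-tailed
t-test with Welch–Satterthwaite degrees of freedom (scipy); degenerate
zero-variance inputs are handled explicitly (equal means → p = 1, unequal
→ p = 0 with a warning). Tumor typing from expression: Mesenchymal if
Vimentin exceeds E-cadherin by more than 0.5 on the log scale, Epithelial
for the reverse, Ambiguous otherwise — a difference of exactly 0.5 is
Ambiguous, since only strict inequalities are defined.

### Cross-species mapping

Genes are assigned to every called region their [start, end) interval
overlaps by ≥ 1 bp. An ortholog pair is conserved when both genes sit in
regions of identical direction (gain↔gain, loss↔loss; for differential
regions, identical contrast labels). Conserved pairs sharing one
(region\_A, region\_B) combination cluster into a syntenic overlap whose
bounds run from the first gene's start to the last gene's end in each
species; counts cover distinct genes per species and distinct pairs. The
inversion flag is the sign of the Spearman rank correlation between the two
species' gene-start orders — +1 preserved, −1 reversed, undefined when a
species contributes one gene, ties reported as +1 with a warning. A region
spanning several synteny blocks of the partner genome therefore splits into
one overlap per region pair. Overlaps supported by a single ortholog pair
are kept in full output and flagged for abbreviated tables.

## Synthetic data

The generator emulates BAC-array cohorts: probes placed uniformly at
random, apportioned to chromosomes by length (largest remainder, ≥ 1 per
chromosome) — uniform placement is irregular enough to exercise the
density sensitivity of the KSE without modeling real BAC layouts. Each
sample carries each planted CNA independently with its frequency; a
carrier's probes in the event interval shift by one
Normal(amplitude\_mean, amplitude\_sd) draw — constant across the event,
matching segment-level biology and keeping ground truth crisp. Whole-
chromosome events are intervals spanning the chromosome with identical
frequency semantics. Independent Normal(0, noise\_sd) noise is added per
cell; tumor types are drawn from the group's mix. Draws come from
`numpy.random.default_rng(seed)` in a fixed order (per CNA: carriers then
amplitudes; then the noise matrix; then tumor types) so seeds are portable.
Carriers are logged exactly (sample, interval, direction, amplitude).
Ortholog tables come from explicit synteny blocks — head-to-tail gene
layouts, mirrored and strand-flipped when inverted.

Not emulated: dye-swap/duplicate-spot structure, GC/wave artifacts,
segment-level amplitude gradients, allele-specific copy number, and real
BAC spacing. Passing tests therefore demonstrate the statistics behave as
designed under clean mixture-of-segments data, not that the pipeline is
robust to platform artifacts real cohorts carry.

## Parameters

| parameter | default | meaning |
|---|---|---|
| kernel\_width | 20 Mb | smoothing scale; σ = width/4 so ±2σ spans it |
| truncation\_radius | = kernel\_width | kernel support cut; ≥ 2σ required |
| grid\_step | kernel\_width/200 (100 kb) | evaluation lattice; probe positions merged in |
| α | 0.05 | familywise level of the max-peak threshold |
| n\_perm (within-group) | 1,000 | position permutations |
| n\_perm (comparative) | 6,000 | class-label permutations |
| q | 0.05 | per-tail FDR level |
| aberrant-fraction cutoff | 0.3 / 0.2 | mouse / human platform config |
| sweep grid | 0.02–0.8 step 0.02 | thresholds for CNA counting |

The "kernel width" ↔ σ convention is stated rather than assumed: width =
4σ here, with σ, truncation and grid all overridable to match other
conventions exactly.

## Numerical choices

Coordinates are 0-based half-open everywhere, including emitted TSVs and
BED. Probes are sorted by natural chromosome order then position; duplicate
probe ids and inverted gene coordinates are hard errors, unparseable ratio
cells become missing values excluded from kernel sums and fraction
denominators (never imputed). The optimized convolution (per-chromosome
truncated weight matrices reused across permutations and samples) agrees
with a brute-force double loop to < 1e−9 on randomized datasets (measured
~2e−15). All-zero aggregates give a degenerate threshold of 0 with a
warning; scaling a curve by such a threshold is an error. Single grid
points exactly at a cutoff become zero-width-plus-ulp regions rather than
invalid intervals. FDR tail counts accumulate in permutation chunks via
binary search, bounding memory at the paper-scale 6,000 permutations.

## Simulation study conditions

The calibration batteries use a genome of 8 × 125 Mb chromosomes with
1,000 probes (≈ 0.8 probes/Mb, the order of a 3,080-probe BAC array on a
mammalian genome), 30 samples per group, log2 noise sd 0.2, a 20 Mb kernel
on a 500 kb grid, and: 200 null datasets × 200 permutations for the
familywise error; 100 runs for gain recovery (frequency 0.6, amplitude
0.8, 30 Mb event; success = overlapping called region with a local KSE
peak within 10 Mb of the event center); 100 runs × 500 class-label
permutations each for comparative sensitivity (frequency 0.7 in one group)
and shared-aberration suppression (equal frequency in both); 10 noise-free
runs for exact cross-species recovery of a plain and an inverted planted
block; 2,000 draws for Welch type-I calibration. These sizes make the whole
battery run in about a minute while leaving the binomial noise on each
rate well inside its acceptance band.

## Known limitations

Sensitivity is tuned to the kernel scale: events much narrower than σ are
attenuated, and nearby events merge. The max-peak null controls familywise
error per sign, not jointly over gains and losses. The permutation null
assumes exchangeable probe aggregates, which breaks if spatial artifacts
(waves) survive normalization. The comparative FDR pools permuted SNRs
across positions, so strong heteroscedasticity across the genome makes it
conservative near high-variance loci. Cross-species conclusions inherit
the ortholog table's quality; many-to-many homologies are counted as
distinct pairs, not weighted.
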