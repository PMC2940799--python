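"""Kernel-smoothed detection of recurrent gains and losses in aCGH cohorts.

For a tumor group, each probe gets an aggregate height H(p): the sum over
samples of the positive parts (gains), negative parts (losses), or raw
values (combined) of its log2 ratios. A Gaussian kernel of bandwidth sigma
is placed at each probe midposition with that height, and the kernel
smoothed estimate (KSE) at a grid point x on chromosome c is

    KSE(x) = sum over probes p on c, |x - pos(p)| <= R,
             of exp(-(x - pos(p))^2 / (2 sigma^2)) * H(p)

with truncation radius R. Kernels never cross chromosome boundaries.

Genome-wide significance uses a max-peak permutation null: the aggregates
H(p) are shuffled uniformly across all probe positions, the KSE recomputed,
and the genome-wide maximum recorded; the threshold is the empirical
(1 - alpha) quantile of those maxima, so calling any region whose curve
crosses it controls the familywise error rate at about alpha per sign.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ACGHGroup, ProbeMap
from .regions import Peak, Region

log = logging.getLogger(__name__)

SIGNS = ("gains", "losses", "combined")


@dataclass(frozen=True)
class KSEParams:
    """Kernel and grid settings.

    The headline parameter is ``kernel_width`` (default 20 Mb, the scale at
    which BAC-array noise smooths away while multi-megabase CNAs survive).
    Convention: ``sigma = kernel_width / 4`` so +-2 sigma spans the stated
    width, and ``truncation_radius = kernel_width``. The evaluation grid is
    a regular ``grid_step`` lattice per chromosome (default
    ``kernel_width / 200`` = 100 kb at 20 Mb) with probe midpositions merged
    in. All three can be overridden to match other conventions.
    """

    kernel_width: float = 20e6
    sigma: float | None = None
    truncation_radius: float | None = None
    grid_step: float | None = None

    def __post_init__(self) -> None:
        if self.kernel_width <= 0:
            raise ValueError("kernel_width must be > 0")
        if self.resolved_sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.resolved_truncation < 2 * self.resolved_sigma:
            raise ValueError("truncation_radius must be >= 2 * sigma")
        if self.resolved_grid_step <= 0:
            raise ValueError("grid_step must be > 0")

    @property
    def resolved_sigma(self) -> float:
        return self.kernel_width / 4 if self.sigma is None else self.sigma

    @property
    def resolved_truncation(self) -> float:
        return self.kernel_width if self.truncation_radius is None else self.truncation_radius

    @property
    def resolved_grid_step(self) -> float:
        return self.kernel_width / 200 if self.grid_step is None else self.grid_step


@dataclass
class KSECurve:
    """Per-chromosome evaluation grid and smoothed values, with a sign tag."""

    sign: str
    chroms: list[str]
    grid: dict[str, np.ndarray]
    values: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.sign not in SIGNS:
            raise ValueError(f"sign must be one of {SIGNS}")

    def to_frame(self) -> pd.DataFrame:
        parts = [pd.DataFrame({"chrom": c, "pos": self.grid[c], "kse": self.values[c]})
                 for c in self.chroms]
        return pd.concat(parts, ignore_index=True)

    def max_abs(self) -> float:
        return max((float(np.max(np.abs(self.values[c]))) for c in self.chroms), default=0.0)


@dataclass(frozen=True)
class Threshold:
    """Empirical (1 - alpha) quantile of genome-wide null maxima.

    ``value`` is non-negative and is applied as ``-value`` to losses curves.
    The quantile convention is the k-th largest null maximum with
    ``k = floor(alpha * n_perm) + 1`` (conservative).
    """

    value: float
    alpha: float
    n_perm: int
    sign: str
    null_maxima: np.ndarray = field(repr=False, default_factory=lambda: np.array([]))


class KernelDesign:
    """Precomputed per-chromosome grids and truncated kernel weight matrices.

    Reused across permutations and samples: the KSE of any aggregate vector
    h is ``W_c @ h[idx_c]`` per chromosome.
    """

    def __init__(self, probe_map: ProbeMap, params: KSEParams):
        self.probe_map = probe_map
        self.params = params
        sigma = params.resolved_sigma
        radius = params.resolved_truncation
        step = params.resolved_grid_step
        self.chroms = probe_map.chroms
        self.grid: dict[str, np.ndarray] = {}
        self.weights: dict[str, np.ndarray] = {}
        self.probe_idx: dict[str, np.ndarray] = {}
        self.weight_sums: dict[str, np.ndarray] = {}
        for chrom in self.chroms:
            pos = probe_map.positions(chrom).astype(float)
            extent = probe_map.chrom_extent(chrom)
            lattice = np.arange(0.0, extent + step / 2, step)
            grid = np.unique(np.concatenate([lattice, pos]))
            d = grid[:, None] - pos[None, :]
            w = np.exp(-(d * d) / (2.0 * sigma * sigma))
            w[np.abs(d) > radius] = 0.0
            self.grid[chrom] = grid
            self.weights[chrom] = w
            self.probe_idx[chrom] = probe_map.probe_indices(chrom)
            self.weight_sums[chrom] = w.sum(axis=1)
        self.n_grid = sum(len(g) for g in self.grid.values())

    def _scale(self, chrom: str, values: np.ndarray, normalized: bool) -> np.ndarray:
        if not normalized:
            return values
        wsum = self.weight_sums[chrom]
        safe = np.where(wsum > 0, wsum, 1.0)
        if values.ndim == 2:
            safe = safe[:, None]
        return values / safe

    def convolve(self, aggregates: np.ndarray, sign: str,
                 normalized: bool = False) -> KSECurve:
        """Smooth one genome-wide per-probe aggregate vector.

        With ``normalized`` the kernel sum at each grid point is divided by
        the total kernel mass there (Nadaraya-Watson), putting the curve on
        the scale of the aggregates instead of a probe-density-weighted sum.
        """
        values = {c: self._scale(c, self.weights[c] @ aggregates[self.probe_idx[c]],
                                 normalized)
                  for c in self.chroms}
        return KSECurve(sign, list(self.chroms), dict(self.grid), values)

    def convolve_matrix(self, aggregates: np.ndarray,
                        normalized: bool = False) -> dict[str, np.ndarray]:
        """Smooth many aggregate vectors at once.

        *aggregates* is (n_probes, n_vectors); returns per chromosome a
        (n_grid_c, n_vectors) array.
        """
        return {c: self._scale(c, self.weights[c] @ aggregates[self.probe_idx[c], :],
                               normalized)
                for c in self.chroms}


def probe_aggregates(group: ACGHGroup, sign: str) -> np.ndarray:
    """Per-probe kernel heights H(p) for one sign; NaN cells contribute 0."""
    if sign not in SIGNS:
        raise ValueError(f"sign must be one of {SIGNS}")
    mat = group.matrix
    if sign == "gains":
        mat = np.where(np.isnan(mat), 0.0, np.clip(mat, 0.0, None))
    elif sign == "losses":
        mat = np.where(np.isnan(mat), 0.0, np.clip(mat, None, 0.0))
    else:
        mat = np.nan_to_num(mat, nan=0.0)
    return mat.sum(axis=0)


def group_kse(group: ACGHGroup, sign: str, params: KSEParams,
              design: KernelDesign | None = None,
              normalized: bool = False) -> KSECurve:
    """Group-level KSE curve for gains, losses, or the combined signal.

    The default is the plain kernel-weighted sum; ``normalized`` divides by
    the local kernel mass, which removes probe-density sensitivity on
    uneven maps at the cost of leaving the summed-log2 scale.
    """
    if group.n_samples == 0:
        raise ValueError("group is empty")
    if design is None:
        design = KernelDesign(group.probes, params)
    return design.convolve(probe_aggregates(group, sign), sign, normalized=normalized)


def significance_threshold(group: ACGHGroup, sign: str, params: KSEParams,
                           n_perm: int = 1000, alpha: float = 0.05, seed: int = 0,
                           design: KernelDesign | None = None) -> Threshold:
    """Max-peak permutation threshold for one sign.

    Aggregates are shuffled across all probe positions genome-wide; each
    permutation's genome-wide maximum absolute KSE is recorded and the
    threshold is the k-th largest with ``k = floor(alpha * n_perm) + 1``.
    """
    if sign not in ("gains", "losses"):
        raise ValueError("threshold is computed for 'gains' or 'losses'")
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if design is None:
        design = KernelDesign(group.probes, params)
    h = probe_aggregates(group, sign)
    if np.all(h == 0):
        warnings.warn("all probe aggregates are zero: degenerate null, threshold 0",
                      stacklevel=2)
        return Threshold(0.0, alpha, n_perm, sign, np.zeros(n_perm))

    rng = np.random.default_rng(seed)
    n = len(h)
    perms = np.empty((n, n_perm))
    for j in range(n_perm):
        perms[:, j] = h[rng.permutation(n)]
    maxima = np.zeros(n_perm)
    for chrom, vals in design.convolve_matrix(perms).items():
        np.maximum(maxima, np.abs(vals).max(axis=0), out=maxima)
    k = int(np.floor(alpha * n_perm)) + 1
    value = float(np.sort(maxima)[::-1][k - 1])
    return Threshold(value, alpha, n_perm, sign, maxima)


def _interp_crossing(x0: float, x1: float, y0: float, y1: float, level: float) -> float:
    if y1 == y0:
        return x0
    return x0 + (level - y0) * (x1 - x0) / (y1 - y0)


def _call_runs(grid: np.ndarray, vals: np.ndarray, cutoff: float, chrom: str,
               direction: str, above: bool, group: str = "") -> list[Region]:
    """Maximal runs of grid points beyond *cutoff*, bounds linearly interpolated.

    *above* selects ``vals >= cutoff`` (gains / A>B) versus ``vals <= cutoff``
    (losses / B>A).
    """
    y = vals if above else -vals
    level = cutoff if above else -cutoff
    mask = y >= level
    if not mask.any():
        return []
    regions = []
    edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
    starts = [0] if mask[0] else []
    starts += [int(e) + 1 for e in edges if mask[e + 1]]
    ends = [int(e) for e in edges if mask[e]]
    if mask[-1]:
        ends.append(len(mask) - 1)
    for i0, i1 in zip(starts, ends):
        left = (grid[i0] if i0 == 0
                else _interp_crossing(grid[i0 - 1], grid[i0], y[i0 - 1], y[i0], level))
        right = (grid[i1] if i1 == len(grid) - 1
                 else _interp_crossing(grid[i1], grid[i1 + 1], y[i1], y[i1 + 1], level))
        if right <= left:  # single grid point exactly at the cutoff
            right = float(np.nextafter(left, np.inf))
        peak_i = i0 + int(np.argmax(y[i0:i1 + 1]))
        regions.append(Region(chrom=chrom, start=float(left), end=float(right),
                              direction=direction, peak_pos=float(grid[peak_i]),
                              peak_height=float(vals[peak_i]), group=group))
    return regions


def call_regions(curve: KSECurve, threshold: Threshold, group: str = "") -> list[Region]:
    """Contiguous stretches where the curve crosses the significance cutoff.

    Region bounds sit at the linear-interpolated crossing between the
    bounding grid points; each region carries its extreme value as the peak.
    """
    if curve.sign not in ("gains", "losses"):
        raise ValueError("call_regions needs a gains or losses curve")
    if threshold.sign != curve.sign:
        raise ValueError(f"threshold sign {threshold.sign!r} != curve sign {curve.sign!r}")
    direction = "gain" if curve.sign == "gains" else "loss"
    above = curve.sign == "gains"
    cutoff = threshold.value if above else -threshold.value
    out: list[Region] = []
    for chrom in curve.chroms:
        out.extend(_call_runs(curve.grid[chrom], curve.values[chrom], cutoff,
                              chrom, direction, above, group))
    return out


def _local_extrema(grid: np.ndarray, vals: np.ndarray, maxima: bool) -> list[tuple[float, float]]:
    """Interior strict local extrema; plateaus report their leftmost point."""
    y = vals if maxima else -vals
    n = len(y)
    out = []
    i = 1
    while i < n - 1:
        if y[i] > y[i - 1]:
            j = i
            while j < n - 1 and y[j + 1] == y[i]:
                j += 1
            # plateau from i..j; peak iff it then strictly drops (and j interior)
            if j < n - 1 and y[j + 1] < y[i]:
                out.append((float(grid[i]), float(vals[i])))
            i = j + 1
        else:
            i += 1
    return out


def find_peaks(curve: KSECurve) -> list[Peak]:
    """Grid points strictly exceeding both neighbors (gains) or strictly
    below both (losses); a combined curve reports both kinds.

    Chromosome endpoints are excluded; plateaus report their leftmost point.
    Requires at least three grid points per chromosome.
    """
    peaks: list[Peak] = []
    for chrom in curve.chroms:
        grid, vals = curve.grid[chrom], curve.values[chrom]
        if len(grid) < 3:
            raise ValueError(f"chromosome {chrom} has fewer than 3 grid points")
        if curve.sign in ("gains", "combined"):
            peaks.extend(Peak(chrom, p, h) for p, h in _local_extrema(grid, vals, True))
        if curve.sign in ("losses", "combined"):
            peaks.extend(Peak(chrom, p, h) for p, h in _local_extrema(grid, vals, False))
    return peaks


def scale_curve(curve: KSECurve, threshold: Threshold) -> KSECurve:
    """Divide the curve by the threshold so the cutoff sits at +-1."""
    if threshold.value == 0:
        raise ValueError("cannot scale by a zero (degenerate) threshold")
    values = {c: curve.values[c] / threshold.value for c in curve.chroms}
    return KSECurve(curve.sign, list(curve.chroms), dict(curve.grid), values)
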