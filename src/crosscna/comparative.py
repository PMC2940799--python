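"""Differential recurrence between two tumor groups (comparative analysis).

Each sample gets its own combined-sign KSE curve (gains and losses not
separated). At every grid position the two groups are contrasted with a
signal-to-noise ratio

    SNR(x) = (mean_A(x) - mean_B(x)) / (sd_A(x) + sd_B(x)),

sample (n-1) standard deviations, 0/0 defined as 0. Significance cutoffs
per tail come from a class-label permutation FDR: group labels are permuted
across the pooled samples, the SNR recomputed, and for a candidate cutoff c

    FDR+(c) = mean over permutations of #{x : SNR_perm(x) >= c}
              / max(1, #{x : SNR_obs(x) >= c}),

the positive cutoff being the smallest observed SNR value with FDR+ <= q
(negative tail analogous). When the number of distinct label assignments is
at most n_perm the enumeration is exhaustive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .io import ACGHGroup
from .kcsmart import KernelDesign, KSECurve, KSEParams
from .regions import Region
from .kcsmart import _call_runs

log = logging.getLogger(__name__)


@dataclass
class SampleKSEMatrix:
    """Per-sample combined KSE curves on one shared evaluation grid.

    ``values`` is (n_samples, n_grid) over the concatenated per-chromosome
    grids; ``grid`` maps chromosome -> positions and ``offsets`` maps
    chromosome -> slice into the concatenated axis.
    """

    chroms: list[str]
    grid: dict[str, np.ndarray]
    offsets: dict[str, slice]
    values: np.ndarray
    sample_ids: list[str]
    groups: pd.Series

    @property
    def n_grid(self) -> int:
        return self.values.shape[1]

    def sample_curve(self, sample_id: str) -> KSECurve:
        i = self.sample_ids.index(sample_id)
        vals = {c: self.values[i, self.offsets[c]] for c in self.chroms}
        return KSECurve("combined", list(self.chroms), dict(self.grid), vals)

    def group_indices(self, label: str) -> np.ndarray:
        return np.flatnonzero((self.groups == label).to_numpy())


@dataclass(frozen=True)
class SNRCurve:
    """Per-position SNR for an ordered group pair (A, B); antisymmetric in swap."""

    chroms: list[str]
    grid: dict[str, np.ndarray]
    offsets: dict[str, slice]
    values: np.ndarray
    pair: tuple[str, str]

    def to_frame(self) -> pd.DataFrame:
        parts = [pd.DataFrame({"chrom": c, "pos": self.grid[c],
                               "snr": self.values[self.offsets[c]]})
                 for c in self.chroms]
        return pd.concat(parts, ignore_index=True)


@dataclass(frozen=True)
class FDRCutoffs:
    """Per-tail SNR cutoffs at FDR level q.

    ``positive`` bounds A>B calls and ``negative`` (stored as a magnitude)
    bounds B>A calls; either is None when no cutoff reaches the target FDR
    ("no significant positions" for that tail). ``exhaustive`` marks exact
    enumeration of all label assignments.
    """

    positive: float | None
    negative: float | None
    q: float
    n_perm: int
    exhaustive: bool
    pair: tuple[str, str]
    fdr_at_positive: float | None = None
    fdr_at_negative: float | None = None


def sample_kse_matrix(groups: list[ACGHGroup] | ACGHGroup, params: KSEParams,
                      design: KernelDesign | None = None,
                      normalized: bool = True) -> SampleKSEMatrix:
    """One combined-sign KSE row per sample across all given cohorts.

    Per-sample curves default to density-normalized smoothing so their
    values stay on the log2-ratio scale: instability sweep thresholds (e.g.
    the conventional 0.15) are then directly interpretable, and the SNR of
    the comparative analysis is unchanged because a per-position scaling
    cancels between its numerator and denominator.
    """
    if isinstance(groups, ACGHGroup):
        groups = [groups]
    first = groups[0]
    for g in groups[1:]:
        if not g.probes.table.equals(first.probes.table):
            raise ValueError("groups do not share one probe map")
    if design is None:
        design = KernelDesign(first.probes, params)

    mats, ids, labels = [], [], []
    for g in groups:
        mats.append(np.nan_to_num(g.matrix, nan=0.0))
        ids.extend(g.sample_ids)
        labels.extend(g.samples["group"].tolist())
    X = np.vstack(mats)  # samples x probes
    per_chrom = design.convolve_matrix(X.T, normalized=normalized)
    offsets, pieces, at = {}, [], 0
    for c in design.chroms:
        vals = per_chrom[c].T
        offsets[c] = slice(at, at + vals.shape[1])
        at += vals.shape[1]
        pieces.append(vals)
    values = np.concatenate(pieces, axis=1)
    return SampleKSEMatrix(list(design.chroms), dict(design.grid), offsets, values,
                           ids, pd.Series(labels, index=ids))


def _zero_den_rule(num: np.ndarray) -> np.ndarray:
    """0/0 -> 0; nonzero/0 -> signed inf."""
    return np.where(num > 0, np.inf, np.where(num < 0, -np.inf, 0.0))


def _snr(values: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray) -> np.ndarray:
    a, b = values[idx_a], values[idx_b]
    num = a.mean(axis=0) - b.mean(axis=0)
    den = a.std(axis=0, ddof=1) + b.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = num / den
    zero = den == 0
    snr[zero] = _zero_den_rule(num[zero])
    return snr


def snr_curve(matrix: SampleKSEMatrix, label_a: str, label_b: str) -> SNRCurve:
    """Observed SNR(x) for the ordered pair (label_a, label_b)."""
    idx_a = matrix.group_indices(label_a)
    idx_b = matrix.group_indices(label_b)
    for label, idx in ((label_a, idx_a), (label_b, idx_b)):
        if len(idx) < 2:
            raise ValueError(f"group {label!r} needs >= 2 samples (sd undefined)")
    return SNRCurve(list(matrix.chroms), dict(matrix.grid), dict(matrix.offsets),
                    _snr(matrix.values, idx_a, idx_b), (label_a, label_b))


def _assignment_matrix(n_pool: int, n_a: int, n_perm: int,
                       seed: int) -> tuple[np.ndarray, bool]:
    """0/1 matrix (n_draws, n_pool) of which pooled samples play group A."""
    n_distinct = comb(n_pool, n_a)
    if n_distinct <= n_perm:
        G = np.zeros((n_distinct, n_pool))
        for i, idx in enumerate(combinations(range(n_pool), n_a)):
            G[i, list(idx)] = 1.0
        return G, True
    rng = np.random.default_rng(seed)
    G = np.zeros((n_perm, n_pool))
    for i in range(n_perm):
        G[i, rng.permutation(n_pool)[:n_a]] = 1.0
    return G, False


def _permuted_tail_counts(X: np.ndarray, G: np.ndarray, candidates_pos: np.ndarray,
                          candidates_neg: np.ndarray, chunk: int = 200
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Total exceedance counts of permuted SNR values beyond each candidate.

    For every chunk of label assignments the full permuted SNR matrix is
    formed via group-sum matmuls, then tail counts accumulate by binary
    search; memory stays bounded by the chunk size.
    """
    n_pool = X.shape[0]
    n_a = int(G[0].sum())
    n_b = n_pool - n_a
    X2 = X * X
    pos_counts = np.zeros(len(candidates_pos))
    neg_counts = np.zeros(len(candidates_neg))
    for lo in range(0, G.shape[0], chunk):
        g = G[lo:lo + chunk]
        sum_a = g @ X
        ssq_a = g @ X2
        sum_b = (1.0 - g) @ X
        ssq_b = (1.0 - g) @ X2
        mu_a, mu_b = sum_a / n_a, sum_b / n_b
        var_a = np.clip((ssq_a - n_a * mu_a ** 2) / (n_a - 1), 0.0, None)
        var_b = np.clip((ssq_b - n_b * mu_b ** 2) / (n_b - 1), 0.0, None)
        num = mu_a - mu_b
        den = np.sqrt(var_a) + np.sqrt(var_b)
        with np.errstate(divide="ignore", invalid="ignore"):
            snr = num / den
        zero = den == 0
        snr[zero] = _zero_den_rule(num[zero])
        flat = np.sort(snr.ravel())
        if len(candidates_pos):
            pos_counts += len(flat) - np.searchsorted(flat, candidates_pos, side="left")
        if len(candidates_neg):
            neg_counts += np.searchsorted(flat, -candidates_neg, side="right")
    return pos_counts, neg_counts


def snr_fdr_cutoffs(matrix: SampleKSEMatrix, label_a: str, label_b: str,
                    n_perm: int = 6000, q: float = 0.05, seed: int = 0) -> FDRCutoffs:
    """Class-label permutation FDR cutoffs for both tails of the SNR curve.

    Candidate cutoffs are the observed SNR values themselves (the empirical
    FDR curve is a step function changing only there). Enumeration is
    exhaustive when the number of distinct assignments is <= n_perm.
    """
    if label_a == label_b:
        raise ValueError("labels must differ")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 (or small enough for exhaustive enumeration)")
    idx_a = matrix.group_indices(label_a)
    idx_b = matrix.group_indices(label_b)
    for label, idx in ((label_a, idx_a), (label_b, idx_b)):
        if len(idx) < 2:
            raise ValueError(f"group {label!r} needs >= 2 samples")
    pool = np.concatenate([idx_a, idx_b])
    X = matrix.values[pool]
    obs = _snr(matrix.values, idx_a, idx_b)

    cand_pos = np.unique(obs[(obs > 0) & np.isfinite(obs)])
    cand_neg = np.unique(-obs[(obs < 0) & np.isfinite(obs)])  # magnitudes, ascending
    G, exhaustive = _assignment_matrix(len(pool), len(idx_a), n_perm, seed)
    n_draws = G.shape[0]
    pos_tail, neg_tail = _permuted_tail_counts(X, G, cand_pos, cand_neg)

    obs_sorted = np.sort(obs[np.isfinite(obs)])

    def pick(candidates: np.ndarray, tail_counts: np.ndarray,
             positive: bool) -> tuple[float | None, float | None]:
        for c, total in zip(candidates, tail_counts):
            if positive:
                n_obs = len(obs_sorted) - np.searchsorted(obs_sorted, c, side="left")
            else:
                n_obs = np.searchsorted(obs_sorted, -c, side="right")
            fdr = (total / n_draws) / max(1, n_obs)
            if fdr <= q:
                return float(c), float(fdr)
        return None, None

    pos_cut, pos_fdr = pick(cand_pos, pos_tail, True)
    neg_cut, neg_fdr = pick(cand_neg, neg_tail, False)
    if pos_cut is None and neg_cut is None:
        log.info("snr_fdr_cutoffs(%s vs %s): no significant positions at q=%g",
                 label_a, label_b, q)
    return FDRCutoffs(pos_cut, neg_cut, q, n_draws, exhaustive, (label_a, label_b),
                      pos_fdr, neg_fdr)


def differential_regions(snr: SNRCurve, cutoffs: FDRCutoffs,
                         group: str = "") -> list[Region]:
    """Runs of SNR beyond the FDR cutoffs, labeled "A>B" / "B>A".

    Bounds are linearly interpolated exactly as in within-group region
    calling.
    """
    if cutoffs.pair != snr.pair:
        raise ValueError(f"cutoffs pair {cutoffs.pair} != SNR pair {snr.pair}")
    a, b = snr.pair
    out: list[Region] = []
    for chrom in snr.chroms:
        grid = snr.grid[chrom]
        vals = snr.values[snr.offsets[chrom]]
        if cutoffs.positive is not None:
            out.extend(_call_runs(grid, vals, cutoffs.positive, chrom,
                                  f"{a}>{b}", True, group))
        if cutoffs.negative is not None:
            out.extend(_call_runs(grid, vals, -cutoffs.negative, chrom,
                                  f"{b}>{a}", False, group))
    return out
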