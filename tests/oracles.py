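"""Independent brute-force oracles used to validate the optimized paths.

Everything here is deliberately naive (explicit Python loops, textbook
formulas, exhaustive enumeration) and shares no code with the library
implementations it checks.
"""

from __future__ import annotations

import math
import statistics
from itertools import combinations

import numpy as np


def brute_kse_values(positions, aggregates, grid, sigma, radius):
    """Double-loop truncated-Gaussian convolution for one chromosome."""
    out = []
    for x in grid:
        s = 0.0
        for p, h in zip(positions, aggregates):
            d = x - p
            if abs(d) <= radius:
                s += math.exp(-(d * d) / (2.0 * sigma * sigma)) * h
        out.append(s)
    return np.array(out)


def scan_runs(grid, vals, cutoff, above=True):
    """Run-scanner over grid points: maximal index runs beyond the cutoff,
    with linearly interpolated bounds and the extreme point as peak."""
    keep = [(v >= cutoff) if above else (v <= cutoff) for v in vals]
    runs = []
    i = 0
    n = len(grid)
    while i < n:
        if keep[i]:
            j = i
            while j + 1 < n and keep[j + 1]:
                j += 1
            if i == 0:
                left = grid[0]
            else:
                x0, x1, y0, y1 = grid[i - 1], grid[i], vals[i - 1], vals[i]
                left = x0 + (cutoff - y0) * (x1 - x0) / (y1 - y0)
            if j == n - 1:
                right = grid[n - 1]
            else:
                x0, x1, y0, y1 = grid[j], grid[j + 1], vals[j], vals[j + 1]
                right = x0 + (cutoff - y0) * (x1 - x0) / (y1 - y0)
            seg = vals[i:j + 1]
            k = int(np.argmax(seg)) if above else int(np.argmin(seg))
            runs.append({"start": left, "end": right,
                         "peak_pos": grid[i + k], "peak_height": vals[i + k]})
            i = j + 1
        else:
            i += 1
    return runs


def count_runs_1d(vals, threshold):
    """Gain runs (> t) plus loss runs (< -t) in one chromosome's values."""
    total = 0
    for keep in ([v > threshold for v in vals], [v < -threshold for v in vals]):
        prev = False
        for k in keep:
            if k and not prev:
                total += 1
            prev = k
    return total


def snr_1d(a, b):
    """Textbook (mean_a - mean_b) / (sd_a + sd_b) with 0/0 -> 0."""
    num = statistics.mean(a) - statistics.mean(b)
    den = statistics.stdev(a) + statistics.stdev(b)
    if den == 0:
        return 0.0 if num == 0 else math.copysign(math.inf, num)
    return num / den


def exhaustive_fdr_cutoffs(values, n_a, q):
    """Exact per-tail permutation-FDR cutoffs over all label assignments.

    *values* is the pooled (n_samples, n_positions) per-sample curve matrix
    with the first n_a rows observed as group A. Returns (positive cutoff,
    negative cutoff magnitude), either None.
    """
    n, m = values.shape
    obs = np.array([snr_1d(values[:n_a, j], values[n_a:, j]) for j in range(m)])
    perm_snrs = []
    for idx_a in combinations(range(n), n_a):
        idx_b = [i for i in range(n) if i not in idx_a]
        perm_snrs.append([snr_1d(values[list(idx_a), j], values[idx_b, j])
                          for j in range(m)])
    perm_snrs = np.array(perm_snrs)  # (n_assignments, m)
    n_draws = perm_snrs.shape[0]
    finite_obs = obs[np.isfinite(obs)]

    pos_cut = None
    for c in sorted(obs[(obs > 0) & np.isfinite(obs)]):
        n_obs = int((finite_obs >= c).sum())
        fdr = (perm_snrs >= c).sum() / n_draws / max(1, n_obs)
        if fdr <= q:
            pos_cut = c
            break
    neg_cut = None
    for c in sorted(-obs[(obs < 0) & np.isfinite(obs)]):
        n_obs = int((finite_obs <= -c).sum())
        fdr = (perm_snrs <= -c).sum() / n_draws / max(1, n_obs)
        if fdr <= q:
            neg_cut = c
            break
    return pos_cut, neg_cut


def welch_from_formula(a, b):
    """Welch statistic, df and two-tailed p from the textbook formulas."""
    from scipy.stats import t as t_dist

    na, nb = len(a), len(b)
    ma, mb = statistics.mean(a), statistics.mean(b)
    va, vb = statistics.variance(a), statistics.variance(b)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * t_dist.sf(abs(t), df)
    return t, df, p
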