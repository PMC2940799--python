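"""Per-tumor genomic-instability metrics and group contrasts.

Two complementary summaries of how damaged a genome is:

* the fraction of probes whose log2 ratio exceeds a fixed cutoff
  (strictly ``> cutoff`` for gains, ``< -cutoff`` for losses), and
* the number of smoothed aberrations per tumor across a grid of KSE
  thresholds — maximal contiguous runs of the per-sample combined KSE
  beyond +-t (a peak-counting mode is available).

Group differences use Welch's unequal-variance two-tailed t-test. Default
cutoffs are platform-specific configuration: 0.3 for the mouse BAC arrays
and 0.2 for the human arrays, whose log2 ratios run lower.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .io import ACGHGroup
from .comparative import SampleKSEMatrix

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class InstabilityResult:
    """Aberrant-probe fractions per sample, per-group mean +- SEM, and
    Welch contrasts between groups."""

    cutoff: float
    per_sample: pd.DataFrame   # sample_id, group, gain_fraction, loss_fraction
    group_summary: pd.DataFrame  # group, n, mean/sem for both fractions
    contrasts: pd.DataFrame    # group_1, group_2, metric, t, p


@dataclass(frozen=True)
class SweepResult:
    """CNA counts per sample across a threshold grid, with group contrasts.

    ``significant`` lists, per contrast, the maximal threshold intervals
    where the Welch p-value is below 0.05 (the darkened stretches of the
    instability sweep plots).
    """

    thresholds: np.ndarray
    counts: pd.DataFrame       # samples x thresholds
    groups: pd.Series
    group_means: pd.DataFrame  # groups x thresholds
    pvalues: pd.DataFrame      # contrast label x thresholds
    significant: dict[str, list[tuple[float, float]]]


def aberrant_fraction(sample_values, cutoff: float) -> tuple[float, float]:
    """(gain fraction, loss fraction) of probes strictly beyond +-cutoff.

    Missing values are excluded from numerator and denominator. Raises if
    every value is missing.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    v = np.asarray(sample_values, dtype=float)
    ok = ~np.isnan(v)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("all values are missing")
    v = v[ok]
    return float((v > cutoff).sum() / n), float((v < -cutoff).sum() / n)


def welch_test(a, b) -> tuple[float, float]:
    """Welch t statistic and two-tailed p (Welch-Satterthwaite df).

    Degenerate cases: both variances zero with equal means gives (0, 1);
    both zero with different means gives (signed inf, 0) with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each vector needs length >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        warnings.warn("zero variance in both groups with different means: "
                      "degenerate Welch test", stacklevel=2)
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def _count_runs(mask: np.ndarray, chrom_starts: np.ndarray) -> np.ndarray:
    """Number of maximal True runs per row, runs reset at chromosome starts.

    *mask* is (n_rows, n_grid); *chrom_starts* flags the first grid index of
    each chromosome.
    """
    prev = np.zeros_like(mask)
    prev[:, 1:] = mask[:, :-1]
    prev[:, chrom_starts] = False
    starts = mask & ~prev
    return starts.sum(axis=1)


def _count_peaks(vals: np.ndarray, mask: np.ndarray, chrom_starts: np.ndarray,
                 maxima: bool) -> np.ndarray:
    """Local extrema (leftmost-of-plateau) falling inside *mask*, per row."""
    y = vals if maxima else -vals
    n_rows, n_grid = y.shape
    counts = np.zeros(n_rows, dtype=int)
    bounds = list(chrom_starts) + [n_grid]
    for c0, c1 in zip(bounds[:-1], bounds[1:]):
        seg = y[:, c0:c1]
        m = mask[:, c0:c1]
        for r in range(n_rows):
            row = seg[r]
            i = 1
            while i < len(row) - 1:
                if row[i] > row[i - 1]:
                    j = i
                    while j < len(row) - 1 and row[j + 1] == row[i]:
                        j += 1
                    if j < len(row) - 1 and row[j + 1] < row[i] and m[r, i]:
                        counts[r] += 1
                    i = j + 1
                else:
                    i += 1
    return counts


def cna_count_sweep(sample_curves: SampleKSEMatrix, thresholds,
                    labels: pd.Series | None = None,
                    mode: str = "runs") -> SweepResult:
    """Count aberrations per sample at each threshold and contrast groups.

    At threshold t, an aberration is a maximal contiguous grid run with
    KSE > t (gains) or KSE < -t (losses); both kinds are summed. With
    ``mode="peaks"`` local extrema beyond the threshold are counted instead.
    Per threshold, every unordered pair of group labels is contrasted with
    Welch's test and thresholds with p < 0.05 are flagged.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(thresholds <= 0):
        raise ValueError("thresholds must be > 0")
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    if mode not in ("runs", "peaks"):
        raise ValueError("mode must be 'runs' or 'peaks'")
    if labels is None:
        labels = sample_curves.groups

    vals = sample_curves.values
    chrom_starts = np.array([sample_curves.offsets[c].start
                             for c in sample_curves.chroms])
    counts = np.zeros((vals.shape[0], len(thresholds)), dtype=int)
    for k, t in enumerate(thresholds):
        if mode == "runs":
            counts[:, k] = (_count_runs(vals > t, chrom_starts)
                            + _count_runs(vals < -t, chrom_starts))
        else:
            counts[:, k] = (_count_peaks(vals, vals > t, chrom_starts, True)
                            + _count_peaks(vals, vals < -t, chrom_starts, False))

    counts_df = pd.DataFrame(counts, index=sample_curves.sample_ids, columns=thresholds)
    labels = labels.loc[counts_df.index]
    group_means = counts_df.groupby(labels).mean()
    group_means.index.name = "group"

    pvals = {}
    significant: dict[str, list[tuple[float, float]]] = {}
    for g1, g2 in combinations(group_means.index, 2):
        key = f"{g1} vs {g2}"
        a = counts[(labels == g1).to_numpy()]
        b = counts[(labels == g2).to_numpy()]
        ps = np.array([welch_test(a[:, k], b[:, k])[1] for k in range(len(thresholds))])
        pvals[key] = ps
        sig = ps < 0.05
        intervals = []
        k = 0
        while k < len(sig):
            if sig[k]:
                j = k
                while j + 1 < len(sig) and sig[j + 1]:
                    j += 1
                intervals.append((float(thresholds[k]), float(thresholds[j])))
                k = j + 1
            else:
                k += 1
        significant[key] = intervals
    pvalues = pd.DataFrame(pvals, index=thresholds).T
    return SweepResult(thresholds, counts_df, labels, group_means, pvalues, significant)


def instability_summary(group: ACGHGroup, cutoff: float) -> InstabilityResult:
    """Aberrant-fraction metrics for every sample, grouped and contrasted."""
    rows = []
    for sid in group.sample_ids:
        g, l = aberrant_fraction(group.values.loc[sid].to_numpy(), cutoff)
        rows.append({"sample_id": sid, "group": group.samples.loc[sid, "group"],
                     "gain_fraction": g, "loss_fraction": l})
    per_sample = pd.DataFrame(rows)

    def sem(x):
        return x.std(ddof=1) / np.sqrt(len(x))

    summary = per_sample.groupby("group").agg(
        n=("sample_id", "size"),
        gain_mean=("gain_fraction", "mean"), gain_sem=("gain_fraction", sem),
        loss_mean=("loss_fraction", "mean"), loss_sem=("loss_fraction", sem),
    ).reset_index()

    contrasts = []
    for g1, g2 in combinations(summary["group"], 2):
        for metric in ("gain_fraction", "loss_fraction"):
            a = per_sample.loc[per_sample["group"] == g1, metric]
            b = per_sample.loc[per_sample["group"] == g2, metric]
            t, p = welch_test(a, b)
            contrasts.append({"group_1": g1, "group_2": g2, "metric": metric,
                              "t": t, "p": p})
    return InstabilityResult(cutoff, per_sample, summary, pd.DataFrame(contrasts))


def classify_tumor_type(ecadherin_log2: float, vimentin_log2: float,
                        margin: float = 0.5) -> str:
    """Epithelial/Mesenchymal call from E-cadherin vs Vimentin expression.

    Mesenchymal if Vimentin exceeds E-cadherin by more than *margin* (log
    scale), Epithelial for the reverse, otherwise Ambiguous (a difference of
    exactly *margin* is Ambiguous).
    """
    if not (np.isfinite(ecadherin_log2) and np.isfinite(vimentin_log2)):
        raise ValueError("expression values must be finite")
    diff = vimentin_log2 - ecadherin_log2
    if diff > margin:
        return "Mesenchymal"
    if -diff > margin:
        return "Epithelial"
    return "Ambiguous"


def composition_percentages(counts: dict[str, int]) -> dict[str, float]:
    """Percentage composition of a scored-category count table.

    Keys map category -> count; returns category -> percent of the total
    scored (rounded to whole percent, as composition tables print them).
    """
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("need positive total count")
    return {k: round(100.0 * v / total) for k, v in counts.items()}
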