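"""Hemispheric asymmetry testing on along-tract profiles.

For each trimmed point (3-98) of a tract/metric, the healthy subjects' left
and right cross-sectional means are compared with a Wilcoxon matched-pairs
signed-rank test; p-values are Bonferroni-corrected over the 96 points of
the tract-metric family, and significant points are reported as contiguous
ranges. A D'Agostino-Pearson omnibus normality screen is provided because
the nonparametric choice is motivated by non-Gaussian point sets; it never
gates the Wilcoxon test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)

N_COMPARISONS = 96
ALPHA = 0.05
_EXACT_MAX_N = 25


def dagostino_pearson(values: np.ndarray) -> tuple:
    """D'Agostino-Pearson K^2 omnibus normality test (skewness + kurtosis
    z-scores, chi-square with 2 df). Requires n >= 8."""
    values = np.asarray(values, dtype=float)
    if values.size < 8:
        raise ValueError("D'Agostino-Pearson test needs n >= 8")
    k2, p = stats.normaltest(values)
    return float(k2), float(p)


@lru_cache(maxsize=64)
def _signed_rank_null(n: int) -> np.ndarray:
    """Exact null distribution of W+ (counts over 0..n(n+1)/2) for untied
    ranks 1..n, by subset-sum dynamic programming. Equivalent to enumerating
    all 2^n sign patterns."""
    counts = np.zeros(n * (n + 1) // 2 + 1, dtype=float)
    counts[0] = 1.0
    for r in range(1, n + 1):
        counts[r:] += counts[:-r].copy()
    return counts


def wilcoxon_signed_rank(x: np.ndarray, y: np.ndarray | None = None) -> tuple:
    """Wilcoxon matched-pairs signed-rank test, two-sided.

    Pass paired samples (x, y) or differences only. Zero differences are
    discarded (classic Wilcoxon convention); tied |differences| receive
    midranks. The p-value is exact (full sign-pattern null) when the
    effective n <= 25 and there are no ties, otherwise a normal
    approximation with continuity and tie correction is used.

    Returns (W, p) with W the sum of positive ranks.
    """
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    n_zero = int(np.sum(d == 0))
    if n_zero:
        log.info("discarded %d zero differences", n_zero)
    d = d[d != 0]
    n = d.size
    if n == 0:
        log.info("all differences zero: p = 1 by convention")
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))
    w = float(np.sum(ranks[d > 0]))

    has_ties = np.unique(np.abs(d)).size < n
    if n <= _EXACT_MAX_N and not has_ties:
        counts = _signed_rank_null(n)
        total = counts.sum()
        wi = int(round(w))
        p_le = counts[: wi + 1].sum() / total
        p_ge = counts[wi:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return w, float(p)

    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_counts**3 - tie_counts) / 48.0
    if var <= 0:
        return w, 1.0
    z = (w - mean - 0.5 * np.sign(w - mean)) / np.sqrt(var)
    return w, float(2.0 * stats.norm.sf(abs(z)))


@dataclass
class AsymmetryResult:
    """Point-wise left-vs-right comparison for one tract/metric family."""

    tract: str
    metric: str
    point_index: np.ndarray
    raw_p: np.ndarray
    adj_p: np.ndarray
    direction: np.ndarray  # +1 left>right, -1 right>left, 0 undefined
    significant: np.ndarray
    ranges: list  # (start_label, end_label, 'left>right'|'right>left')
    n_pairs: int


def _contiguous_ranges(labels: np.ndarray, keep: np.ndarray, direction: np.ndarray) -> list:
    out = []
    start = None
    for i in range(len(labels) + 1):
        active = i < len(labels) and keep[i]
        if active and (start is None or direction[i] != direction[start]):
            if start is not None:
                out.append((int(labels[start]), int(labels[i - 1]), _dir_label(direction[start])))
            start = i
        elif not active and start is not None:
            out.append((int(labels[start]), int(labels[i - 1]), _dir_label(direction[start])))
            start = None
    return out


def _dir_label(d: int) -> str:
    return "left>right" if d > 0 else "right>left"


def pointwise_asymmetry(
    left: np.ndarray,
    right: np.ndarray,
    point_index: np.ndarray | None = None,
    tract: str = "",
    metric: str = "",
    n_comparisons: int = N_COMPARISONS,
    alpha: float = ALPHA,
) -> AsymmetryResult:
    """Wilcoxon test at every point, Bonferroni over the family.

    ``left``/``right`` are (n_subjects, n_points) arrays of matched
    cross-sectional means. Adjusted p = min(1, n_comparisons * p); a point is
    significant when adjusted p < alpha (strict). Subjects missing either
    side at a point are dropped pair-wise; points with < 6 complete pairs are
    skipped (exact p cannot reach the corrected threshold at tiny n).
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape:
        raise ValueError("left and right cohorts must be matched in shape")
    n_sub, n_pts = left.shape
    if point_index is None:
        point_index = np.arange(3, 3 + n_pts)
    point_index = np.asarray(point_index, dtype=int)

    raw_p = np.full(n_pts, np.nan)
    direction = np.zeros(n_pts, dtype=int)
    for k in range(n_pts):
        pair_ok = np.isfinite(left[:, k]) & np.isfinite(right[:, k])
        if pair_ok.sum() < 6:
            log.info("point %d skipped: only %d complete pairs", point_index[k], pair_ok.sum())
            continue
        d = left[pair_ok, k] - right[pair_ok, k]
        _, raw_p[k] = wilcoxon_signed_rank(d)
        med = np.median(d[d != 0]) if np.any(d != 0) else 0.0
        direction[k] = int(np.sign(med))

    adj_p = np.minimum(1.0, n_comparisons * raw_p)
    significant = np.where(np.isfinite(adj_p), adj_p < alpha, False)
    ranges = _contiguous_ranges(point_index, significant, direction)
    return AsymmetryResult(
        tract=tract, metric=metric, point_index=point_index,
        raw_p=raw_p, adj_p=adj_p, direction=direction,
        significant=significant, ranges=ranges, n_pairs=n_sub,
    )
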