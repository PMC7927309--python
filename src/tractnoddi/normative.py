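"""Normative reference database built from a healthy cohort.

Per trimmed point of each tract/side/metric: the across-subject mean, sample
SD and t-based 95% confidence interval of the cross-sectional means; plus
outlier screening (ROUT at Q = 1% and Tukey IQR fences), coefficient-of-
variation summaries, and inter-metric Spearman correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class NormativeProfile:
    """Across-subject summary of cross-sectional means at each point."""

    tract: str
    side: str
    metric: str
    point_index: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_subjects: int

    @property
    def ci_width(self) -> np.ndarray:
        return self.ci_high - self.ci_low


def build_normative(
    profiles: np.ndarray | list,
    tract: str = "",
    side: str = "",
    metric: str = "",
    point_index: np.ndarray | None = None,
) -> NormativeProfile:
    """Aggregate per-subject trimmed profiles (rows = subjects) into a
    normative profile.

    The 95% CI is t-based: mean +/- t(0.975, n-1) * SD / sqrt(n), so the
    CI width equals 2*t(0.975, n-1)/sqrt(n) * SD (about 1.1076*SD at n=15).
    """
    if hasattr(profiles[0], "mean") and not isinstance(profiles[0], np.ndarray):
        first = profiles[0]
        tract = tract or first.tract
        side = side or first.side
        metric = metric or first.metric
        point_index = first.point_index if point_index is None else point_index
        data = np.vstack([p.mean for p in profiles])
    else:
        data = np.asarray(profiles, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2:
        raise ValueError("need >= 2 subject profiles with equal point counts")
    n = data.shape[0]
    if point_index is None:
        point_index = np.arange(3, 3 + data.shape[1])
    point_index = np.asarray(point_index, dtype=int)
    if point_index.size != data.shape[1]:
        raise ValueError("point_index length does not match the profiles")

    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
    return NormativeProfile(
        tract=tract, side=side, metric=metric, point_index=point_index,
        mean=mean, sd=sd, ci_low=mean - half, ci_high=mean + half, n_subjects=n,
    )


def detect_outliers_iqr(values: np.ndarray) -> np.ndarray:
    """Tukey fences: flag values outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR].

    Quartiles use linear interpolation between order statistics (type 7).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        log.info("IQR screen skipped: n=%d < 4", values.size)
        return np.zeros(values.size, bool)
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    return (values < q1 - 1.5 * iqr) | (values > q3 + 1.5 * iqr)


def _lorentzian_center(values: np.ndarray, max_iter: int = 200, tol: float = 1e-12) -> tuple:
    """Robust location by IRLS for the Lorentzian M-estimate.

    Start at the median; each sweep rescales by the RSDR (68.27th percentile
    of |residuals| with the n/(n-1) small-sample correction) and reweights
    w = 1/(1 + (r/s)^2). Returns (center, rsdr)."""
    n = values.size
    c = float(np.median(values))
    s = 0.0
    for _ in range(max_iter):
        r = values - c
        s = float(np.percentile(np.abs(r), 68.27)) * n / (n - 1)
        if s <= 0:
            return c, 0.0
        w = 1.0 / (1.0 + (r / s) ** 2)
        c_new = float(np.sum(w * values) / np.sum(w))
        if abs(c_new - c) < tol * max(1.0, abs(c)):
            c = c_new
            break
        c = c_new
    r = values - c
    s = float(np.percentile(np.abs(r), 68.27)) * n / (n - 1)
    return c, s


def detect_outliers_rout(values: np.ndarray, q: float = 0.01) -> np.ndarray:
    """ROUT outlier screen adapted to a univariate location model.

    A robust center is fitted by the Lorentzian M-estimate; residuals are
    scaled by the RSDR and referred to a t distribution with n-1 df. Testing
    proceeds from the largest |t| downward: the value of rank i (from the
    largest) is flagged when its two-tailed p < Q*(n-i+1)/n, stopping at the
    first failure — an FDR-style step-down with Q the maximum desired false
    discovery rate.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    flags = np.zeros(n, bool)
    if n < 5:
        log.info("ROUT screen skipped: n=%d < 5", n)
        return flags
    center, rsdr = _lorentzian_center(values)
    if rsdr <= 0:
        return flags
    t_stat = (values - center) / rsdr
    p = 2.0 * stats.t.sf(np.abs(t_stat), n - 1)
    order = np.argsort(-np.abs(t_stat))
    for i, idx in enumerate(order, start=1):
        if p[idx] < q * (n - i + 1) / n:
            flags[idx] = True
        else:
            break
    return flags


def outlier_summary(database: dict, q: float = 0.01) -> dict:
    """Count and percentage of flagged point-values per tract/metric and
    overall, separately for ROUT and IQR.

    ``database`` maps (tract, side, metric) -> (n_subjects, n_points) array
    of cross-sectional means.
    """
    per_key = {}
    tot = {"rout": 0, "iqr": 0, "n": 0}
    for key, data in database.items():
        data = np.asarray(data, dtype=float)
        n_rout = n_iqr = 0
        for point in data.T:
            n_rout += int(detect_outliers_rout(point, q=q).sum())
            n_iqr += int(detect_outliers_iqr(point).sum())
        n_vals = data.size
        per_key[key] = {
            "rout_count": n_rout,
            "iqr_count": n_iqr,
            "n_values": n_vals,
            "rout_pct": 100.0 * n_rout / n_vals,
            "iqr_pct": 100.0 * n_iqr / n_vals,
        }
        tot["rout"] += n_rout
        tot["iqr"] += n_iqr
        tot["n"] += n_vals
    overall = {
        "rout_count": tot["rout"],
        "iqr_count": tot["iqr"],
        "n_values": tot["n"],
        "rout_pct": 100.0 * tot["rout"] / tot["n"] if tot["n"] else 0.0,
        "iqr_pct": 100.0 * tot["iqr"] / tot["n"] if tot["n"] else 0.0,
        "q": q,
    }
    return {"per_tract_metric": per_key, "overall": overall}


def cv_summary(database: dict) -> dict:
    """Median and quartiles of the per-point coefficient of variation
    (100 * SD / mean, %) for each tract/side/metric. Points with zero mean
    are excluded (CV undefined) with a log record."""
    out = {}
    for key, data in database.items():
        data = np.asarray(data, dtype=float)
        mean = data.mean(axis=0)
        sd = data.std(axis=0, ddof=1)
        ok = mean != 0
        if np.any(~ok):
            log.info("%s: %d zero-mean points excluded from CV", key, int(np.sum(~ok)))
        cv = 100.0 * sd[ok] / np.abs(mean[ok])
        q1, med, q3 = np.percentile(cv, [25, 50, 75])
        out[key] = {"q1": float(q1), "median": float(med), "q3": float(q3)}
    return out


@dataclass
class CorrelationResult:
    metric_a: str
    metric_b: str
    r: float
    p: float
    n: int


def spearman_profiles(
    a: np.ndarray, b: np.ndarray, metric_a: str = "", metric_b: str = ""
) -> CorrelationResult:
    """Spearman rank correlation between two along-tract mean profiles
    (midranks for ties; large-sample p). Constant input gives r = NaN."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 5:
        raise ValueError("profiles must have equal length >= 5")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return CorrelationResult(metric_a, metric_b, float("nan"), float("nan"), a.size)
    r, p = stats.spearmanr(a, b)
    return CorrelationResult(metric_a, metric_b, float(r), float(p), a.size)
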