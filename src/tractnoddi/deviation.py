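"""Single-patient deviation detection against the normative database.

A patient point is flagged when it deviates by >= 2 normative SDs from the
healthy mean (boundary inclusive). Flagged points are reported as maximal
contiguous runs ("points [a-b]") and the joint behaviour of FICV, FECV,
FISO, ODI and FA is classified into the peritumoral deviation taxonomy:

* Pattern A — FICV decrease with FECV increase; FA spared, or abnormal over
  a remarkably shorter segment.
* Pattern B — FICV decrease with FECV increase and a paradoxical FA
  increase (colocalizing with ODI decrease).
* Pattern C — global derangement: FICV down, FECV up, extensive FA decrease
  and an FISO upsurge.
* Pattern D — isolated FISO upsurge with no other metric affected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .normative import NormativeProfile
from .profile import AlongTractProfile

log = logging.getLogger(__name__)

Z_THRESHOLD = 2.0
#: Pattern-A/C split: FA-low run length relative to FICV-low run length.
RHO_DEFAULT = 0.5

LOW, IN_RANGE, HIGH, MISSING = "low", "in-range", "high", "missing"


@dataclass
class DeviationFlags:
    """Per-point deviation state and z-scores for one metric."""

    metric: str
    point_index: np.ndarray
    z: np.ndarray
    state: np.ndarray  # array of LOW/IN_RANGE/HIGH/MISSING

    def count(self, state: str) -> int:
        return int(np.sum(self.state == state))


@dataclass
class DeviationReport:
    """Full single-tract deviation report for one patient."""

    patient_id: str
    tract: str
    side: str
    flags: dict = field(default_factory=dict)  # metric -> DeviationFlags
    runs: dict = field(default_factory=dict)  # metric -> {low: [...], high: [...]}
    pattern: str = "none"
    trace: dict = field(default_factory=dict)


def flag_deviations(
    patient: AlongTractProfile, normative: NormativeProfile, z_threshold: float = Z_THRESHOLD
) -> DeviationFlags:
    """z = (patient - normative mean) / normative SD per point;
    |z| >= threshold flags the point (inclusive at the boundary).
    Points with zero normative SD or missing data are marked missing."""
    if patient.metric and normative.metric and patient.metric != normative.metric:
        raise ValueError(f"metric mismatch: {patient.metric} vs {normative.metric}")
    if patient.tract and normative.tract and patient.tract != normative.tract:
        raise ValueError(f"tract mismatch: {patient.tract} vs {normative.tract}")
    if len(patient.mean) != len(normative.mean):
        raise ValueError("patient and normative profiles differ in length")
    if not np.array_equal(patient.point_index, normative.point_index):
        raise ValueError("patient and normative point labels differ")

    with np.errstate(invalid="ignore", divide="ignore"):
        z = (patient.mean - normative.mean) / normative.sd
    bad = ~np.isfinite(z)
    if bad.any():
        log.info("%s: %d points unflaggable (zero SD or missing)", patient.metric, bad.sum())
    state = np.full(len(z), IN_RANGE, dtype=object)
    state[z <= -z_threshold] = LOW
    state[z >= z_threshold] = HIGH
    state[bad] = MISSING
    return DeviationFlags(
        metric=patient.metric or normative.metric,
        point_index=patient.point_index.copy(),
        z=z,
        state=state,
    )


def flagged_runs(flags: DeviationFlags) -> dict:
    """Maximal contiguous runs of identical out-of-range state, labelled by
    original point indices: {'low': [(a, b), ...], 'high': [...]}."""
    runs: dict = {LOW: [], HIGH: []}
    labels = flags.point_index
    start = None
    cur = None
    for i in range(len(labels) + 1):
        s = flags.state[i] if i < len(labels) else IN_RANGE
        if s in (LOW, HIGH):
            if start is None or s != cur:
                if start is not None:
                    runs[cur].append((int(labels[start]), int(labels[i - 1])))
                start, cur = i, s
        elif start is not None:
            runs[cur].append((int(labels[start]), int(labels[i - 1])))
            start = cur = None
    return runs


def _run_point_count(runs: list) -> int:
    return sum(b - a + 1 for a, b in runs)


def format_runs(runs: list) -> str:
    """Human-readable run list: "points [5-86], [92]"."""
    parts = [f"[{a}-{b}]" if a != b else f"[{a}]" for a, b in runs]
    return "points " + ", ".join(parts) if parts else "none"


def classify_pattern(runs_by_metric: dict, rho: float = RHO_DEFAULT) -> tuple:
    """Assign the deviation pattern label from per-metric low/high runs.

    ``runs_by_metric`` maps metric name (FICV, FECV, FISO, ODI, FA) to the
    output of :func:`flagged_runs`. Rules are evaluated in the order
    D -> C -> B -> A so the singleton patterns are not absorbed:

    * D: FISO-high present and no other metric flagged.
    * C: FICV-low, FECV-high, FA-low and FISO-high all present, with the
      FA-low extent >= rho * FICV-low extent.
    * B: FICV-low and FECV-high present, with any FA-high segment.
    * A: FICV-low and FECV-high present, no FA-high, and FA-low extent
      < rho * FICV-low extent ("remarkably shorter segment").

    Returns (label, trace); the trace records the per-metric point counts
    and which rule fired.
    """
    required = {"FICV", "FECV", "FISO", "ODI", "FA"}
    missing = required - set(runs_by_metric)
    if missing:
        raise ValueError(f"runs missing for metrics: {sorted(missing)}")

    n = {
        m: {d: _run_point_count(runs_by_metric[m][d]) for d in (LOW, HIGH)}
        for m in required
    }
    trace = {"counts": n, "rho": rho}

    others_flagged = any(
        n[m][d] > 0 for m in required - {"FISO"} for d in (LOW, HIGH)
    ) or n["FISO"][LOW] > 0
    ficv_low = n["FICV"][LOW] > 0
    fecv_high = n["FECV"][HIGH] > 0

    if n["FISO"][HIGH] > 0 and not others_flagged:
        trace["rule"] = "D: isolated FISO upsurge"
        return "D", trace
    if (
        ficv_low and fecv_high and n["FA"][LOW] > 0 and n["FISO"][HIGH] > 0
        and n["FA"][LOW] >= rho * n["FICV"][LOW]
    ):
        trace["rule"] = "C: FICV down, FECV up, extensive FA down, FISO up"
        return "C", trace
    if ficv_low and fecv_high and n["FA"][HIGH] > 0:
        trace["rule"] = "B: FICV down, FECV up, paradoxical FA increase"
        return "B", trace
    if ficv_low and fecv_high and n["FA"][HIGH] == 0 and n["FA"][LOW] < rho * n["FICV"][LOW]:
        trace["rule"] = "A: FICV down, FECV up, FA spared or barely affected"
        return "A", trace
    trace["rule"] = "none"
    return "none", trace


def build_report(
    patient_id: str,
    tract: str,
    side: str,
    patient_profiles: dict,
    normative_profiles: dict,
    rho: float = RHO_DEFAULT,
    z_threshold: float = Z_THRESHOLD,
) -> DeviationReport:
    """Flag all metrics of one patient tract and classify the pattern."""
    report = DeviationReport(patient_id=patient_id, tract=tract, side=side)
    for metric, prof in patient_profiles.items():
        fl = flag_deviations(prof, normative_profiles[metric], z_threshold)
        report.flags[metric] = fl
        report.runs[metric] = flagged_runs(fl)
    classifiable = {"FICV", "FECV", "FISO", "ODI", "FA"}
    if classifiable <= set(report.runs):
        report.pattern, report.trace = classify_pattern(
            {m: report.runs[m] for m in classifiable}, rho=rho
        )
    return report


def compare_md_shells(
    patient_low: AlongTractProfile,
    patient_high: AlongTractProfile,
    normative_low: NormativeProfile,
    normative_high: NormativeProfile,
    z_threshold: float = Z_THRESHOLD,
) -> dict:
    """Shell-wise MD comparison (b=711 vs b=3000).

    Flags each shell against its own normative profile and summarizes
    per-point state agreement and whether the low-b curve dominates the
    high-b curve (restricted diffusion lowers the apparent diffusivity at
    high b, so healthy MD(b=711) > MD(b=3000) point-wise).
    """
    flags_low = flag_deviations(patient_low, normative_low, z_threshold)
    flags_high = flag_deviations(patient_high, normative_high, z_threshold)
    agree = flags_low.state == flags_high.state
    return {
        "flags_b_low": flags_low,
        "flags_b_high": flags_high,
        "runs_b_low": flagged_runs(flags_low),
        "runs_b_high": flagged_runs(flags_high),
        "state_agreement": float(np.mean(agree)),
        "low_b_dominates": bool(np.all(patient_low.mean > patient_high.mean)),
    }
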