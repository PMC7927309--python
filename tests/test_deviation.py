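import numpy as np
import pytest

from tractnoddi.deviation import (
    HIGH,
    IN_RANGE,
    LOW,
    MISSING,
    DeviationFlags,
    build_report,
    classify_pattern,
    compare_md_shells,
    flag_deviations,
    flagged_runs,
    format_runs,
)
from tractnoddi.normative import NormativeProfile
from tractnoddi.profile import AlongTractProfile
from tractnoddi.synthetic import (
    BETWEEN_SUBJECT_SD,
    PATTERN_AMPLITUDES,
    PerturbationSpec,
    default_templates,
    inject_perturbation,
    trimmed_arc_positions,
)

POINTS = np.arange(3, 99)
S = trimmed_arc_positions()


def _profile(metric, mean):
    return AlongTractProfile(
        metric=metric, point_index=POINTS, mean=np.asarray(mean, float),
        sd=np.zeros(96), n_streamlines=20, tract="AF", side="right",
    )


def _normative(metric, mean, sd):
    mean = np.asarray(mean, float)
    sd = np.broadcast_to(np.asarray(sd, float), mean.shape)
    half = 1.1076 * sd / 2
    return NormativeProfile(
        tract="AF", side="right", metric=metric, point_index=POINTS,
        mean=mean, sd=sd.copy(), ci_low=mean - half, ci_high=mean + half,
        n_subjects=15,
    )


def template_normative(template, metric, sd=None):
    """True-parameter normative: template mean with the generator's SD."""
    sd = BETWEEN_SUBJECT_SD[metric] if sd is None else sd
    return _normative(metric, template(metric, S), sd)


class TestFlagDeviations:
    def test_patient_at_mean_unflagged(self):
        ref = _normative("FICV", np.full(96, 0.5), 0.02)
        fl = flag_deviations(_profile("FICV", np.full(96, 0.5)), ref)
        assert fl.count(LOW) == 0 and fl.count(HIGH) == 0

    def test_z_score_arithmetic(self):
        ref = _normative("FICV", np.full(96, 0.50), 0.05)
        patient = np.full(96, 0.50)
        patient[10] = 0.62
        fl = flag_deviations(_profile("FICV", patient), ref)
        assert fl.z[10] == pytest.approx(2.4)
        assert fl.state[10] == HIGH

    def test_boundary_inclusive_at_two_sd(self):
        # dyadic values so patient - mean == 2*SD holds exactly in floats
        ref = _normative("FICV", np.full(96, 0.5), 0.0625)
        patient = np.full(96, 0.5)
        patient[5] = 0.625  # exactly mean + 2 SD
        patient[6] = 0.375  # exactly mean - 2 SD
        fl = flag_deviations(_profile("FICV", patient), ref)
        assert fl.state[5] == HIGH and fl.state[6] == LOW

    def test_zero_sd_point_is_missing(self):
        sd = np.full(96, 0.05)
        sd[0] = 0.0
        ref = _normative("FICV", np.full(96, 0.5), sd)
        fl = flag_deviations(_profile("FICV", np.full(96, 0.7)), ref)
        assert fl.state[0] == MISSING

    def test_metric_mismatch_rejected(self):
        ref = _normative("FA", np.full(96, 0.5), 0.05)
        with pytest.raises(ValueError, match="metric mismatch"):
            flag_deviations(_profile("FICV", np.full(96, 0.5)), ref)

    def test_monotone_in_patient_value(self):
        """Raising a single patient point never demotes it from high."""
        ref = _normative("FICV", np.full(96, 0.5), 0.05)
        base = np.full(96, 0.5)
        prev_high = False
        for value in np.linspace(0.5, 0.8, 31):
            patient = base.copy()
            patient[40] = value
            state = flag_deviations(_profile("FICV", patient), ref).state[40]
            if prev_high:
                assert state == HIGH
            prev_high = state == HIGH


class TestFlaggedRuns:
    def _flags(self, high_pts=(), low_pts=()):
        state = np.full(96, IN_RANGE, dtype=object)
        for p in high_pts:
            state[p - 3] = HIGH
        for p in low_pts:
            state[p - 3] = LOW
        return DeviationFlags("FICV", POINTS, np.zeros(96), state)

    def test_run_grouping(self):
        runs = flagged_runs(self._flags(high_pts=[5, 6, 7, 8, 9, 10, 12]))
        assert runs[HIGH] == [(5, 10), (12, 12)]
        assert format_runs(runs[HIGH]) == "points [5-10], [12]"

    def test_no_flags_empty(self):
        runs = flagged_runs(self._flags())
        assert runs[HIGH] == [] and runs[LOW] == []

    def test_full_span(self):
        runs = flagged_runs(self._flags(low_pts=range(3, 99)))
        assert runs[LOW] == [(3, 98)]


def _runs(**kwargs):
    base = {m: {LOW: [], HIGH: []} for m in ("FICV", "FECV", "FISO", "ODI", "FA")}
    for key, spans in kwargs.items():
        metric, direction = key.rsplit("_", 1)
        base[metric][LOW if direction == "low" else "high"] = spans
    return base


class TestClassifyPattern:
    def test_pattern_a(self):
        label, trace = classify_pattern(
            _runs(FICV_low=[(30, 60)], FECV_high=[(32, 58)])
        )
        assert label == "A"
        assert trace["rule"].startswith("A")

    def test_pattern_b(self):
        label, _ = classify_pattern(
            _runs(
                FICV_low=[(44, 57)], FECV_high=[(37, 55)],
                FA_high=[(36, 47)], ODI_low=[(36, 47)],
            )
        )
        assert label == "B"

    def test_pattern_c(self):
        label, _ = classify_pattern(
            _runs(
                FICV_low=[(24, 98)], FECV_high=[(23, 98)],
                FISO_high=[(42, 69)], FA_low=[(41, 98)], ODI_low=[(37, 45)],
            )
        )
        assert label == "C"

    def test_pattern_d(self):
        label, _ = classify_pattern(_runs(FISO_high=[(42, 69)]))
        assert label == "D"

    def test_no_flags_is_none(self):
        label, _ = classify_pattern(_runs())
        assert label == "none"

    def test_a_with_short_fa_segment_still_a(self):
        # FA affected over a remarkably shorter segment than FICV
        label, _ = classify_pattern(
            _runs(FICV_low=[(10, 60)], FECV_high=[(12, 58)], FA_low=[(30, 35)])
        )
        assert label == "A"

    def test_missing_metric_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            classify_pattern({"FICV": {LOW: [], HIGH: []}})


class TestEndToEndPatterns:
    def _patient_report(self, pattern, interval=(0.3, 0.62)):
        template = default_templates()
        perturbed = inject_perturbation(template, PerturbationSpec(pattern, interval))
        metrics = ("FICV", "FECV", "FISO", "ODI", "FA")
        patient = {m: _profile(m, perturbed(m, S)) for m in metrics}
        normative = {m: template_normative(template, m) for m in metrics}
        return build_report("p", "AF", "right", patient, normative)

    @pytest.mark.parametrize("pattern", ["A", "B", "C", "D"])
    def test_injected_pattern_recovered(self, pattern):
        assert self._patient_report(pattern).pattern == pattern

    def test_null_patient_yields_none(self):
        template = default_templates()
        metrics = ("FICV", "FECV", "FISO", "ODI", "FA")
        patient = {m: _profile(m, template(m, S)) for m in metrics}
        normative = {m: template_normative(template, m) for m in metrics}
        report = build_report("p", "AF", "right", patient, normative)
        assert report.pattern == "none"
        assert all(r == {LOW: [], HIGH: []} for r in report.runs.values())

    def test_noisy_null_flag_rate(self):
        """Healthy subjects drawn from the generator average <= 5 flagged
        points per metric against the true normative (about 4.6% expected
        for two-sided |z| >= 2)."""
        from tractnoddi.synthetic import CohortConfig, simulate_profile_cohort

        template = default_templates()
        ref = template_normative(template, "FICV")
        n = 1500  # per-subject counts are heavy-tailed (smooth noise flags
        # whole runs at once), so the mean needs a large cohort to settle
        coh = simulate_profile_cohort(
            CohortConfig(n_subjects=n, seed=21), metrics=("FICV",)
        )
        total = 0
        for row in coh["right"]["FICV"]:
            fl = flag_deviations(_profile("FICV", row), ref)
            total += fl.count(LOW) + fl.count(HIGH)
        assert total / n <= 5.0


class TestMdShells:
    def test_identical_patient_unflagged_both_shells(self):
        mean_lo = np.full(96, 0.8e-3)
        mean_hi = np.full(96, 0.6e-3)
        out = compare_md_shells(
            _profile("MD_b711", mean_lo), _profile("MD_b3000", mean_hi),
            _normative("MD_b711", mean_lo, 3e-5), _normative("MD_b3000", mean_hi, 3e-5),
        )
        assert out["runs_b_low"][HIGH] == [] and out["runs_b_high"][HIGH] == []
        assert out["state_agreement"] == 1.0
        assert out["low_b_dominates"]

    def test_edema_like_lesion_flags_overlap_between_shells(self):
        s = S
        window = PerturbationSpec("D", interval=(0.35, 0.65)).window(s)
        mean_lo = np.full(96, 0.8e-3)
        mean_hi = np.full(96, 0.6e-3)
        bump = 3e-4 * window  # free-water rise inflates MD on both shells
        out = compare_md_shells(
            _profile("MD_b711", mean_lo + bump), _profile("MD_b3000", mean_hi + bump),
            _normative("MD_b711", mean_lo, 3e-5), _normative("MD_b3000", mean_hi, 3e-5),
        )
        lo_pts = {p for a, b in out["runs_b_low"][HIGH] for p in range(a, b + 1)}
        hi_pts = {p for a, b in out["runs_b_high"][HIGH] for p in range(a, b + 1)}
        assert lo_pts and hi_pts
        overlap = len(lo_pts & hi_pts) / max(len(lo_pts), len(hi_pts))
        assert overlap >= 0.8
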