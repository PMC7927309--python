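import numpy as np
import pytest

from tractnoddi.core import arc_length
from tractnoddi.noddi import D_ISO
from tractnoddi.profile import along_tract_stats, trim_endpoints
from tractnoddi.scheme import AcquisitionScheme
from tractnoddi.synthetic import (
    BundleSpec,
    CohortConfig,
    GridSpec,
    PerturbationSpec,
    TemplateProfileSet,
    default_templates,
    generate_bundle,
    inject_perturbation,
    paint_volumes,
    simulate_cohort,
    simulate_dwi,
    simulate_profile_cohort,
    trimmed_arc_positions,
)

S_GRID = np.linspace(0.0, 1.0, 501)


class TestGenerateBundle:
    def test_streamline_count(self):
        b = generate_bundle(BundleSpec("AF", n_streamlines=20, seed=0))
        assert len(b) == 20

    def test_determinism(self):
        spec = BundleSpec("CST", n_streamlines=5, seed=42)
        a = generate_bundle(spec)
        b = generate_bundle(BundleSpec("CST", n_streamlines=5, seed=42))
        for sa, sb in zip(a.streamlines, b.streamlines):
            assert np.array_equal(sa, sb)

    def test_arc_lengths_near_centerline_length(self):
        # straight 80 mm centerline with 1 mm jitter: lengths within [75, 85]
        center = np.column_stack([np.linspace(0, 80, 8), np.zeros(8), np.zeros(8)])
        b = generate_bundle(
            BundleSpec("CST", centerline=center, n_streamlines=30,
                       radial_jitter_mm=1.0, seed=3)
        )
        lengths = [arc_length(sl) for sl in b.streamlines]
        assert min(lengths) > 75 and max(lengths) < 85

    def test_degenerate_centerline_rejected(self):
        with pytest.raises(ValueError, match="zero length|degenerate"):
            BundleSpec("AF", centerline=np.zeros((5, 3)))

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            BundleSpec("AF", n_streamlines=0)
        with pytest.raises(ValueError):
            BundleSpec("AF", radial_jitter_mm=-1.0)


class TestTemplates:
    def test_compartments_sum_to_one(self, templates):
        total = templates.compartment_sum(S_GRID)
        assert np.max(np.abs(total - 1.0)) < 1e-12

    def test_ranges_valid(self, templates):
        templates.check(S_GRID)

    def test_missing_metric_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            TemplateProfileSet({"FA": lambda s: s})


class TestInjectPerturbation:
    def test_locality(self, templates):
        pert = PerturbationSpec("A", interval=(0.3, 0.6),
                                amplitudes={"FICV": -0.10, "FECV": +0.10})
        out = inject_perturbation(templates, pert)
        assert out("FICV", 0.45) == pytest.approx(templates("FICV", 0.45) - 0.10, abs=1e-12)
        assert out("FICV", 0.1) == pytest.approx(templates("FICV", 0.1), abs=1e-12)
        assert out("FA", 0.45) == pytest.approx(templates("FA", 0.45), abs=1e-12)

    def test_zero_amplitudes_identity(self, templates):
        pert = PerturbationSpec("A", amplitudes={})
        out = inject_perturbation(templates, pert)
        for m in ("FICV", "FECV", "FISO", "FA", "MD"):
            assert np.allclose(out(m, S_GRID), templates(m, S_GRID), atol=1e-12)

    @pytest.mark.parametrize("pattern", ["A", "B", "C", "D"])
    def test_sum_preserved_after_perturbation(self, templates, pattern):
        out = inject_perturbation(templates, PerturbationSpec(pattern))
        total = out("FICV", S_GRID) + out("FECV", S_GRID) + out("FISO", S_GRID)
        assert np.max(np.abs(total - 1.0)) < 1e-12

    def test_pattern_d_preserves_tissue_ratio(self, templates):
        out = inject_perturbation(templates, PerturbationSpec("D", interval=(0.3, 0.6)))
        s_in = np.linspace(0.36, 0.54, 20)  # inside, past the taper
        ratio_before = templates("FICV", s_in) / templates("FECV", s_in)
        ratio_after = out("FICV", s_in) / out("FECV", s_in)
        assert np.allclose(ratio_after, ratio_before, atol=1e-12)
        assert np.all(out("FISO", s_in) > templates("FISO", s_in))
        s_out = np.array([0.1, 0.8])
        assert np.allclose(out("FISO", s_out), templates("FISO", s_out), atol=1e-12)

    def test_overflow_clipped_with_warning(self, templates):
        pert = PerturbationSpec("D", amplitudes={"FISO": 2.0})
        with pytest.warns(UserWarning, match="clipping"):
            out = inject_perturbation(templates, pert)
        assert np.all(out("FISO", S_GRID) <= 1.0)


class TestPaintVolumes:
    def test_constant_template_paints_constant(self, bundle):
        const = TemplateProfileSet(
            {m: (lambda s: np.full_like(np.asarray(s, float), 0.5))
             for m in ("FICV", "FECV", "FISO", "ODI", "FA", "MD", "AD", "RD")}
        )
        vols = paint_volumes(const, bundle, metrics=("FA",))
        data = vols["FA"].data
        assert np.all(data[np.isfinite(data)] == 0.5)

    def test_background_fill_is_nan(self, bundle, templates):
        vols = paint_volumes(templates, bundle, metrics=("FA",))
        data = vols["FA"].data
        assert np.isnan(data).any() and np.isfinite(data).any()

    def test_linear_ramp_round_trip(self, bundle):
        ramp = dict.fromkeys(("FICV", "FECV", "FISO", "ODI", "MD", "AD", "RD"))
        funcs = {m: (lambda s: 0.1 + 0.0 * np.asarray(s, float)) for m in ramp}
        funcs["FISO"] = lambda s: 0.8 - 0.0 * np.asarray(s, float)
        funcs["FECV"] = lambda s: 0.1 + 0.0 * np.asarray(s, float)
        funcs["FA"] = lambda s: 0.2 + 0.6 * np.asarray(s, float)
        tmpl = TemplateProfileSet(funcs)
        vols = paint_volumes(tmpl, bundle, metrics=("FA",))
        profiles = along_tract_stats(bundle, vols)
        trimmed = trim_endpoints(profiles["FA"])
        s = trimmed_arc_positions()
        assert np.nanmax(np.abs(trimmed.mean - (0.2 + 0.6 * s))) < 0.02

    def test_bundle_outside_grid_rejected(self, bundle, templates):
        tiny = GridSpec(shape=(3, 3, 3), affine=np.eye(4))
        with pytest.raises(ValueError, match="outside"):
            paint_volumes(templates, bundle, tiny)


class TestSimulateCohort:
    def test_construction_and_symmetry(self, templates):
        cfg = CohortConfig(n_subjects=2, n_streamlines=4, seed=0,
                           between_subject_sd={m: 0.0 for m in templates.funcs})
        subjects = simulate_cohort(cfg, templates)
        assert len(subjects) == 2
        s = np.linspace(0, 1, 50)
        for subj in subjects:
            left = subj.templates[("AF", "left")]
            right = subj.templates[("AF", "right")]
            assert np.allclose(left("FICV", s), right("FICV", s), atol=1e-12)
            # zero between-subject SD: templates equal the base
            assert np.allclose(left("FICV", s), templates("FICV", s), atol=1e-12)

    def test_profile_cohort_shapes_and_determinism(self):
        cfg = CohortConfig(n_subjects=15, seed=5)
        a = simulate_profile_cohort(cfg, metrics=("FICV", "FA"))
        b = simulate_profile_cohort(cfg, metrics=("FICV", "FA"))
        assert a["left"]["FICV"].shape == (15, 96)
        assert np.array_equal(a["right"]["FA"], b["right"]["FA"])

    def test_zero_variability_collapses_cohort(self):
        cfg = CohortConfig(n_subjects=4, seed=1,
                           between_subject_sd={"FICV": 0.0})
        coh = simulate_profile_cohort(cfg, metrics=("FICV",))
        assert np.allclose(np.ptp(coh["left"]["FICV"], axis=0), 0.0, atol=1e-15)


class TestSimulateDwi:
    def _params(self, n=1):
        return {
            "fiso": np.full(n, 0.1),
            "ficvf": np.full(n, 0.6),
            "kappa": np.full(n, 2.0),
            "mu": np.tile([0.0, 0.0, 1.0], (n, 1)),
        }

    def test_b0_equals_s0_noise_free(self, scheme):
        dwi = simulate_dwi(self._params(), scheme, snr=np.inf, s0=123.0)
        assert np.allclose(dwi.signal[..., scheme.b0_mask], 123.0)

    def test_free_water_attenuation(self, scheme):
        params = self._params()
        params["fiso"][:] = 1.0
        dwi = simulate_dwi(params, scheme, snr=np.inf, s0=1.0)
        dw = ~scheme.b0_mask
        assert np.allclose(
            dwi.signal[0, 0, 0][dw], np.exp(-scheme.bvals[dw] * D_ISO), atol=1e-12
        )

    def test_rician_mean_close_to_s0(self):
        # 500 noisy repetitions at SNR 50: mean b=0 signal within 1% of S0
        sch = AcquisitionScheme([0.0, 0.0], np.zeros((2, 3)))
        params = self._params(500)
        dwi = simulate_dwi(params, sch, snr=50.0, s0=1.0, seed=9)
        assert abs(dwi.signal[..., 0].mean() - 1.0) < 0.01

    def test_noise_is_seeded(self, scheme):
        a = simulate_dwi(self._params(), scheme, snr=20.0, seed=3)
        b = simulate_dwi(self._params(), scheme, snr=20.0, seed=3)
        c = simulate_dwi(self._params(), scheme, snr=20.0, seed=4)
        assert np.array_equal(a.signal, b.signal)
        assert not np.array_equal(a.signal, c.signal)
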