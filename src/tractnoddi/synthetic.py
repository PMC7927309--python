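"""Synthetic cohorts with known ground truth.

Everything downstream of tractography is testable against this module: it
generates bundle geometry (smooth perturbations of named centerlines),
smooth along-arc metric templates satisfying the compartment sum constraint,
painted metric volumes, lesion-like perturbations matching the deviation
pattern taxonomy, per-subject between-subject variability, and (optionally)
two-shell DWI signals from the Watson-NODDI forward model with Rician noise.

All outputs are pure functions of (configuration, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import interpolate, ndimage

from .core import ScalarVolume, TractModel, arc_length
from .noddi import kappa_from_odi, noddi_signal
from .scheme import AcquisitionScheme, DWIDataset
from .profile import N_POINTS, TRIM

COMPARTMENTS = ("FICV", "FECV", "FISO")
METRICS = ("FICV", "FECV", "FISO", "ODI", "FA", "MD", "AD", "RD")

#: Valid value range per metric (used for clipping after perturbation).
METRIC_RANGES = {
    "FICV": (0.0, 1.0),
    "FECV": (0.0, 1.0),
    "FISO": (0.0, 1.0),
    "ODI": (0.0, 1.0),
    "FA": (0.0, 1.0),
    "MD": (1e-6, 4e-3),
    "AD": (1e-6, 4e-3),
    "RD": (1e-6, 4e-3),
}

#: Default between-subject SD of the smooth per-subject offsets.
BETWEEN_SUBJECT_SD = {
    "FICV": 0.017, "FECV": 0.017, "FISO": 0.017, "ODI": 0.017, "FA": 0.017,
    "MD": 3e-5, "AD": 3e-5, "RD": 3e-5,
}


# ---------------------------------------------------------------------------
# templates

class TemplateProfileSet:
    """Smooth metric templates as functions of arc position s in [0, 1].

    The compartment fractions satisfy FICV + FECV + FISO = 1 for every s by
    construction; perturbation and per-subject offsets renormalize the sum.
    """

    def __init__(self, funcs: dict):
        missing = set(METRICS) - set(funcs)
        if missing:
            raise ValueError(f"templates missing for metrics: {sorted(missing)}")
        self.funcs = dict(funcs)

    def __call__(self, metric: str, s: np.ndarray) -> np.ndarray:
        return np.asarray(self.funcs[metric](np.asarray(s, dtype=float)), dtype=float)

    def compartment_sum(self, s: np.ndarray) -> np.ndarray:
        return self("FICV", s) + self("FECV", s) + self("FISO", s)

    def check(self, s: np.ndarray | None = None, tol: float = 1e-12) -> None:
        if s is None:
            s = np.linspace(0.0, 1.0, 257)
        total = self("FICV", s) + self("FECV", s) + self("FISO", s)
        if np.max(np.abs(total - 1.0)) > tol:
            raise ValueError("compartment templates do not sum to 1")
        for m in ("FICV", "FECV", "FISO", "ODI", "FA"):
            v = self(m, s)
            if np.any((v < -tol) | (v > 1 + tol)):
                raise ValueError(f"{m} template leaves [0, 1]")
        for m in ("MD", "AD", "RD"):
            if np.any(self(m, s) <= 0):
                raise ValueError(f"{m} template must stay positive")


def default_templates() -> TemplateProfileSet:
    """Physiologically plausible healthy white-matter templates.

    Free water is kept low (FISO ~ 0.05), the intra-neurite fraction of
    tissue around 0.55, ODI in the coherent-to-moderate range, and FA tied
    inversely to ODI (its main determinant in healthy tracts). Diffusivities
    are in mm^2/s with MD = (AD + 2 RD)/3.
    """
    fiso = lambda s: 0.05 + 0.02 * np.sin(np.pi * s)
    ficvf = lambda s: 0.55 + 0.08 * np.sin(2 * np.pi * s)
    odi = lambda s: 0.25 + 0.10 * np.cos(np.pi * s)
    ad = lambda s: 1.30e-3 + 0.10e-3 * np.cos(2 * np.pi * s)
    rd = lambda s: 0.50e-3 + 0.06e-3 * np.sin(np.pi * s + 0.7)
    return TemplateProfileSet(
        {
            "FICV": lambda s: (1.0 - fiso(s)) * ficvf(s),
            "FECV": lambda s: (1.0 - fiso(s)) * (1.0 - ficvf(s)),
            "FISO": fiso,
            "ODI": odi,
            "FA": lambda s: 0.62 - 0.75 * odi(s),
            "AD": ad,
            "RD": rd,
            "MD": lambda s: (ad(s) + 2.0 * rd(s)) / 3.0,
        }
    )


# ---------------------------------------------------------------------------
# perturbations

#: Signed default amplitudes per pattern (compartment deltas sum to zero so
#: renormalization is the identity where possible).
PATTERN_AMPLITUDES = {
    "A": {"FICV": -0.10, "FECV": +0.10},
    "B": {"FICV": -0.10, "FECV": +0.10, "ODI": -0.10, "FA": +0.10},
    "C": {"FICV": -0.15, "FECV": +0.07, "FISO": +0.08, "FA": -0.12},
    # the compartment renormalization spreads an FISO rise across the tissue
    # fractions (~ -FICV*delta), so D stays "isolated" only while that induced
    # shift remains inside the +/-2 SD band of healthy variability
    "D": {"FISO": +0.055},
}


@dataclass
class PerturbationSpec:
    """A localized lesion-like template perturbation."""

    pattern: str
    interval: tuple = (0.3, 0.6)
    amplitudes: dict | None = None
    taper: float = 0.05

    def __post_init__(self) -> None:
        if self.pattern not in PATTERN_AMPLITUDES:
            raise ValueError(f"unknown pattern {self.pattern!r}")
        lo, hi = self.interval
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("interval must satisfy 0 <= s_lo < s_hi <= 1")
        if self.amplitudes is None:
            self.amplitudes = dict(PATTERN_AMPLITUDES[self.pattern])

    def window(self, s: np.ndarray) -> np.ndarray:
        """Smoothstep window: 1 on the interval interior, cubic taper of
        width ``taper`` inside each edge, 0 outside."""
        s = np.asarray(s, dtype=float)
        lo, hi = self.interval
        t = np.minimum((s - lo), (hi - s)) / max(self.taper, 1e-12)
        t = np.clip(t, 0.0, 1.0)
        return np.where((s >= lo) & (s <= hi), t * t * (3.0 - 2.0 * t), 0.0)


def _perturbed_funcs(template: TemplateProfileSet, deltas: dict, window) -> dict:
    """Apply windowed additive deltas; renormalize the compartment sum."""

    def compartment(metric):
        def f(s):
            vals = {
                m: np.clip(
                    template(m, s) + deltas.get(m, 0.0) * window(s), 0.0, 1.0
                )
                for m in COMPARTMENTS
            }
            total = vals["FICV"] + vals["FECV"] + vals["FISO"]
            return vals[metric] / total

        return f

    def scalar(metric):
        lo, hi = METRIC_RANGES[metric]

        def f(s):
            return np.clip(template(metric, s) + deltas.get(metric, 0.0) * window(s), lo, hi)

        return f

    funcs = {}
    for m in METRICS:
        funcs[m] = compartment(m) if m in COMPARTMENTS else scalar(m)
    return funcs


def inject_perturbation(
    template: TemplateProfileSet, pert: PerturbationSpec
) -> TemplateProfileSet:
    """Return a new template altered only inside the perturbation interval.

    Compartment deltas are applied to FICV/FECV/FISO, clipped to [0, 1] and
    renormalized to sum to 1 (so a lone FISO increase scales the tissue
    fractions down while preserving the FICV/FECV ratio); other metrics get
    the windowed delta with range clipping.
    """
    s_check = np.linspace(*pert.interval, 33)
    for m, d in pert.amplitudes.items():
        lo, hi = METRIC_RANGES[m]
        raw = template(m, s_check) + d
        if np.any((raw < lo) | (raw > hi)):
            warnings.warn(f"{m} perturbation leaves its valid range; clipping", stacklevel=2)
    return TemplateProfileSet(_perturbed_funcs(template, pert.amplitudes, pert.window))


def offset_template(
    template: TemplateProfileSet, offsets: dict
) -> TemplateProfileSet:
    """Apply smooth additive offset functions (metric -> callable of s),
    renormalizing compartments; used for between-subject variability and
    configured asymmetries."""

    def compartment(metric):
        def f(s):
            vals = {}
            for m in COMPARTMENTS:
                v = template(m, s)
                if m in offsets:
                    v = v + offsets[m](s)
                vals[m] = np.clip(v, 0.0, 1.0)
            total = vals["FICV"] + vals["FECV"] + vals["FISO"]
            return vals[metric] / total

        return f

    def scalar(metric):
        lo, hi = METRIC_RANGES[metric]

        def f(s):
            v = template(metric, s)
            if metric in offsets:
                v = v + offsets[metric](s)
            return np.clip(v, lo, hi)

        return f

    funcs = {m: (compartment(m) if m in COMPARTMENTS else scalar(m)) for m in METRICS}
    return TemplateProfileSet(funcs)


def smooth_offset(rng: np.random.Generator, sd: float):
    """A smooth random function with pointwise SD exactly ``sd``:
    sd/sqrt(3) * (z0 + sqrt(2) z1 cos(pi s) + sqrt(2) z2 sin(pi s))."""
    z = rng.standard_normal(3)

    def f(s):
        s = np.asarray(s, dtype=float)
        return (sd / np.sqrt(3.0)) * (
            z[0] + np.sqrt(2.0) * z[1] * np.cos(np.pi * s) + np.sqrt(2.0) * z[2] * np.sin(np.pi * s)
        )

    return f


# ---------------------------------------------------------------------------
# bundle geometry

#: Control points (mm) of named tract-like centerlines, left-hemisphere
#: convention (x < 0); purely synthetic shapes that exercise curvature and
#: reorientation, not anatomical models.
_CENTERLINES = {
    # C-shaped arc (fronto-temporal)
    "AF": [(-30, 40, 10), (-35, 20, 25), (-35, -5, 30), (-33, -25, 20), (-30, -35, 0)],
    # mostly vertical with a gentle bend
    "FAT": [(-25, 30, 45), (-28, 25, 30), (-30, 18, 15), (-28, 12, 0)],
    "IFOF": [(-28, 45, 0), (-32, 20, 5), (-34, -10, 8), (-30, -45, 5)],
    "UF": [(-28, 35, -5), (-36, 22, -12), (-38, 8, -10), (-30, 2, -20)],
    "CING": [(-8, 35, 25), (-10, 10, 32), (-10, -15, 30), (-8, -35, 22)],
    "CST": [(-22, -15, 55), (-24, -12, 30), (-25, -14, 5), (-20, -18, -25)],
    "OR": [(-24, -25, 5), (-30, -45, 3), (-28, -65, 2), (-20, -80, 0)],
}


def default_centerline(name: str, side: str = "left", n_control: int = 8) -> np.ndarray:
    """Control points for a named tract shape (right side mirrors x)."""
    base = np.asarray(_CENTERLINES.get(name, _CENTERLINES["AF"]), dtype=float)
    if n_control > len(base):
        tck, _ = interpolate.splprep(base.T, s=0, k=3)
        base = np.array(interpolate.splev(np.linspace(0, 1, n_control), tck)).T
    if side == "right":
        base = base * np.array([-1.0, 1.0, 1.0])
    return base


@dataclass
class BundleSpec:
    """Recipe for one synthetic bundle."""

    name: str
    side: str = "left"
    centerline: np.ndarray | None = None
    n_streamlines: int = 20
    radial_jitter_mm: float = 1.0
    points_per_streamline: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_streamlines < 1:
            raise ValueError("n_streamlines must be >= 1")
        if self.radial_jitter_mm < 0:
            raise ValueError("radial_jitter_mm must be nonnegative")
        if self.points_per_streamline < 10:
            raise ValueError("points_per_streamline must be >= 10")
        if self.centerline is None:
            self.centerline = default_centerline(self.name, self.side)
        self.centerline = np.asarray(self.centerline, dtype=float)
        if self.centerline.shape[0] < 4:
            raise ValueError("centerline needs >= 4 control points")
        if arc_length(self.centerline) <= 0:
            raise ValueError("degenerate centerline (zero length)")


def generate_bundle(spec: BundleSpec) -> TractModel:
    """Generate a bundle as smooth random perturbations of the centerline.

    Each streamline is the centerline spline plus a smooth 3-D offset field
    whose pointwise per-component SD is ``radial_jitter_mm``; deterministic
    given the spec seed. Vertex 1 corresponds to arc position s=0, and the
    origin anchor is placed at the centerline start.
    """
    rng = np.random.default_rng(spec.seed)
    tck, _ = interpolate.splprep(spec.centerline.T, s=0, k=3)
    t = np.linspace(0.0, 1.0, spec.points_per_streamline)
    center = np.array(interpolate.splev(t, tck)).T
    streamlines = []
    for _ in range(spec.n_streamlines):
        offset = np.column_stack(
            [smooth_offset(rng, spec.radial_jitter_mm)(t) for _ in range(3)]
        )
        streamlines.append(center + offset)
    origin = np.array(interpolate.splev(0.0, tck)).ravel()
    return TractModel(spec.name, spec.side, streamlines, origin_mm=origin)


# ---------------------------------------------------------------------------
# volume painting

@dataclass
class GridSpec:
    """Target grid: shape plus voxel-to-world affine."""

    shape: tuple
    affine: np.ndarray

    @classmethod
    def around(cls, bundles, voxel_mm: float = 2.0, margin_mm: float = 8.0) -> "GridSpec":
        """Axis-aligned grid covering the bundles with a margin (default
        2 mm isotropic voxels, a typical dMRI resolution)."""
        pts = np.vstack([np.vstack(b.streamlines) for b in np.atleast_1d(bundles)])
        lo = pts.min(axis=0) - margin_mm
        hi = pts.max(axis=0) + margin_mm
        shape = tuple(np.ceil((hi - lo) / voxel_mm).astype(int) + 1)
        affine = np.diag([voxel_mm] * 3 + [1.0])
        affine[:3, 3] = lo
        return cls(shape=shape, affine=affine)


def _arc_positions(streamline: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(streamline, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    return cum / cum[-1]


def paint_arc_field(
    bundle: TractModel, grid: GridSpec, pad_mm: float = 2.5, step_mm: float = 0.5
) -> tuple:
    """Rasterize the bundle into an arc-position field on the grid.

    Each voxel traversed by the bundle gets the arc position s of the
    nearest dense streamline sample; voxels within ``pad_mm`` of the painted
    set inherit s from their nearest painted voxel (so trilinear sampling
    near the bundle surface does not touch background). Returns
    (s_field, mask).
    """
    ref = ScalarVolume(np.zeros(grid.shape), grid.affine)
    pts = []
    svals = []
    for sl in bundle.streamlines:
        s = _arc_positions(sl)
        length = arc_length(sl)
        n_dense = max(int(np.ceil(length / step_mm)), len(sl))
        t = np.linspace(0.0, 1.0, n_dense)
        dense = np.column_stack([np.interp(t, s, sl[:, i]) for i in range(3)])
        pts.append(dense)
        svals.append(t)
    pts = np.vstack(pts)
    svals = np.concatenate(svals)

    vox = ref.world_to_voxel(pts)
    idx = np.rint(vox).astype(int)
    if np.any(idx < 0) or np.any(idx >= np.array(grid.shape)):
        raise ValueError("bundle extends outside the target grid")
    dist = np.linalg.norm(vox - idx, axis=1)

    flat = np.ravel_multi_index(idx.T, grid.shape)
    order = np.lexsort((dist, flat))
    flat_sorted = flat[order]
    first = np.concatenate([[True], flat_sorted[1:] != flat_sorted[:-1]])
    chosen = order[first]

    s_field = np.full(grid.shape, np.nan)
    s_field.ravel()[flat[chosen]] = svals[chosen]
    mask = np.isfinite(s_field)

    if pad_mm > 0:
        voxel = float(np.cbrt(abs(np.linalg.det(np.asarray(grid.affine)[:3, :3]))))
        d, (ii, jj, kk) = ndimage.distance_transform_edt(~mask, return_indices=True)
        grow = (~mask) & (d * voxel <= pad_mm)
        s_field[grow] = s_field[ii[grow], jj[grow], kk[grow]]
        mask = np.isfinite(s_field)
    return s_field, mask


def paint_volumes(
    template: TemplateProfileSet,
    bundle: TractModel,
    grid: GridSpec | None = None,
    metrics=METRICS,
    fill: float = np.nan,
    pad_mm: float = 2.5,
) -> dict:
    """Paint metric volumes from an along-arc template.

    Every bundle voxel holds the template value at the arc position of the
    nearest streamline passage; background voxels hold ``fill``.
    """
    if grid is None:
        grid = GridSpec.around([bundle])
    s_field, mask = paint_arc_field(bundle, grid, pad_mm=pad_mm)
    out = {}
    for m in metrics:
        data = np.full(grid.shape, fill)
        data[mask] = template(m, s_field[mask])
        out[m] = ScalarVolume(data, grid.affine)
    return out


# ---------------------------------------------------------------------------
# cohorts

@dataclass
class CohortConfig:
    """Study conditions for the synthetic healthy cohort: 15 subjects,
    bilateral bundles, smooth between-subject variability."""

    bundles: tuple = ("AF",)
    n_subjects: int = 15
    n_streamlines: int = 20
    radial_jitter_mm: float = 1.0
    voxel_mm: float = 2.0
    between_subject_sd: dict = field(default_factory=lambda: dict(BETWEEN_SUBJECT_SD))
    #: optional left-side offsets: metric -> (s_lo, s_hi, delta)
    left_offsets: dict = field(default_factory=dict)
    metrics: tuple = METRICS
    seed: int = 0


@dataclass
class SyntheticSubject:
    """One simulated subject: bundles, painted volumes, ground truth."""

    subject_id: str
    tracts: dict  # (bundle, side) -> TractModel
    volumes: dict  # (bundle, side) -> {metric: ScalarVolume}
    templates: dict  # (bundle, side) -> TemplateProfileSet
    seed: int


def _subject_template(
    base: TemplateProfileSet, rng: np.random.Generator, sd: dict, metrics
) -> TemplateProfileSet:
    """Per-subject smooth offsets with pointwise SD as configured.

    Compartment offsets are the sum-zero projection of three iid smooth
    fields (scaled by sqrt(3/2) so each marginal keeps the nominal SD);
    this preserves FICV+FECV+FISO = 1 without renormalization shrinkage.
    """
    offsets: dict = {}
    sd_comp = float(np.mean([sd.get(m, 0.0) for m in COMPARTMENTS]))
    if sd_comp > 0:
        fields = [smooth_offset(rng, sd_comp * np.sqrt(1.5)) for _ in COMPARTMENTS]

        def projected(i):
            def f(s):
                vals = [g(s) for g in fields]
                return vals[i] - sum(vals) / 3.0

            return f

        for i, m in enumerate(COMPARTMENTS):
            offsets[m] = projected(i)
    for m in metrics:
        if m not in COMPARTMENTS:
            offsets[m] = smooth_offset(rng, sd.get(m, 0.0))
    return offset_template(base, offsets)


def _asymmetry_offsets(left_offsets: dict) -> dict:
    """Windowed additive offsets for configured asymmetries.

    A tissue-compartment offset is compensated in the complementary tissue
    compartment (FICV <-> FECV) so the configured metric shifts by exactly
    the requested delta instead of being shrunk by renormalization.
    """
    compensate = {"FICV": "FECV", "FECV": "FICV"}
    terms: dict = {}
    for m, (lo, hi, delta) in left_offsets.items():
        window = PerturbationSpec("A", interval=(lo, hi)).window
        terms.setdefault(m, []).append((delta, window))
        if m in compensate:
            terms.setdefault(compensate[m], []).append((-delta, window))

    def combine(parts):
        def f(s):
            return sum(d * w(s) for d, w in parts)

        return f

    return {m: combine(parts) for m, parts in terms.items()}


def simulate_cohort(config: CohortConfig, template: TemplateProfileSet | None = None) -> list:
    """Simulate the healthy cohort with painted metric volumes.

    Left and right share the same base template unless ``left_offsets`` is
    configured; between-subject variability is a smooth random offset per
    subject, side and metric with the configured pointwise SD.
    """
    base = template if template is not None else default_templates()
    rng = np.random.default_rng(config.seed)
    subjects = []

    grids = {}
    left_base = offset_template(base, _asymmetry_offsets(config.left_offsets)) \
        if config.left_offsets else base
    for name in config.bundles:
        probe = [
            generate_bundle(BundleSpec(name, side, n_streamlines=1,
                                       radial_jitter_mm=config.radial_jitter_mm, seed=0))
            for side in ("left", "right")
        ]
        grids[name] = GridSpec.around(
            probe, voxel_mm=config.voxel_mm,
            margin_mm=8.0 + 4.0 * config.radial_jitter_mm,
        )

    for i in range(config.n_subjects):
        tracts, volumes, templates = {}, {}, {}
        for name in config.bundles:
            for side in ("left", "right"):
                side_base = left_base if side == "left" else base
                subj_template = _subject_template(
                    side_base, rng, config.between_subject_sd, config.metrics
                )
                bundle_seed = int(rng.integers(0, 2**31 - 1))
                bundle = generate_bundle(
                    BundleSpec(
                        name, side,
                        n_streamlines=config.n_streamlines,
                        radial_jitter_mm=config.radial_jitter_mm,
                        seed=bundle_seed,
                    )
                )
                tracts[(name, side)] = bundle
                templates[(name, side)] = subj_template
                volumes[(name, side)] = paint_volumes(
                    subj_template, bundle, grids[name], metrics=config.metrics
                )
        subjects.append(
            SyntheticSubject(
                subject_id=f"sub-{i + 1:02d}", tracts=tracts,
                volumes=volumes, templates=templates, seed=config.seed,
            )
        )
    return subjects


def trimmed_arc_positions(n_points: int = N_POINTS, trim: int = TRIM) -> np.ndarray:
    """Arc positions s of the trimmed points (labels 3-98)."""
    return np.arange(trim, n_points - trim) / (n_points - 1)


def simulate_profile_cohort(
    config: CohortConfig | None = None,
    template: TemplateProfileSet | None = None,
    metrics=None,
    seed: int | None = None,
) -> dict:
    """Fast path: per-subject trimmed 96-point profiles straight from the
    templates (no volume painting).

    Statistically identical to profiling painted volumes up to voxelization:
    subject profile = (base template + smooth offsets) evaluated at the
    trimmed arc positions. Returns {side: {metric: (n_subjects, 96)}}.
    """
    config = config or CohortConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    base = template if template is not None else default_templates()
    metrics = tuple(metrics) if metrics is not None else config.metrics
    rng = np.random.default_rng(config.seed)
    s = trimmed_arc_positions()
    left_base = offset_template(base, _asymmetry_offsets(config.left_offsets)) \
        if config.left_offsets else base

    out = {side: {m: np.empty((config.n_subjects, s.size)) for m in metrics}
           for side in ("left", "right")}
    for i in range(config.n_subjects):
        for side in ("left", "right"):
            side_base = left_base if side == "left" else base
            subj = _subject_template(side_base, rng, config.between_subject_sd, metrics)
            for m in metrics:
                out[side][m][i] = subj(m, s)
    return out


# ---------------------------------------------------------------------------
# DWI simulation

def simulate_dwi(
    params: dict,
    scheme: AcquisitionScheme,
    snr: float = np.inf,
    s0: float = 1.0,
    affine: np.ndarray | None = None,
    seed: int = 0,
) -> DWIDataset:
    """Forward-simulate two-shell DWI from per-voxel Watson-NODDI parameters.

    ``params`` maps 'fiso', 'ficvf', 'kappa' to arrays of one spatial shape
    and 'mu' to unit vectors of that shape + (3,). A finite ``snr`` applies
    Rician noise with sigma = s0/snr (magnitude-MRI convention), seeded.
    """
    fiso = np.atleast_3d(np.asarray(params["fiso"], dtype=float))
    ficvf = np.atleast_3d(np.asarray(params["ficvf"], dtype=float))
    kappa = np.atleast_3d(np.asarray(params["kappa"], dtype=float))
    mu = np.asarray(params["mu"], dtype=float)
    mu = mu.reshape(fiso.shape + (3,))
    shape = fiso.shape

    signal = np.empty(shape + (len(scheme),))
    for idx in np.ndindex(shape):
        signal[idx] = s0 * noddi_signal(
            scheme, float(fiso[idx]), float(ficvf[idx]), float(kappa[idx]), mu[idx]
        )
    if np.isfinite(snr):
        rng = np.random.default_rng(seed)
        sigma = s0 / snr
        n1 = rng.normal(0.0, sigma, signal.shape)
        n2 = rng.normal(0.0, sigma, signal.shape)
        signal = np.sqrt((signal + n1) ** 2 + n2**2)
    return DWIDataset(signal, scheme, affine if affine is not None else np.eye(4))


def noddi_params_from_template(
    template: TemplateProfileSet, s: np.ndarray, mu: np.ndarray | None = None
) -> dict:
    """Per-point NODDI parameters along the arc, for DWI simulation.

    fiso and ficvf are read off the compartment templates
    (ficvf = FICV / (FICV + FECV)); kappa comes from the ODI template.
    """
    s = np.asarray(s, dtype=float)
    fiso = template("FISO", s)
    ficv = template("FICV", s)
    fecv = template("FECV", s)
    ficvf = ficv / (ficv + fecv)
    kappa = np.asarray(kappa_from_odi(np.clip(template("ODI", s), 1e-3, 1 - 1e-3)))
    if mu is None:
        mu_arr = np.tile([0.0, 0.0, 1.0], (s.size, 1))
    else:
        mu_arr = np.broadcast_to(np.asarray(mu, dtype=float), (s.size, 3)).copy()
    return {"fiso": fiso, "ficvf": ficvf, "kappa": kappa, "mu": mu_arr}
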