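"""Along-tract profiling: streamline reorientation, equal-arc-length spline
resampling to 100 vertices, skeletonization, voxel-to-vertex metric sampling,
and cross-sectional statistics.

The per-vertex correspondence strategy follows the classic along-tract-stats
approach: every streamline of a bundle is reoriented to a common anatomical
origin, reparameterized with a cubic B-spline, and resampled into 100 points
evenly spaced by arc length, so that the k-th vertex of one streamline
corresponds to the set of k-th vertices of the others. The cross-sectional
mean and SD of a scalar map over that set give the along-tract profile; the
first and last two points are discarded afterwards (endpoint instability),
leaving points 3-98.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate

from .core import ScalarVolume, TractModel

log = logging.getLogger(__name__)

N_POINTS = 100
TRIM = 2  # points dropped at each end (1, 2, 99, 100)
_ARC_SUBDIV = 1000  # dense subdivisions for arc-length inversion


@dataclass
class ResampledTract:
    """A tract with every streamline resampled to the same vertex count."""

    tract: TractModel
    vertices: np.ndarray  # (n_streamlines, n_points, 3)
    samples: dict = field(default_factory=dict)  # metric -> (n_streamlines, n_points)

    @property
    def n_streamlines(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_points(self) -> int:
        return self.vertices.shape[1]


@dataclass
class AlongTractProfile:
    """Cross-sectional mean/SD of one metric along one subject's tract."""

    metric: str
    point_index: np.ndarray  # original 1-based point labels
    mean: np.ndarray
    sd: np.ndarray
    n_streamlines: int
    tract: str = ""
    side: str = ""
    n_excluded: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.point_index = np.asarray(self.point_index, dtype=int)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if not (len(self.point_index) == len(self.mean) == len(self.sd)):
            raise ValueError("point_index, mean and sd must have equal length")

    @property
    def is_trimmed(self) -> bool:
        return len(self.mean) == N_POINTS - 2 * TRIM


def reorient_streamlines(tract: TractModel) -> TractModel:
    """Flip streamlines so every first vertex is the end nearer the origin
    anchor. Pure reordering: no vertex is moved. Idempotent."""
    if tract.origin_mm is None:
        raise ValueError("tract has no origin anchor")
    anchor = tract.origin_mm
    out = []
    for i, sl in enumerate(tract.streamlines):
        d_first = np.linalg.norm(sl[0] - anchor)
        d_last = np.linalg.norm(sl[-1] - anchor)
        if abs(d_first - d_last) < 1e-6:
            log.info("streamline %d equidistant from anchor; keeping original order", i)
            out.append(sl)
        elif d_last < d_first:
            out.append(sl[::-1].copy())
        else:
            out.append(sl)
    return TractModel(tract.name, tract.side, out, tract.origin_mm)


def _spline_through(vertices: np.ndarray):
    """Interpolating cubic B-spline (linear fallback below 4 vertices)."""
    vertices = np.asarray(vertices, dtype=float)
    # collapse consecutive duplicates, which splprep rejects
    keep = np.ones(len(vertices), bool)
    keep[1:] = np.linalg.norm(np.diff(vertices, axis=0), axis=1) > 0
    vertices = vertices[keep]
    if len(vertices) < 2:
        raise ValueError("streamline has zero length")
    k = 3 if len(vertices) >= 4 else 1
    if k == 1:
        log.info("streamline with %d vertices: linear resampling fallback", len(vertices))
    tck, _ = interpolate.splprep(vertices.T, s=0, k=k)
    return tck


def resample_streamline(vertices: np.ndarray, n: int = N_POINTS) -> np.ndarray:
    """Resample a streamline to ``n`` points evenly spaced by arc length.

    The polyline is reparameterized with an interpolating cubic B-spline;
    arc length along the spline is approximated by dense piecewise-linear
    subdivision and inverted to give equal increments.
    """
    tck = _spline_through(vertices)
    u_dense = np.linspace(0.0, 1.0, _ARC_SUBDIV + 1)
    dense = np.array(interpolate.splev(u_dense, tck)).T
    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    if cum[-1] <= 0:
        raise ValueError("streamline has zero length")
    targets = np.linspace(0.0, cum[-1], n)
    u_eq = np.interp(targets, cum, u_dense)
    out = np.array(interpolate.splev(u_eq, tck)).T
    # endpoints of an interpolating spline are the curve ends
    out[0], out[-1] = dense[0], dense[-1]
    return out


def resample_tract(tract: TractModel, n: int = N_POINTS) -> ResampledTract:
    verts = np.stack([resample_streamline(sl, n) for sl in tract.streamlines])
    return ResampledTract(tract=tract, vertices=verts)


def compute_skeleton(rt: ResampledTract) -> np.ndarray:
    """The skeleton tract: per-vertex-index mean coordinate across
    streamlines ("collapsing" corresponding vertices). Shape (n_points, 3)."""
    return rt.vertices.mean(axis=0)


def sample_metric(
    volume: ScalarVolume, rt: ResampledTract, method: str = "trilinear"
) -> np.ndarray:
    """Sample a scalar map at every resampled vertex.

    Returns (n_streamlines, n_points); vertices outside the grid (or over
    NaN background) are NaN, the undefined marker.
    """
    flat = rt.vertices.reshape(-1, 3)
    vals = volume.sample(flat, method=method)
    n_bad = int(np.sum(~np.isfinite(vals)))
    if n_bad:
        log.info("%d of %d vertex samples undefined", n_bad, vals.size)
    return vals.reshape(rt.vertices.shape[:2])


def along_tract_stats(
    tract: TractModel,
    volumes: dict,
    method: str = "trilinear",
    reorient: bool = True,
) -> dict:
    """Full chain: (reorient ->) resample -> sample -> cross-sectional stats.

    ``volumes`` maps metric name to ScalarVolume. Returns a dict of raw
    100-point AlongTractProfiles keyed by metric.
    """
    if reorient and tract.origin_mm is not None:
        tract = reorient_streamlines(tract)
    rt = resample_tract(tract)
    profiles = {}
    for name, vol in volumes.items():
        samples = sample_metric(vol, rt, method=method)
        rt.samples[name] = samples
        profiles[name] = cross_sectional_profile(samples, name, tract)
    return profiles


def cross_sectional_profile(
    samples: np.ndarray, metric: str, tract: TractModel | None = None
) -> AlongTractProfile:
    """Per-point mean and sample SD (n-1 denominator) across streamlines.

    Undefined (NaN) samples are excluded point-wise; a point with no finite
    sample is marked missing (NaN mean/SD). A single-streamline tract has
    SD defined as 0.
    """
    finite = np.isfinite(samples)
    n_ok = finite.sum(axis=0)
    n_excluded = samples.shape[0] - n_ok
    if n_excluded.sum():
        log.info("excluded %d undefined samples across %d points",
                 int(n_excluded.sum()), int(np.sum(n_excluded > 0)))
    vals = np.where(finite, samples, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n_ok > 0, vals.sum(axis=0) / n_ok, np.nan)
        ss = np.where(finite, (samples - mean) ** 2, 0.0).sum(axis=0)
        sd = np.where(
            n_ok > 1, np.sqrt(ss / np.maximum(n_ok - 1, 1)),
            np.where(n_ok == 1, 0.0, np.nan),
        )
    return AlongTractProfile(
        metric=metric,
        point_index=np.arange(1, samples.shape[1] + 1),
        mean=mean,
        sd=sd,
        n_streamlines=samples.shape[0],
        tract=tract.name if tract else "",
        side=tract.side if tract else "",
        n_excluded=n_excluded,
    )


def trim_endpoints(p: AlongTractProfile) -> AlongTractProfile:
    """Discard points 1, 2, 99 and 100, keeping the central 96 points
    (labels 3-98): cross-sectional means are unstable near endpoints."""
    if len(p.mean) != N_POINTS:
        raise ValueError(f"expected a {N_POINTS}-point raw profile, got {len(p.mean)}")
    sl = slice(TRIM, N_POINTS - TRIM)
    return AlongTractProfile(
        metric=p.metric,
        point_index=p.point_index[sl],
        mean=p.mean[sl],
        sd=p.sd[sl],
        n_streamlines=p.n_streamlines,
        tract=p.tract,
        side=p.side,
        n_excluded=None if p.n_excluded is None else p.n_excluded[sl],
    )
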