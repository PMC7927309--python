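"""File I/O: TRK/TCK streamlines, NIfTI volumes, profile and database tables.

World coordinates are RAS millimetres; the TRK voxel-offset convention is
converted on read/write through nibabel's tractogram API. NIfTI affines
follow nibabel's precedence (sform preferred when valid).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import ScalarVolume, TractModel
from .normative import NormativeProfile
from .profile import AlongTractProfile


def read_streamlines(path, name: str = "", side: str = "", origin_mm=None) -> TractModel:
    """Read a TRK or TCK file into a TractModel (vertices in world RAS mm)."""
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty streamline file")
    try:
        tractogram_file = nib.streamlines.load(str(path))
    except Exception as exc:  # nibabel raises format-specific errors
        raise ValueError(f"{path}: cannot parse streamlines ({exc})") from exc
    streamlines = [np.asarray(sl, dtype=float) for sl in tractogram_file.streamlines]
    if not streamlines:
        raise ValueError(f"{path}: no streamlines")
    return TractModel(name or path.stem, side, streamlines, origin_mm=origin_mm)


def write_streamlines(tract: TractModel, path) -> None:
    """Write a TractModel as TRK or TCK (by extension), world RAS mm."""
    tractogram = nib.streamlines.Tractogram(
        [sl.astype(np.float32) for sl in tract.streamlines],
        affine_to_rasmm=np.eye(4),
    )
    nib.streamlines.save(tractogram, str(path))


def read_volume(path) -> ScalarVolume:
    """Read a 3-D NIfTI scalar map."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim == 4 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    return ScalarVolume(data, np.asarray(img.affine, dtype=float))


def write_volume(vol: ScalarVolume, path) -> None:
    nib.save(nib.Nifti1Image(vol.data.astype(np.float32), vol.affine), str(path))


def write_dwi(signal: np.ndarray, affine: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(signal, dtype=np.float32), affine), str(path))


# ---------------------------------------------------------------------------
# tables

def profiles_to_frame(profiles) -> pd.DataFrame:
    """Flatten AlongTractProfiles into a tidy table."""
    rows = []
    for p in profiles:
        for i in range(len(p.mean)):
            rows.append(
                {
                    "tract": p.tract,
                    "side": p.side,
                    "metric": p.metric,
                    "point_index": int(p.point_index[i]),
                    "mean": p.mean[i],
                    "sd": p.sd[i],
                    "n_streamlines": p.n_streamlines,
                    "n_excluded": 0 if p.n_excluded is None else int(p.n_excluded[i]),
                }
            )
    return pd.DataFrame(rows)


def write_profiles(profiles, path) -> None:
    profiles_to_frame(profiles).to_csv(path, index=False)


def read_profiles(path) -> list:
    """Read a profile CSV back into AlongTractProfile objects."""
    df = pd.read_csv(path)
    out = []
    for (tract, side, metric), grp in df.groupby(["tract", "side", "metric"], dropna=False):
        grp = grp.sort_values("point_index")
        out.append(
            AlongTractProfile(
                metric=str(metric),
                point_index=grp["point_index"].to_numpy(),
                mean=grp["mean"].to_numpy(),
                sd=grp["sd"].to_numpy(),
                n_streamlines=int(grp["n_streamlines"].iloc[0]),
                tract="" if pd.isna(tract) else str(tract),
                side="" if pd.isna(side) else str(side),
                n_excluded=grp["n_excluded"].to_numpy(),
            )
        )
    return out


def write_normative(profiles, out_dir, metadata: dict | None = None) -> None:
    """Persist a normative database: one CSV row per tract/side/metric/point
    plus a JSON metadata sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in profiles:
        for i in range(len(p.mean)):
            rows.append(
                {
                    "tract": p.tract, "side": p.side, "metric": p.metric,
                    "point_index": int(p.point_index[i]),
                    "mean": p.mean[i], "sd": p.sd[i],
                    "ci_low": p.ci_low[i], "ci_high": p.ci_high[i],
                    "n_subjects": p.n_subjects,
                }
            )
    pd.DataFrame(rows).to_csv(out_dir / "normative.csv", index=False)
    meta = {
        "ci_formula": "mean +/- t(0.975, n-1) * sd / sqrt(n)",
        "quartile_convention": "linear interpolation (type 7)",
    }
    meta.update(metadata or {})
    (out_dir / "normative.json").write_text(json.dumps(meta, indent=2))


def read_normative(out_dir) -> list:
    df = pd.read_csv(Path(out_dir) / "normative.csv")
    out = []
    for (tract, side, metric), grp in df.groupby(["tract", "side", "metric"], dropna=False):
        grp = grp.sort_values("point_index")
        out.append(
            NormativeProfile(
                tract="" if pd.isna(tract) else str(tract),
                side="" if pd.isna(side) else str(side),
                metric=str(metric),
                point_index=grp["point_index"].to_numpy(),
                mean=grp["mean"].to_numpy(),
                sd=grp["sd"].to_numpy(),
                ci_low=grp["ci_low"].to_numpy(),
                ci_high=grp["ci_high"].to_numpy(),
                n_subjects=int(grp["n_subjects"].iloc[0]),
            )
        )
    return out
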