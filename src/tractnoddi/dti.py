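"""Diffusion tensor estimation by log-linear least squares, and the
standard rotation-invariant scalars (FA, MD, AD, RD)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scheme import AcquisitionScheme, DWIDataset


def tensor_scalars(eigenvalues: np.ndarray) -> tuple:
    """FA, MD, AD, RD from tensor eigenvalues (sorted descending).

    FA = sqrt(3/2 * sum((l_i - l_mean)^2) / sum(l_i^2)); an all-zero tensor
    has FA defined as 0. Works element-wise on stacked (..., 3) input.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    if ev.shape[-1] != 3:
        raise ValueError("expected eigenvalue triples in the last axis")
    md = ev.mean(axis=-1)
    ad = ev[..., 0]
    rd = (ev[..., 1] + ev[..., 2]) / 2.0
    denom = np.sum(ev**2, axis=-1)
    num = np.sum((ev - md[..., None]) ** 2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / denom)
    fa = np.where(denom > 0, fa, 0.0)
    return fa, md, ad, rd


@dataclass
class TensorFit:
    """Voxel-wise tensor fit: lower-triangular components, eigensystem, scalars.

    ``tensors`` holds (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) per voxel in mm^2/s.
    ``valid`` marks voxels where the log-linear fit was well posed.
    """

    tensors: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    fa: np.ndarray
    md: np.ndarray
    ad: np.ndarray
    rd: np.ndarray
    valid: np.ndarray
    s0: np.ndarray

    @property
    def principal_direction(self) -> np.ndarray:
        """Unit eigenvector of the largest eigenvalue, per voxel."""
        return self.eigenvectors[..., :, 0]


def design_matrix(scheme: AcquisitionScheme) -> np.ndarray:
    """Rows [-b gx^2, -b gy^2, -b gz^2, -2b gxgy, -2b gxgz, -2b gygz, 1]
    acting on (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz, log S0)."""
    b = scheme.bvals
    g = scheme.bvecs
    return np.column_stack(
        [
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2 * b * g[:, 0] * g[:, 1],
            -2 * b * g[:, 0] * g[:, 2],
            -2 * b * g[:, 1] * g[:, 2],
            np.ones_like(b),
        ]
    )


def tensor_signal(tensor6: np.ndarray, scheme: AcquisitionScheme, s0: float = 1.0) -> np.ndarray:
    """Forward mono-exponential tensor signal for one voxel."""
    X = design_matrix(scheme)
    coef = np.concatenate([np.asarray(tensor6, dtype=float), [np.log(s0)]])
    return np.exp(X @ coef)


def _tensor_from_lower(t6: np.ndarray) -> np.ndarray:
    xx, yy, zz, xy, xz, yz = np.moveaxis(t6, -1, 0)
    T = np.empty(t6.shape[:-1] + (3, 3))
    T[..., 0, 0] = xx
    T[..., 1, 1] = yy
    T[..., 2, 2] = zz
    T[..., 0, 1] = T[..., 1, 0] = xy
    T[..., 0, 2] = T[..., 2, 0] = xz
    T[..., 1, 2] = T[..., 2, 1] = yz
    return T


def fit_dti(dwi: DWIDataset, mask: np.ndarray | None = None) -> TensorFit:
    """Log-linear least-squares tensor fit, voxel-wise.

    Negative eigenvalues are clamped at 0 before scalar computation (noise
    can break positivity). Voxels with non-positive signal anywhere are
    flagged invalid rather than aborting the fit.
    """
    scheme = dwi.scheme
    if len(scheme) < 7:
        raise ValueError("tensor fit needs at least 7 volumes (6 directions + b=0)")
    if np.sum(~scheme.b0_mask) < 6:
        raise ValueError("tensor fit needs at least 6 diffusion-weighted directions")
    if mask is None:
        mask = dwi.mask if dwi.mask is not None else np.ones(dwi.signal.shape[:3], bool)

    shape = dwi.signal.shape[:3]
    sig = dwi.signal[mask]  # (n_vox, n_vol)
    valid_vox = np.all(sig > 0, axis=1)
    X = design_matrix(scheme)
    pinv = np.linalg.pinv(X)

    coefs = np.zeros((sig.shape[0], 7))
    safe = np.where(sig > 0, sig, 1.0)
    coefs[valid_vox] = (pinv @ np.log(safe[valid_vox]).T).T

    T = _tensor_from_lower(coefs[:, :6])
    evals, evecs = np.linalg.eigh(T)
    # eigh returns ascending; flip to descending and clamp at zero
    evals = np.clip(evals[..., ::-1], 0.0, None)
    evecs = evecs[..., ::-1]
    fa, md, ad, rd = tensor_scalars(evals)

    def full(arr, fill=0.0):
        out = np.full(shape + arr.shape[1:], fill, dtype=float)
        out[mask] = arr
        return out

    valid_full = np.zeros(shape, bool)
    valid_full[mask] = valid_vox
    return TensorFit(
        tensors=full(coefs[:, :6]),
        eigenvalues=full(evals),
        eigenvectors=full(evecs),
        fa=full(fa),
        md=full(md),
        ad=full(ad),
        rd=full(rd),
        valid=valid_full,
        s0=full(np.exp(coefs[:, 6])),
    )
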