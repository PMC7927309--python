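"""Acquisition schemes, two-shell defaults, shell extraction, bval/bvec I/O."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

#: Default b=0 detection threshold (s/mm^2).
B0_THRESHOLD = 50.0

#: Default shell-matching tolerance (s/mm^2).
SHELL_TOL = 50.0


@dataclass
class AcquisitionScheme:
    """Per-volume b-values (s/mm^2) and unit gradient directions."""

    bvals: np.ndarray
    bvecs: np.ndarray
    b0_threshold: float = B0_THRESHOLD

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.shape != (self.bvals.size, 3):
            raise ValueError("bvecs must be (n_volumes, 3)")
        if np.any(self.bvals < 0):
            raise ValueError("b-values must be nonnegative")
        dw = ~self.b0_mask
        norms = np.linalg.norm(self.bvecs[dw], axis=1)
        if norms.size and np.any(np.abs(norms - 1.0) > 1e-6):
            warnings.warn("non-unit gradient vectors normalized", stacklevel=2)
            self.bvecs = self.bvecs.copy()
            self.bvecs[dw] /= norms[:, None]
        if not np.any(self.b0_mask):
            raise ValueError("scheme needs at least one b=0 volume for normalization")

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals <= self.b0_threshold

    def __len__(self) -> int:
        return int(self.bvals.size)

    def subset(self, index: np.ndarray) -> "AcquisitionScheme":
        return AcquisitionScheme(self.bvals[index], self.bvecs[index], self.b0_threshold)

    def shells(self, tol: float = SHELL_TOL) -> list[float]:
        """Distinct nonzero shell b-values, clustered within ``tol``."""
        out: list[float] = []
        for b in sorted(self.bvals[~self.b0_mask]):
            if not out or abs(b - out[-1]) > tol:
                out.append(float(b))
        return out


@dataclass
class DWIDataset:
    """4-D diffusion-weighted signal with its scheme and affine."""

    signal: np.ndarray
    scheme: AcquisitionScheme
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4-D (x, y, z, volume)")
        if self.signal.shape[-1] != len(self.scheme):
            raise ValueError(
                f"signal has {self.signal.shape[-1]} volumes but the scheme "
                f"defines {len(self.scheme)}"
            )
        self.affine = np.asarray(self.affine, dtype=float)
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.signal.shape[:3]:
                raise ValueError("mask shape must match the spatial grid")


def fibonacci_directions(n: int, hemisphere: bool = True) -> np.ndarray:
    """``n`` roughly uniform unit vectors from a Fibonacci spiral.

    Deterministic; adequate as a noncollinear gradient table for synthetic
    acquisitions (antipodal symmetry makes the hemisphere sufficient).
    """
    i = np.arange(n, dtype=float) + 0.5
    z = 1.0 - i / n if hemisphere else 1.0 - 2.0 * i / n
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def two_shell_scheme(
    n_high: int = 60, b_high: float = 3000.0, n_low: int = 35, b_low: float = 711.0, n_b0: int = 11
) -> AcquisitionScheme:
    """The default two-shell protocol: 60 directions at b=3000 s/mm^2,
    35 at b=711 s/mm^2, and 11 interleaved b=0 volumes."""
    bvals = np.concatenate(
        [np.zeros(n_b0), np.full(n_low, b_low), np.full(n_high, b_high)]
    )
    bvecs = np.vstack(
        [np.zeros((n_b0, 3)), fibonacci_directions(n_low), fibonacci_directions(n_high)]
    )
    return AcquisitionScheme(bvals, bvecs)


def extract_shell(dwi: DWIDataset, target_b: float, tol: float = SHELL_TOL) -> DWIDataset:
    """Subset one shell (plus all b=0 volumes) out of a multi-shell dataset."""
    scheme = dwi.scheme
    weighted = (~scheme.b0_mask) & (np.abs(scheme.bvals - target_b) <= tol)
    if not np.any(weighted):
        raise ValueError(f"no diffusion-weighted volumes within {tol} of b={target_b}")
    keep = np.where(weighted | scheme.b0_mask)[0]
    return DWIDataset(dwi.signal[..., keep], scheme.subset(keep), dwi.affine, dwi.mask)


def read_bvals_bvecs(bval_path, bvec_path) -> AcquisitionScheme:
    """Read FSL-dialect bval/bvec text files (whitespace-separated rows)."""
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    return AcquisitionScheme(bvals, bvecs)


def write_bvals_bvecs(scheme: AcquisitionScheme, bval_path, bvec_path) -> None:
    np.savetxt(bval_path, scheme.bvals[None, :], fmt="%.1f")
    np.savetxt(bvec_path, scheme.bvecs.T, fmt="%.8f")
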