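"""Watson-NODDI: forward signal model, voxel-wise fitting, and the derived
compartment fractions.

The model decomposes the normalized diffusion signal into three compartments:

    S/S0 = (1 - fiso) * [ficvf * A_ic + (1 - ficvf) * A_ec] + fiso * exp(-b*d_iso)

* ``A_ic`` — intra-neurite "sticks" with orientations Watson-distributed
  about a mean direction mu with concentration kappa; the stick attenuation
  exp(-b*d_par*(g.n)^2) is averaged over the Watson distribution by
  numeric quadrature on the sphere.
* ``A_ec`` — extra-neurite Gaussian compartment: an axisymmetric tensor with
  tortuosity-constrained perpendicular diffusivity d_perp = d_par*(1-ficvf),
  orientationally averaged over the same Watson distribution (which keeps it
  Gaussian with modified axial/radial diffusivities).
* free water — isotropic Gaussian diffusion at d_iso.

Fixed diffusivities follow the standard in-vivo defaults:
d_par = 1.7e-3 mm^2/s, d_iso = 3.0e-3 mm^2/s.

The orientation dispersion index maps concentration to [0, 1]:
ODI = (2/pi) * arctan(1/kappa).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import least_squares

from .core import ScalarVolume
from .dti import fit_dti
from .scheme import AcquisitionScheme, DWIDataset

D_PAR = 1.7e-3  # intrinsic parallel diffusivity, mm^2/s
D_ISO = 3.0e-3  # free-water diffusivity, mm^2/s

# Above this concentration the Watson distribution is treated as a delta
# (coherent stick); quadrature would need resolution ~1/sqrt(kappa).
_KAPPA_DELTA = 1.0e4

# Product quadrature: Gauss-Legendre in cos(theta), uniform periodic in phi.
_N_T = 50
_N_PHI = 32


def odi_from_kappa(kappa) -> np.ndarray | float:
    """ODI = (2/pi) * arctan(1/kappa); strictly decreasing, range (0, 1)."""
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa <= 0):
        raise ValueError("kappa must be positive")
    out = (2.0 / np.pi) * np.arctan(1.0 / kappa)
    return float(out) if out.ndim == 0 else out


def kappa_from_odi(odi) -> np.ndarray | float:
    odi = np.asarray(odi, dtype=float)
    if np.any((odi <= 0) | (odi >= 1)):
        raise ValueError("ODI must lie strictly inside (0, 1)")
    out = 1.0 / np.tan(np.pi * odi / 2.0)
    return float(out) if out.ndim == 0 else out


def reparameterize_compartments(ficvf, fiso) -> tuple:
    """Derive the voxel-level fractions (FICV, FECV, FISO).

    The fit parameterizes tissue by the intra-neurite fraction ``ficvf`` of
    the non-isotropic volume; re-expressing both tissue compartments as
    fractions of the whole voxel gives FICV = (1-fiso)*ficvf,
    FECV = (1-fiso)*(1-ficvf), FISO = fiso, which sum to 1 by construction.
    """
    ficvf_a = np.asarray(ficvf, dtype=float)
    fiso_a = np.asarray(fiso, dtype=float)
    if np.any((ficvf_a < 0) | (ficvf_a > 1)) or np.any((fiso_a < 0) | (fiso_a > 1)):
        raise ValueError("ficvf and fiso must lie in [0, 1]")
    ficv = (1.0 - fiso_a) * ficvf_a
    fecv = (1.0 - fiso_a) * (1.0 - ficvf_a)
    fiso_out = np.broadcast_to(fiso_a, ficv.shape).copy()
    if ficv.ndim == 0:
        return float(ficv), float(fecv), float(fiso_out)
    return ficv, fecv, fiso_out


def compartment_rgb(ficv: ScalarVolume, fecv: ScalarVolume, fiso: ScalarVolume) -> np.ndarray:
    """Stack the three fractions into a 4-D RGB composite:
    red = FECV, green = FICV, blue = FISO; values clipped to [0, 1]."""
    if not (ficv.data.shape == fecv.data.shape == fiso.data.shape):
        raise ValueError("compartment volumes must share one grid")
    if not (np.allclose(ficv.affine, fecv.affine) and np.allclose(ficv.affine, fiso.affine)):
        raise ValueError("compartment volumes must share one affine")
    rgb = np.stack([fecv.data, ficv.data, fiso.data], axis=-1)
    return np.clip(rgb, 0.0, 1.0)


@lru_cache(maxsize=1)
def _sphere_nodes() -> tuple:
    t, wt = np.polynomial.legendre.leggauss(_N_T)
    phi = 2.0 * np.pi * np.arange(_N_PHI) / _N_PHI
    return t, wt, np.cos(phi), np.sin(phi)


def _watson_row_weights(kappa: float) -> tuple:
    """Unnormalized Watson weights per cos(theta) node, and their sum."""
    t, wt, _, _ = _sphere_nodes()
    w = wt * np.exp(kappa * (t**2 - 1.0))  # shifted for overflow safety
    return w, float(w.sum())


def watson_tau1(kappa: float) -> float:
    """Mean squared cosine <(mu.n)^2> under Watson(kappa); 1/3 at kappa->0,
    1 at kappa->inf."""
    if kappa >= _KAPPA_DELTA:
        return 1.0
    t, _, _, _ = _sphere_nodes()
    w, tot = _watson_row_weights(kappa)
    return float(np.sum(w * t**2) / tot)


def _intra_attenuation(b: np.ndarray, cos_gm: np.ndarray, kappa: float, d_par: float) -> np.ndarray:
    """Watson-averaged stick attenuation for each volume.

    ``cos_gm`` is the cosine between each gradient and the mean direction.
    Exploits axial symmetry: in the mu-frame the gradient is
    (sin psi, 0, cos psi), and the average over orientation n reduces to a
    2-D quadrature in (cos theta, phi).
    """
    if kappa >= _KAPPA_DELTA:
        return np.exp(-b * d_par * cos_gm**2)
    t, _, cphi, sphi = _sphere_nodes()
    w, tot = _watson_row_weights(kappa)
    st = np.sqrt(np.clip(1.0 - t**2, 0.0, None))
    sin_gm = np.sqrt(np.clip(1.0 - cos_gm**2, 0.0, None))
    # (n_vol, n_t, n_phi): g.n = sin psi sin theta cos phi + cos psi cos theta
    dot = (
        sin_gm[:, None, None] * st[None, :, None] * cphi[None, None, :]
        + cos_gm[:, None, None] * t[None, :, None]
    )
    att = np.exp(-(b[:, None, None] * d_par) * dot**2)
    return att.mean(axis=2) @ w / tot


def noddi_signal(
    scheme: AcquisitionScheme,
    fiso: float,
    ficvf: float,
    kappa: float,
    mu: np.ndarray,
    d_par: float = D_PAR,
    d_iso: float = D_ISO,
) -> np.ndarray:
    """Normalized Watson-NODDI signal S/S0, one value per scheme volume.

    Equals 1 exactly at b=0; lies in (0, 1] everywhere in the valid domain.
    """
    if not (0.0 <= fiso <= 1.0 and 0.0 <= ficvf <= 1.0):
        raise ValueError("fiso and ficvf must lie in [0, 1]")
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    mu = np.asarray(mu, dtype=float).reshape(3)
    mu = mu / np.linalg.norm(mu)
    b = scheme.bvals
    cos_gm = scheme.bvecs @ mu

    a_ic = _intra_attenuation(b, cos_gm, kappa, d_par)

    d_perp = d_par * (1.0 - ficvf)  # tortuosity constraint
    tau1 = watson_tau1(kappa)
    d_axial = d_perp + (d_par - d_perp) * tau1
    d_radial = d_perp + (d_par - d_perp) * (1.0 - tau1) / 2.0
    a_ec = np.exp(-b * (d_radial + (d_axial - d_radial) * cos_gm**2))

    s = (1.0 - fiso) * (ficvf * a_ic + (1.0 - ficvf) * a_ec) + fiso * np.exp(-b * d_iso)
    # exact normalization at b=0 regardless of quadrature round-off
    s[scheme.b0_mask] = 1.0
    return s


@dataclass
class NoddiFit:
    """Voxel-wise Watson-NODDI estimates and derived maps."""

    fiso: np.ndarray
    ficvf: np.ndarray
    kappa: np.ndarray
    mu: np.ndarray
    odi: np.ndarray
    ficv: np.ndarray
    fecv: np.ndarray
    residual: np.ndarray
    valid: np.ndarray

    @property
    def fractions(self) -> tuple:
        return self.ficv, self.fecv, self.fiso


_FISO_GRID = np.array([0.0, 0.15, 0.3, 0.5, 0.7, 0.9])
_FICVF_GRID = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
_ODI_GRID = np.array([0.04, 0.1, 0.2, 0.35, 0.55, 0.8])

_BOUNDS_LO = np.array([0.0, 0.0, np.log(0.05), -np.pi, -np.pi])
_BOUNDS_HI = np.array([1.0, 1.0, np.log(128.0), np.pi, np.pi])


def _angles_to_unit(theta: float, phi: float) -> np.ndarray:
    return np.array(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
    )


def _fit_voxel(y: np.ndarray, scheme: AcquisitionScheme, mu0: np.ndarray) -> tuple:
    """Grid-initialized bounded least squares for one voxel.

    ``y`` is the normalized signal over all scheme volumes; ``mu0`` the
    orientation seed (tensor principal eigenvector). Deterministic.
    """
    b = scheme.bvals
    dw = ~scheme.b0_mask
    cos_gm = scheme.bvecs @ mu0

    # coarse init: kappa-dependent pieces computed once per ODI candidate
    best = (np.inf, 0.3, 0.5, 1.0)
    iso_att = np.exp(-b * D_ISO)
    for odi0 in _ODI_GRID:
        k0 = kappa_from_odi(float(odi0))
        a_ic = _intra_attenuation(b, cos_gm, k0, D_PAR)
        tau1 = watson_tau1(k0)
        for vf in _FICVF_GRID:
            d_perp = D_PAR * (1.0 - vf)
            d_ax = d_perp + (D_PAR - d_perp) * tau1
            d_rad = d_perp + (D_PAR - d_perp) * (1.0 - tau1) / 2.0
            a_ec = np.exp(-b * (d_rad + (d_ax - d_rad) * cos_gm**2))
            tissue = vf * a_ic + (1.0 - vf) * a_ec
            for fi in _FISO_GRID:
                model = (1.0 - fi) * tissue + fi * iso_att
                sse = float(np.sum((model[dw] - y[dw]) ** 2))
                if sse < best[0]:
                    best = (sse, fi, vf, k0)

    _, fi0, vf0, k0 = best
    theta0 = float(np.arccos(np.clip(mu0[2], -1.0, 1.0)))
    phi0 = float(np.arctan2(mu0[1], mu0[0]))
    x0 = np.clip(
        np.array([fi0, vf0, np.log(k0), theta0, phi0]), _BOUNDS_LO + 1e-9, _BOUNDS_HI - 1e-9
    )

    def residuals(x):
        fi, vf, logk, th, ph = x
        s = noddi_signal(scheme, fi, vf, float(np.exp(logk)), _angles_to_unit(th, ph))
        return s[dw] - y[dw]

    sol = least_squares(
        residuals, x0, bounds=(_BOUNDS_LO, _BOUNDS_HI), xtol=1e-12, ftol=1e-12, gtol=1e-12
    )
    fi, vf, logk, th, ph = sol.x
    return fi, vf, float(np.exp(logk)), _angles_to_unit(th, ph), float(np.linalg.norm(sol.fun))


def fit_noddi(dwi: DWIDataset, mask: np.ndarray | None = None) -> NoddiFit:
    """Fit the Watson-NODDI model voxel-wise on a (two-shell) dataset.

    Initialization is a coarse deterministic grid over (fiso, ficvf, ODI)
    with the orientation seeded from the tensor principal eigenvector,
    refined by bounded nonlinear least squares. No random restarts, so the
    result is a pure function of the data.
    """
    scheme = dwi.scheme
    if not np.any(~scheme.b0_mask):
        raise ValueError("scheme has only b=0 volumes; the model is unidentifiable")
    if len(scheme.shells()) < 2:
        warnings.warn(
            "single-shell data: NODDI parameters are poorly identified", stacklevel=2
        )
    if mask is None:
        mask = dwi.mask if dwi.mask is not None else np.ones(dwi.signal.shape[:3], bool)

    tensor = fit_dti(dwi, mask)
    shape = dwi.signal.shape[:3]
    fiso = np.zeros(shape)
    ficvf = np.zeros(shape)
    kappa = np.full(shape, np.nan)
    mu = np.zeros(shape + (3,))
    residual = np.full(shape, np.nan)
    valid = np.zeros(shape, bool)

    s0_all = dwi.signal[..., scheme.b0_mask].mean(axis=-1)
    for idx in zip(*np.nonzero(mask)):
        s0 = s0_all[idx]
        if not np.isfinite(s0) or s0 <= 0:
            continue
        y = dwi.signal[idx] / s0
        mu0 = tensor.principal_direction[idx]
        if np.linalg.norm(mu0) < 0.5:
            mu0 = np.array([0.0, 0.0, 1.0])
        fi, vf, k, m, rn = _fit_voxel(y, scheme, mu0)
        fiso[idx], ficvf[idx], kappa[idx] = fi, vf, k
        mu[idx] = m
        residual[idx] = rn
        valid[idx] = True

    with np.errstate(invalid="ignore", divide="ignore"):
        odi = np.where(valid, (2.0 / np.pi) * np.arctan(1.0 / kappa), np.nan)
    ficv = (1.0 - fiso) * ficvf
    fecv = (1.0 - fiso) * (1.0 - ficvf)
    return NoddiFit(
        fiso=fiso, ficvf=ficvf, kappa=kappa, mu=mu, odi=odi,
        ficv=ficv, fecv=fecv, residual=residual, valid=valid,
    )
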