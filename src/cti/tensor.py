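"""Diffusion tensor estimation and conductivity tensor assembly.

The water diffusion tensor D is fitted at the b=1000 s/mm^2 shell by weighted
log-linear least squares.  The extracellular tensor D_e rescales D so that its
mean diffusivity matches the extracellular diffusivity d_e from the
compartment fit (D and D_e share eigenvectors):

    D_e = eta * D,    eta = 3 * d_e / (d_xx + d_yy + d_zz)

The low-frequency conductivity tensor combines the high-frequency conductivity
with the compartment variables:

    C_LF = [ chi_e * sigma_HF / (chi_e * d_e + (1 - chi_e) * d_i * beta) ] * D_e

where beta = 0.41 is the ratio of ion concentrations between intra- and
extracellular spaces.  The isotropic-equivalent map is the geometric mean of
the conductivity tensor's eigenvalues (the isotropic tensor of equal ellipsoid
volume).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import UNDEFINED, DwiSeries, ScalarVolume, TensorVolume

__all__ = [
    "CtiConstants",
    "fit_diffusion_tensor",
    "eig_decompose",
    "extracellular_tensor",
    "conductivity_tensor",
    "isotropic_equivalent",
]

_SIGNAL_FLOOR = 1e-12


@dataclass(frozen=True)
class CtiConstants:
    """Physical constant of the conductivity model."""

    beta: float = 0.41  # intra/extracellular ion concentration ratio

    def __post_init__(self):
        if not 0 < self.beta <= 1:
            raise ValueError("beta must lie in (0, 1]")


def _design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Rows of -b * [gx^2, gy^2, gz^2, 2 gx gy, 2 gx gz, 2 gy gz]."""
    g = bvecs
    cols = np.stack(
        [
            g[:, 0] ** 2,
            g[:, 1] ** 2,
            g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1],
            2 * g[:, 0] * g[:, 2],
            2 * g[:, 1] * g[:, 2],
        ],
        axis=1,
    )
    return -bvals[:, None] * cols


def fit_diffusion_tensor(
    dwi: DwiSeries, shell: float = 1000.0, mask: np.ndarray | None = None
) -> tuple[TensorVolume, dict]:
    """Weighted log-linear least-squares tensor fit on one shell.

    Solves ln(S/S0) = -b g^T D g for the six tensor components, first by
    ordinary least squares and then with one reweighting pass using the
    squared predicted signals as weights (the optimal weighting for
    log-transformed Rician-free data).  Non-positive signals are floored at a
    small epsilon and counted.  Voxels need >= 6 usable directions.
    """
    idx = dwi.gtab.shell_indices(shell)
    if len(idx) < 6:
        raise ValueError(f"shell b={shell} has fewer than 6 directions")
    s0 = dwi.s0().data
    if mask is None:
        mask = np.isfinite(s0) & (s0 > 0)
    else:
        mask = np.asarray(mask, dtype=bool) & np.isfinite(s0) & (s0 > 0)

    bmat = _design_matrix(dwi.gtab.bvals[idx], dwi.gtab.bvecs[idx])  # (ndir, 6)
    sig = dwi.data[..., idx][mask]  # (nvox, ndir)
    n_floored = int(np.sum(sig <= 0))
    sig = np.maximum(sig, _SIGNAL_FLOOR)
    y = np.log(sig / s0[mask][:, None])

    pinv = np.linalg.pinv(bmat)
    d_ols = y @ pinv.T  # (nvox, 6)
    # one reweighting pass: weights are the squared predicted signals
    w = np.exp(2.0 * (d_ols @ bmat.T))
    a = np.einsum("vd,di,dj->vij", w, bmat, bmat)
    rhs = np.einsum("vd,di,vd->vi", w, bmat, y)
    d_wls = np.linalg.solve(a, rhs[..., None])[..., 0]

    out = np.full(dwi.shape + (6,), UNDEFINED)
    out[mask] = d_wls
    report = {"n_floored_signals": n_floored, "n_voxels": int(mask.sum())}
    return TensorVolume(out, dwi.affine.copy()), report


def eig_decompose(tensors: TensorVolume) -> tuple[np.ndarray, np.ndarray, int]:
    """Eigendecomposition of the symmetric tensor field.

    Returns eigenvalues sorted descending, shape (..., 3); the matching
    orthonormal eigenvectors as columns, shape (..., 3, 3); and the count of
    negative eigenvalues clamped to zero.  For symmetric positive
    semi-definite tensors this coincides with the singular value
    decomposition.
    """
    m = tensors.to_matrices()
    finite = np.all(np.isfinite(m), axis=(-2, -1))
    vals = np.full(m.shape[:-1], UNDEFINED)
    vecs = np.full(m.shape, UNDEFINED)
    if finite.any():
        ev, evec = np.linalg.eigh(m[finite])
        ev = ev[..., ::-1]  # descending
        evec = evec[..., ::-1]
        vals[finite] = ev
        vecs[finite] = evec
    n_clamped = int(np.sum(vals[finite] < 0)) if finite.any() else 0
    with np.errstate(invalid="ignore"):
        vals = np.where(np.isfinite(vals) & (vals < 0), 0.0, vals)
    return vals, vecs, n_clamped


def extracellular_tensor(
    d_tensor: TensorVolume, d_e: ScalarVolume
) -> tuple[TensorVolume, int]:
    """Rescale D so its mean diffusivity equals d_e (shared eigenvectors).

    eta = 3 d_e / trace(D); voxels with zero trace get a zero tensor and are
    counted in the returned flag count.
    """
    tr = d_tensor.trace()
    with np.errstate(divide="ignore", invalid="ignore"):
        eta = 3.0 * d_e.data / tr
    zero_trace = np.isfinite(tr) & (tr == 0)
    eta = np.where(zero_trace, 0.0, eta)
    out = d_tensor.data * eta[..., None]
    return TensorVolume(out, d_tensor.affine.copy()), int(zero_trace.sum())


def conductivity_tensor(
    sigma_hf: ScalarVolume,
    chi_e: ScalarVolume,
    d_e: ScalarVolume,
    d_i: ScalarVolume,
    de_tensor: TensorVolume,
    const: CtiConstants | None = None,
) -> tuple[TensorVolume, int]:
    """Low-frequency conductivity tensor (S/m).

    C_LF = [chi_e sigma_HF / (chi_e d_e + (1 - chi_e) d_i beta)] * D_e.
    Undefined inputs propagate; zero denominators mark the voxel undefined and
    are counted.
    """
    c = const or CtiConstants()
    denom = chi_e.data * d_e.data + (1.0 - chi_e.data) * d_i.data * c.beta
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = chi_e.data * sigma_hf.data / denom
    bad = np.isfinite(denom) & (denom <= 0)
    scale = np.where(bad, UNDEFINED, scale)
    out = de_tensor.data * scale[..., None]
    return TensorVolume(out, de_tensor.affine.copy()), int(bad.sum())


def isotropic_equivalent(c_tensor: TensorVolume) -> ScalarVolume:
    """Isotropic-equivalent conductivity: geometric mean of the eigenvalues.

    The returned scalar is the conductivity of the isotropic tensor whose
    ellipsoid volume matches the measured one; any zero eigenvalue yields 0.
    """
    vals, _, _ = eig_decompose(c_tensor)
    with np.errstate(invalid="ignore"):
        prod = np.prod(np.maximum(vals, 0.0), axis=-1)
    iso = np.cbrt(prod)
    iso = np.where(np.all(np.isfinite(vals), axis=-1), iso, UNDEFINED)
    return ScalarVolume(iso, c_tensor.affine.copy())
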