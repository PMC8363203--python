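"""Voxel-grid containers shared by every pipeline stage.

All volumes live on a common 3-D grid described by a NIfTI-style affine.
Undefined voxels (masked out, out of validity range, degenerate fits) are
represented by NaN and must be tolerated by every downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ScalarVolume",
    "TensorVolume",
    "GradientTable",
    "DwiSeries",
    "UNDEFINED",
    "TENSOR_COMPONENT_ORDER",
]

#: Marker for undefined voxels, propagated through all maps.
UNDEFINED = np.nan

#: Order of the six unique components of a symmetric 3x3 tensor.
TENSOR_COMPONENT_ORDER = ("xx", "yy", "zz", "xy", "xz", "yz")


def _default_affine(voxel_size=(1.0, 1.0, 1.0)) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


@dataclass
class ScalarVolume:
    """3-D scalar field on a voxel grid.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel values; NaN marks undefined voxels.
    affine : ndarray, shape (4, 4)
        Voxel-to-world transform (NIfTI convention).
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=_default_affine)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"ScalarVolume requires 3-D data, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm, from the affine column norms."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def same_grid(self, other: "ScalarVolume") -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine)

    def like(self, data: np.ndarray) -> "ScalarVolume":
        """New volume with the same grid geometry."""
        return ScalarVolume(np.asarray(data), self.affine.copy())


@dataclass
class TensorVolume:
    """Symmetric 3x3 tensor per voxel, stored as six unique components.

    Component order is (xx, yy, zz, xy, xz, yz) along the last axis.
    Units are mm^2/s for diffusion tensors and S/m for conductivity tensors.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=_default_affine)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4 or self.data.shape[-1] != 6:
            raise ValueError(
                f"TensorVolume requires data of shape (nx, ny, nz, 6), got {self.data.shape}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def to_matrices(self) -> np.ndarray:
        """Expand to full symmetric matrices, shape (nx, ny, nz, 3, 3)."""
        xx, yy, zz, xy, xz, yz = np.moveaxis(self.data, -1, 0)
        m = np.empty(self.shape + (3, 3))
        m[..., 0, 0] = xx
        m[..., 1, 1] = yy
        m[..., 2, 2] = zz
        m[..., 0, 1] = m[..., 1, 0] = xy
        m[..., 0, 2] = m[..., 2, 0] = xz
        m[..., 1, 2] = m[..., 2, 1] = yz
        return m

    @classmethod
    def from_matrices(cls, m: np.ndarray, affine=None) -> "TensorVolume":
        m = np.asarray(m)
        if m.shape[-2:] != (3, 3):
            raise ValueError("expected (..., 3, 3) matrices")
        comps = np.stack(
            [m[..., 0, 0], m[..., 1, 1], m[..., 2, 2], m[..., 0, 1], m[..., 0, 2], m[..., 1, 2]],
            axis=-1,
        )
        if affine is None:
            affine = _default_affine()
        return cls(comps, affine)

    def trace(self) -> np.ndarray:
        return self.data[..., 0] + self.data[..., 1] + self.data[..., 2]


@dataclass
class GradientTable:
    """Diffusion gradient table: b-values (s/mm^2) and unit direction vectors.

    Zero vectors are allowed (and required) only where b == 0.  Shells are
    identified by clustering b-values within +/- `shell_tolerance` s/mm^2.
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    shell_tolerance: float = 25.0

    def __post_init__(self):
        self.bvals = np.atleast_1d(np.asarray(self.bvals, dtype=float))
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.ndim != 2 or self.bvecs.shape[1] != 3:
            raise ValueError(f"bvecs must be (N, 3), got {self.bvecs.shape}")
        if len(self.bvals) != len(self.bvecs):
            raise ValueError(
                f"bvals ({len(self.bvals)}) and bvecs ({len(self.bvecs)}) length mismatch"
            )
        if np.any(self.bvals < 0):
            raise ValueError("negative b-value")
        norms = np.linalg.norm(self.bvecs, axis=1)
        nz = self.bvals > self.shell_tolerance
        if np.any(np.abs(norms[nz] - 1.0) > 1e-6):
            raise ValueError("bvecs at b > 0 must have unit norm (within 1e-6)")
        if np.any(norms[~nz] > 1e-6):
            raise ValueError("bvecs at b == 0 must be zero vectors")

    def __len__(self) -> int:
        return len(self.bvals)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals <= self.shell_tolerance

    def shells(self) -> dict[float, np.ndarray]:
        """Nonzero shells as {representative b-value: volume index array}."""
        out: dict[float, np.ndarray] = {}
        remaining = np.where(~self.b0_mask)[0]
        remaining = remaining[np.argsort(self.bvals[remaining], kind="stable")]
        while remaining.size:
            b0 = self.bvals[remaining[0]]
            in_shell = np.abs(self.bvals[remaining] - b0) <= self.shell_tolerance
            idx = remaining[in_shell]
            out[float(np.mean(self.bvals[idx]))] = np.sort(idx)
            remaining = remaining[~in_shell]
        return out

    def shell_indices(self, b: float) -> np.ndarray:
        """Volume indices of the shell containing b-value ``b``."""
        for rep, idx in self.shells().items():
            if abs(rep - b) <= self.shell_tolerance:
                return idx
        raise KeyError(f"no shell at b={b} s/mm^2")


@dataclass
class DwiSeries:
    """4-D diffusion-weighted series plus its gradient table."""

    data: np.ndarray
    gtab: GradientTable
    affine: np.ndarray = field(default_factory=_default_affine)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"DWI data must be 4-D, got shape {self.data.shape}")
        if self.data.shape[-1] != len(self.gtab):
            raise ValueError(
                f"volume count {self.data.shape[-1]} does not match gradient table "
                f"length {len(self.gtab)}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def s0(self) -> ScalarVolume:
        """Mean of all b=0 volumes."""
        b0 = self.gtab.b0_mask
        if not b0.any():
            raise ValueError("no b=0 volume in series")
        return ScalarVolume(self.data[..., b0].mean(axis=-1), self.affine.copy())
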