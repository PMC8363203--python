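"""Water-content mapping and high-frequency conductivity.

The water volume fraction W is obtained from the ratio of two spin-echo images
acquired at different repetition times (the ratio is a surrogate for T1
weighting), through an exponential transfer function calibrated for typical
GM/WM/CSF water concentrations at 3 T:

    W = w1 * exp(-w2 * I_r),        I_r = S(TR1) / S(TR2)

A second exponential transfer function maps water content to conductivity at
the Larmor frequency (high frequency, ~128 MHz at 3 T):

    sigma_HF = c1 + c2 * exp(c3 * W),    valid for 0.6 <= W <= 1

Voxels whose W falls outside the validity range are masked to NaN rather than
extrapolated (the exponential would amplify errors) and counted in a report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import UNDEFINED, ScalarVolume

__all__ = [
    "WaterMapParams",
    "HfConductivityParams",
    "image_ratio",
    "water_from_ratio",
    "hf_conductivity",
]


@dataclass(frozen=True)
class WaterMapParams:
    """Coefficients of the spin-echo-ratio -> water transfer function."""

    w1: float = 1.525  # dimensionless
    w2: float = 1.443  # dimensionless

    def __post_init__(self):
        if self.w1 <= 0 or self.w2 <= 0:
            raise ValueError("w1 and w2 must be positive")


@dataclass(frozen=True)
class HfConductivityParams:
    """Coefficients and validity range of the water -> sigma_HF transfer
    function.  Re-optimizable when reference conductivities are available."""

    c1: float = 0.286  # S/m
    c2: float = 1.526e-5  # S/m
    c3: float = 11.852  # dimensionless
    valid_range: tuple[float, float] = (0.6, 1.0)

    def __post_init__(self):
        if self.c2 <= 0 or self.c3 <= 0:
            raise ValueError("c2 and c3 must be positive")
        if self.valid_range[0] >= self.valid_range[1]:
            raise ValueError("valid_range bounds must be ordered")


def image_ratio(
    se_tr1: ScalarVolume, se_tr2: ScalarVolume, mask: np.ndarray | None = None
) -> ScalarVolume:
    """Voxelwise ratio I_r = S(TR1) / S(TR2); NaN outside the mask.

    Raises on grid mismatch or a zero denominator inside the mask.
    """
    if not se_tr1.same_grid(se_tr2):
        raise ValueError("spin-echo images are not on the same grid")
    if mask is None:
        mask = np.isfinite(se_tr2.data) & (se_tr2.data != 0)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != se_tr1.shape:
            raise ValueError("mask shape does not match image grid")
        if np.any(se_tr2.data[mask] == 0):
            raise ValueError("zero denominator inside mask")
    out = np.full(se_tr1.shape, UNDEFINED)
    out[mask] = se_tr1.data[mask] / se_tr2.data[mask]
    return se_tr1.like(out)


def water_from_ratio(i_r: ScalarVolume, params: WaterMapParams | None = None) -> ScalarVolume:
    """Water map W = w1 * exp(-w2 * I_r); strictly decreasing in the ratio."""
    p = params or WaterMapParams()
    return i_r.like(p.w1 * np.exp(-p.w2 * i_r.data))


def hf_conductivity(
    w: ScalarVolume, params: HfConductivityParams | None = None
) -> tuple[ScalarVolume, int]:
    """High-frequency conductivity sigma_HF = c1 + c2 * exp(c3 * W), in S/m.

    Voxels with W outside the validity range are set to NaN.  Returns the map
    and the count of defined voxels that fell out of range.
    """
    p = params or HfConductivityParams()
    lo, hi = p.valid_range
    data = w.data
    with np.errstate(invalid="ignore"):
        out_of_range = np.isfinite(data) & ((data < lo) | (data > hi))
        sigma = p.c1 + p.c2 * np.exp(p.c3 * data)
    sigma = np.where(out_of_range, UNDEFINED, sigma)
    return w.like(sigma), int(out_of_range.sum())
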