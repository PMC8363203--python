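"""Tissue statistics and spatial-resolution assessment of conductivity maps.

CSF is segmented directly on the high-frequency conductivity map by a 2 S/m
threshold (CSF conductivity is far above GM/WM).  Per-tissue distributions are
summarized by mean, standard deviation and coefficient of variation; the
coefficient of joint variation between the GM and WM distributions measures
their overlap (how well the map separates the two tissues).

Achieved spatial resolution is probed by the averaged power spectral density
of image lines along one axis, in dB with the DC bin removed, and by comparing
against band-limited references obtained by down/up-sampling the map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import periodogram
from skimage.transform import resize

from .core import ScalarVolume

__all__ = [
    "TissueStats",
    "PsdProfile",
    "csf_mask_from_sigma",
    "tissue_distributions",
    "cjv",
    "psd_profile",
    "resample_resolution_reference",
]

DB_FLOOR = -120.0  # dB value reported for zero-power bins


@dataclass
class TissueStats:
    tissue: str
    mean: float  # S/m
    std: float  # S/m (population)
    cv: float  # percent
    n_voxels: int


@dataclass
class PsdProfile:
    frequencies: np.ndarray  # cycles/mm
    power_db: np.ndarray  # DC bin removed
    axis: int
    n_lines: int


def csf_mask_from_sigma(sigma_hf: ScalarVolume, threshold: float = 2.0) -> np.ndarray:
    """CSF segmentation: sigma_HF >= threshold (S/m). NaN voxels excluded."""
    with np.errstate(invalid="ignore"):
        return np.isfinite(sigma_hf.data) & (sigma_hf.data >= threshold)


def tissue_distributions(
    sigma_map: ScalarVolume, masks: dict[str, np.ndarray], ddof: int = 0
) -> tuple[list[TissueStats], dict[str, np.ndarray]]:
    """Per-tissue mean/std/CV over defined in-mask voxels.

    ``masks`` maps tissue name to a boolean mask; masks must be disjoint.
    Population std by default (``ddof=0``).  Returns the stats and the raw
    per-tissue value distributions.
    """
    names = list(masks)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if np.any(masks[a] & masks[b]):
                raise ValueError(f"masks {a!r} and {b!r} overlap")
    stats, dists = [], {}
    for name in names:
        vals = sigma_map.data[np.asarray(masks[name], dtype=bool)]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(f"mask {name!r} contains no defined voxels")
        mean = float(vals.mean())
        std = float(vals.std(ddof=ddof))
        cv = 100.0 * std / mean if mean != 0 else np.inf
        stats.append(TissueStats(name, mean, std, cv, int(vals.size)))
        dists[name] = vals
    return stats, dists


def cjv(stats_gm: TissueStats, stats_wm: TissueStats) -> float:
    """Coefficient of joint variation between GM and WM, in percent:

        CJV = (std_GM + std_WM) / (mean_GM - mean_WM)

    Reported in GM-minus-WM orientation by contract (positive when GM has the
    larger mean).  Raises if the means coincide.
    """
    denom = stats_gm.mean - stats_wm.mean
    if denom == 0:
        raise ValueError("GM and WM means are equal; CJV undefined")
    return 100.0 * (stats_gm.std + stats_wm.std) / denom


def psd_profile(
    volume: ScalarVolume,
    axis: int = 1,
    mask: np.ndarray | None = None,
    min_samples: int = 16,
) -> PsdProfile:
    """Averaged line periodogram along ``axis``, in dB with DC removed.

    Every line with at least ``min_samples`` in-mask voxels contributes: its
    in-mask samples are compacted into a sequence and zero-padded to the axis
    length so all lines share one frequency grid; line periodograms are
    averaged, converted to 10*log10, and the DC bin is dropped (this
    normalizes overall level differences between maps).  Zero-power bins are
    floored at -120 dB.
    """
    data = volume.data
    if mask is None:
        mask = np.isfinite(data)
    else:
        mask = np.asarray(mask, dtype=bool) & np.isfinite(data)
    spacing = volume.voxel_size[axis]
    nfft = data.shape[axis]

    moved = np.moveaxis(data, axis, -1)
    mask_m = np.moveaxis(mask, axis, -1)
    lines = moved.reshape(-1, nfft)
    lmask = mask_m.reshape(-1, nfft)

    psds = []
    for vals, m in zip(lines, lmask):
        if m.sum() < min_samples:
            continue
        seq = np.zeros(nfft)
        seq[: m.sum()] = vals[m]
        freqs, p = periodogram(seq, fs=1.0 / spacing, nfft=nfft, detrend=False)
        psds.append(p)
    if not psds:
        raise ValueError("no usable lines (too few in-mask samples)")
    avg = np.mean(psds, axis=0)
    with np.errstate(divide="ignore"):
        db = 10.0 * np.log10(avg)
    db = np.maximum(db, DB_FLOOR)
    return PsdProfile(frequencies=freqs[1:], power_db=db[1:], axis=axis, n_lines=len(psds))


def resample_resolution_reference(
    volume: ScalarVolume, target_spacing: float
) -> ScalarVolume:
    """Band-limited reference: downsample in-plane to ``target_spacing`` (mm)
    and linearly upsample back to the native grid.

    Emulates a map acquired at coarser in-plane resolution on the same grid.
    In-plane means the first two axes; linear interpolation both ways.
    """
    native = volume.voxel_size[:2]
    if np.any(target_spacing < native - 1e-9):
        raise ValueError("target spacing must be >= native spacing")
    shape = volume.shape
    coarse_shape = (
        max(int(round(shape[0] * native[0] / target_spacing)), 2),
        max(int(round(shape[1] * native[1] / target_spacing)), 2),
        shape[2],
    )
    down = resize(
        volume.data, coarse_shape, order=1, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )
    up = resize(
        down, shape, order=1, mode="edge", anti_aliasing=False, preserve_range=True
    )
    return volume.like(up)
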