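"""Synthetic brain phantom: spin-echo pairs and multi-shell DWI with known truth.

The phantom is a concentric-shell "brain" (CSF rim, GM ribbon, WM core, plus a
CSF ventricle block) on a regular grid.  Per-tissue ground truth covers water
content, T1, proton density and the three-compartment diffusion parameters, so
every downstream stage of the conductivity pipeline can be exercised against
known values without downloading data.

Two DWI forward models are provided: ``spherical`` emits the
direction-independent three-compartment signal (so the direction average equals
the model exactly), and ``tensor`` emits a mono-exponential Gaussian signal
from a ground-truth tensor per voxel, for testing the tensor-fit path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import DwiSeries, GradientTable, ScalarVolume
from .microstructure import ModelConstants, predict_signal
from .water import WaterMapParams

__all__ = [
    "TissueParams",
    "PhantomSpec",
    "default_phantom_spec",
    "make_default_phantom",
    "simulate_se_pair",
    "simulate_dwi",
    "add_noise",
    "make_gradient_table",
    "LABEL_BACKGROUND",
    "LABEL_GM",
    "LABEL_WM",
    "LABEL_CSF",
]

LABEL_BACKGROUND, LABEL_GM, LABEL_WM, LABEL_CSF = 0, 1, 2, 3
_TISSUE_LABELS = {"GM": LABEL_GM, "WM": LABEL_WM, "CSF": LABEL_CSF}


@dataclass
class TissueParams:
    """Ground-truth parameters for one tissue class.

    ``W_target`` must lie in [0.6, 1], the validity range of the
    water-to-conductivity transfer function.  ``d_e_star`` doubles as the mean
    diffusivity of the ground-truth tensor in tensor mode.
    """

    W_target: float  # water volume fraction
    T1: float  # longitudinal relaxation time, s
    proton_density: float  # arbitrary units
    v_ic: float  # intracellular volume fraction
    v_iso: float  # isotropic (free-water) volume fraction
    d_e_star: float  # extracellular mean diffusivity, mm^2/s
    principal_orientation: tuple[float, float, float] = (1.0, 0.0, 0.0)
    fractional_eccentricity: float = 0.0

    def __post_init__(self):
        if not 0.6 <= self.W_target <= 1.0:
            raise ValueError(f"W_target={self.W_target} outside [0.6, 1]")
        if self.T1 <= 0:
            raise ValueError("T1 must be positive")
        for name in ("v_ic", "v_iso"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.d_e_star < 0:
            raise ValueError("d_e_star must be >= 0")
        if self.fractional_eccentricity < 0:
            raise ValueError("fractional_eccentricity must be >= 0")
        n = np.linalg.norm(self.principal_orientation)
        if n == 0:
            raise ValueError("principal_orientation must be nonzero")
        self.principal_orientation = tuple(np.asarray(self.principal_orientation) / n)

    def tensor(self) -> np.ndarray:
        """Ground-truth diffusion tensor (3x3) with trace 3 * d_e_star.

        Eigenvalues are md*(1+fe), md*(1-fe/2), md*(1-fe/2) about the principal
        orientation, so fractional_eccentricity=0 gives an isotropic tensor.
        """
        md, fe = self.d_e_star, self.fractional_eccentricity
        e1 = np.asarray(self.principal_orientation)
        # complete an orthonormal basis around e1
        helper = np.array([0.0, 0.0, 1.0]) if abs(e1[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
        e2 = np.cross(e1, helper)
        e2 /= np.linalg.norm(e2)
        e3 = np.cross(e1, e2)
        lam = md * np.array([1.0 + fe, 1.0 - fe / 2.0, 1.0 - fe / 2.0])
        basis = np.stack([e1, e2, e3], axis=1)
        return basis @ np.diag(lam) @ basis.T


def default_phantom_spec(
    grid_shape=(32, 32, 32),
    voxel_size=(1.0, 1.0, 1.0),
    noise_model: str = "none",
    noise_sigma: float | None = None,
    seed: int = 0,
) -> "PhantomSpec":
    """Phantom with literature-typical 3 T tissue values.

    The defaults place every tissue's water content inside the transfer
    function's validity range and reproduce commonly reported conductivities
    (GM ~0.63, WM ~0.37, CSF ~2.2 S/m at high frequency).
    """
    tissues = {
        "GM": TissueParams(W_target=0.846, T1=1.30, proton_density=1.0,
                           v_ic=0.4, v_iso=0.2, d_e_star=1.2e-3),
        "WM": TissueParams(W_target=0.727, T1=0.83, proton_density=0.9,
                           v_ic=0.6, v_iso=0.2, d_e_star=0.8e-3,
                           principal_orientation=(1.0, 0.0, 0.0),
                           fractional_eccentricity=0.5),
        "CSF": TissueParams(W_target=0.990, T1=4.0, proton_density=1.1,
                            v_ic=0.0, v_iso=1.0, d_e_star=3.0e-3),
    }
    return PhantomSpec(
        grid_shape=tuple(grid_shape),
        voxel_size=tuple(voxel_size),
        tissues=tissues,
        noise_model=noise_model,
        noise_sigma=noise_sigma,
        seed=seed,
    )


@dataclass
class PhantomSpec:
    """Geometry, per-tissue ground truth and noise settings for the phantom."""

    grid_shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    tissues: dict[str, TissueParams]
    noise_model: str = "none"  # none | gaussian | rician
    noise_sigma: float | None = None  # None: SNR ~ 40 at b=0
    seed: int = 0
    label_map: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.noise_model not in ("none", "gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.noise_sigma is not None and self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        missing = set(_TISSUE_LABELS) - set(self.tissues)
        if missing:
            raise ValueError(f"missing tissue definitions: {sorted(missing)}")

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size
        return aff

    def labels(self) -> ScalarVolume:
        """Label geometry; built on first use if not supplied."""
        if self.label_map is None:
            self.label_map = make_default_phantom(self).data
        return ScalarVolume(self.label_map, self.affine)

    def sigma(self) -> float:
        """Noise standard deviation in signal units."""
        if self.noise_sigma is not None:
            return float(self.noise_sigma)
        pd = max(t.proton_density for t in self.tissues.values())
        return pd / 40.0  # SNR ~ 40 at b=0

    def parameter_map(self, name: str, background=np.nan) -> ScalarVolume:
        """Voxelwise ground-truth map of a per-tissue scalar parameter."""
        labels = self.labels().data
        out = np.full(self.grid_shape, background, dtype=float)
        for tissue, lab in _TISSUE_LABELS.items():
            out[labels == lab] = getattr(self.tissues[tissue], name)
        return ScalarVolume(out, self.affine)

    def tissue_mask(self, tissue: str) -> np.ndarray:
        return self.labels().data == _TISSUE_LABELS[tissue]

    def brain_mask(self) -> np.ndarray:
        return self.labels().data != LABEL_BACKGROUND


def make_default_phantom(spec: PhantomSpec) -> ScalarVolume:
    """Concentric-shell geometry: CSF rim, GM ribbon, WM core, CSF ventricle.

    Deterministic for a given spec.  Raises if the grid is smaller than 16
    voxels along any axis (too small to contain all three tissues).
    """
    shape = np.asarray(spec.grid_shape)
    if np.any(shape < 16):
        raise ValueError(f"grid {tuple(shape)} too small; need >= 16 voxels per axis")
    center = (shape - 1) / 2.0
    ijk = np.stack(np.meshgrid(*(np.arange(n) for n in shape), indexing="ij"), axis=-1)
    # per-axis normalized radius: the brain is an ellipsoid filling the grid
    r = np.linalg.norm((ijk - center) / (shape / 2.0), axis=-1)

    labels = np.zeros(tuple(shape), dtype=np.int16)
    labels[r <= 0.90] = LABEL_CSF  # outer CSF rim
    labels[r <= 0.76] = LABEL_GM  # cortical ribbon
    labels[r <= 0.56] = LABEL_WM  # WM core
    # CSF ventricle block inside the WM core
    half = np.maximum((shape * 0.06).astype(int), 1)
    lo = (center - half).astype(int)
    hi = (center + half).astype(int) + 1
    labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = LABEL_CSF

    for lab in (LABEL_GM, LABEL_WM, LABEL_CSF):
        if not np.any(labels == lab):
            raise ValueError("grid too small to contain all three tissues")
    return ScalarVolume(labels, spec.affine)


def simulate_se_pair(
    spec: PhantomSpec,
    tr1: float = 0.7,
    tr2: float = 3.0,
    calibrated: bool = False,
    water_params: WaterMapParams | None = None,
) -> tuple[ScalarVolume, ScalarVolume]:
    """Simulate the two spin-echo magnitude images at TR1 < TR2.

    Default mode uses saturation recovery S(TR) = PD * (1 - exp(-TR/T1)) with a
    shared TE that cancels in the ratio.  In ``calibrated`` mode the TR1 image
    is synthesized so that the image ratio inverts the water transfer function
    exactly at ``W_target``, making the water round trip exact (noise off).
    """
    if tr1 >= tr2:
        raise ValueError("TR1 must be smaller than TR2")
    labels = spec.labels().data
    pd = spec.parameter_map("proton_density", background=0.0).data
    t1 = spec.parameter_map("T1", background=np.inf).data

    s2 = pd * (1.0 - np.exp(-tr2 / t1))
    if calibrated:
        wp = water_params or WaterMapParams()
        ratio = np.zeros_like(s2)
        for tissue, lab in _TISSUE_LABELS.items():
            w = spec.tissues[tissue].W_target
            if not 0.0 < w < wp.w1:
                raise ValueError(
                    f"W_target={w} for {tissue} outside (0, {wp.w1}); "
                    "water transfer function not invertible"
                )
            ratio[labels == lab] = -np.log(w / wp.w1) / wp.w2
        s1 = ratio * s2
    else:
        s1 = pd * (1.0 - np.exp(-tr1 / t1))

    if spec.noise_model != "none":
        # Gaussian is the conventional choice for high-SNR SE magnitude data
        model = "gaussian" if spec.noise_model == "rician" else spec.noise_model
        s1 = add_noise(s1, model, spec.sigma(), spec.seed)
        s2 = add_noise(s2, model, spec.sigma(), spec.seed + 1)
    aff = spec.affine
    return ScalarVolume(s1, aff), ScalarVolume(s2, aff.copy())


def simulate_dwi(
    spec: PhantomSpec,
    gtab: GradientTable,
    mode: str = "spherical",
    const: ModelConstants | None = None,
) -> DwiSeries:
    """Simulate a multi-shell DWI series from the phantom ground truth.

    ``spherical`` evaluates the direction-independent three-compartment signal
    per voxel at each b-value, so shell direction averages match the model to
    machine precision.  ``tensor`` evaluates S = S0 * exp(-b g^T D g) with the
    per-tissue ground-truth tensor.
    """
    if mode not in ("spherical", "tensor"):
        raise ValueError(f"unknown DWI mode {mode!r}")
    const = const or ModelConstants()
    labels = spec.labels().data
    s0 = spec.parameter_map("proton_density", background=0.0).data
    nvol = len(gtab)
    data = np.zeros(spec.grid_shape + (nvol,), dtype=float)

    if mode == "spherical":
        for tissue, lab in _TISSUE_LABELS.items():
            t = spec.tissues[tissue]
            atten = predict_signal(gtab.bvals, t.v_ic, t.v_iso, t.d_e_star, const)
            data[labels == lab] = atten  # broadcasts to (n_voxels, nvol)
    else:
        for tissue, lab in _TISSUE_LABELS.items():
            d = spec.tissues[tissue].tensor()
            quad = np.einsum("vi,ij,vj->v", gtab.bvecs, d, gtab.bvecs)
            data[labels == lab] = np.exp(-gtab.bvals * quad)
    data *= s0[..., None]

    if spec.noise_model != "none":
        model = "rician" if spec.noise_model == "rician" else spec.noise_model
        data = add_noise(data, model, spec.sigma(), spec.seed + 2)
    return DwiSeries(data, gtab, spec.affine)


def add_noise(volume, model: str, sigma: float, seed: int):
    """Add seeded Gaussian or Rician noise; accepts arrays or ScalarVolumes."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if model not in ("none", "gaussian", "rician"):
        raise ValueError(f"unknown noise model {model!r}")
    is_vol = isinstance(volume, ScalarVolume)
    data = volume.data if is_vol else np.asarray(volume, dtype=float)
    if sigma == 0 or model == "none":
        out = data.copy()
    else:
        rng = np.random.default_rng(seed)
        if model == "gaussian":
            out = data + rng.normal(0.0, sigma, data.shape)
        else:  # rician: magnitude of complex signal + circular Gaussian noise
            re = data + rng.normal(0.0, sigma, data.shape)
            im = rng.normal(0.0, sigma, data.shape)
            out = np.hypot(re, im)
    return volume.like(out) if is_vol else out


def make_gradient_table(
    bvals=(50.0, 150.0, 1000.0, 1800.0, 4500.0),
    n_dirs: int = 16,
    n_b0: int = 1,
) -> GradientTable:
    """Gradient table matching the acquisition protocol: one b0 plus five
    shells sharing the same ``n_dirs`` directions (matched across shells).

    Directions are a deterministic Fibonacci-sphere set, well spread and
    reproducible.
    """
    dirs = _fibonacci_sphere(n_dirs)
    all_b = [0.0] * n_b0
    all_v = [np.zeros(3)] * n_b0
    for b in bvals:
        all_b.extend([float(b)] * n_dirs)
        all_v.extend(dirs)
    return GradientTable(np.array(all_b), np.vstack(all_v))


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    v = np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )
    return v / np.linalg.norm(v, axis=1, keepdims=True)
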