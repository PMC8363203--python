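"""Three-compartment diffusion model: direction-averaged fit with leave-one-out
maximum-intensity-projection (MIP) stabilization.

The model expresses the direction-averaged diffusion signal at b-value b as a
mixture of intracellular, extracellular and isotropic (free-water) pools:

    S_b / S_0 = (1 - v_iso) * [ v_ic  * exp(-b * v_ic * d_ic)
                              + (1 - v_ic) * exp(-b * (1 - v_ic) * d_e*) ]
              + v_iso * exp(-b * d_iso)

with fixed intracellular and free-water diffusivities d_ic, d_iso and three
free parameters: the intracellular volume fraction v_ic in [0, 1], the
isotropic volume fraction v_iso in [0, 1], and the extracellular mean
diffusivity d_e* >= 0.

Fitting a 3-parameter model to a handful of shell averages is fragile, so the
fit is repeated once per leave-one-out subset of the gradient directions
(n subsets of n-1 directions each, the same excluded index at every shell) and
the final map is the voxelwise maximum over the runs.  Residual low-value
artifacts are labeled by a physiological cutoff and re-filled by slice-wise
Delaunay interpolation.

The bounded minimization works on transformed parameters — a sigmoid for the
two volume fractions and a softplus for d_e* — which maps the constraint box
onto R^3 and avoids projection artifacts at the bounds.  Because the objective
is multimodal (local minima trade v_ic against d_e* along flat valleys), each
voxel is minimized by Levenberg-Marquardt with an analytic Jacobian from
several starting points: the conventional initial guess plus the best
coarse-grid point within each v_ic stripe; the lowest objective wins.  The
iteration is batched over voxels for speed; voxels are independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import griddata

from .core import UNDEFINED, DwiSeries, ScalarVolume

__all__ = [
    "ModelConstants",
    "FitOptions",
    "CompartmentFit",
    "direction_average",
    "predict_signal",
    "fit_voxel",
    "fit_compartments",
    "fit_loo_mip",
    "label_and_impute",
    "derive_lf_params",
]


@dataclass(frozen=True)
class ModelConstants:
    """Fixed diffusivities of the compartment model (mm^2/s), taken from the
    literature rather than fitted, to stabilize the fit."""

    d_ic: float = 1.7e-3  # intracellular diffusivity
    d_iso: float = 3.0e-3  # isotropic (free) water diffusivity

    def __post_init__(self):
        if self.d_ic <= 0 or self.d_iso <= 0:
            raise ValueError("diffusivities must be positive")


@dataclass(frozen=True)
class FitOptions:
    """Settings for the per-voxel bounded minimization."""

    ftol: float = 1e-10  # relative objective-improvement tolerance
    max_iter: int = 2000  # per starting point
    init_v_ic: float = 0.0
    init_v_iso: float = 0.5
    init_d_e_star: float = 0.0  # mm^2/s


@dataclass
class CompartmentFit:
    """Per-voxel result of the three-compartment fit."""

    v_ic: float
    v_iso: float
    d_e_star: float
    objective: float  # residual sum of squares on S/S0
    converged: bool
    n_iter: int


def direction_average(
    dwi: DwiSeries, shell: float, subset: np.ndarray | None = None
) -> ScalarVolume:
    """Arithmetic mean of the shell's diffusion volumes over the selected
    gradient directions, per voxel.

    ``subset`` indexes positions within the shell's direction list (used by the
    leave-one-out runs); default is all directions.
    """
    idx = dwi.gtab.shell_indices(shell)
    if subset is not None:
        subset = np.asarray(subset, dtype=int)
        if subset.size == 0:
            raise ValueError("empty direction subset")
        idx = idx[subset]
    return ScalarVolume(dwi.data[..., idx].mean(axis=-1), dwi.affine.copy())


def predict_signal(b, v_ic, v_iso, d_e_star, const: ModelConstants | None = None):
    """Normalized direction-averaged signal S_b / S_0 of the compartment model.

    Broadcasts over b and over parameter arrays.  Note the volume fractions
    appear inside the exponents (apparent per-compartment diffusivities scale
    with the occupancy of the compartment).
    """
    c = const or ModelConstants()
    b = np.asarray(b, dtype=float)
    v_ic = np.asarray(v_ic, dtype=float)
    v_iso = np.asarray(v_iso, dtype=float)
    d_e_star = np.asarray(d_e_star, dtype=float)
    intra = v_ic * np.exp(-b * v_ic * c.d_ic)
    extra = (1.0 - v_ic) * np.exp(-b * (1.0 - v_ic) * d_e_star)
    iso = np.exp(-b * c.d_iso)
    return (1.0 - v_iso) * (intra + extra) + v_iso * iso


# ---------------------------------------------------------------------------
# bounded minimization: transformed parameters, multistart Levenberg-Marquardt

_D_SCALE = 1.0e-3  # mm^2/s; natural magnitude of d_e*
_INIT_EPS = 1e-2  # boundary inits are nudged inside the open box for the transform
#: v_ic stripes used to seed one start per basin: the objective's local minima
#: trade v_ic against d_e* along flat valleys, so bracketing v_ic is what makes
#: the multistart reliable.
_VIC_STRIPES = ((0.0, 0.2), (0.2, 0.4), (0.4, 0.6), (0.6, 0.8), (0.8, 1.0))


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _logit(p):
    return np.log(p / (1.0 - p))


def _softplus(x):
    return np.logaddexp(0.0, x)


def _inv_softplus(y):
    return y + np.log(-np.expm1(-y))


def _to_params(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Transformed coordinates -> (v_ic, v_iso, d_e_star)."""
    return _sigmoid(x[..., 0]), _sigmoid(x[..., 1]), _softplus(x[..., 2]) * _D_SCALE


def _initial_vertex(opts: FitOptions) -> np.ndarray:
    v_ic = min(max(opts.init_v_ic, _INIT_EPS), 1.0 - _INIT_EPS)
    v_iso = min(max(opts.init_v_iso, _INIT_EPS), 1.0 - _INIT_EPS)
    de = max(opts.init_d_e_star / _D_SCALE, _INIT_EPS)
    return np.array([_logit(v_ic), _logit(v_iso), _inv_softplus(de)])


def fit_compartments(
    bvals: np.ndarray,
    sbar: np.ndarray,
    const: ModelConstants | None = None,
    opts: FitOptions | None = None,
) -> dict[str, np.ndarray]:
    """Fit the compartment model to many voxels at once.

    Parameters
    ----------
    bvals : (n_shells,) nonzero shell b-values, s/mm^2.
    sbar : (n_voxels, n_shells) direction-averaged signals normalized by S_0.

    Returns arrays ``v_ic``, ``v_iso``, ``d_e_star``, ``objective``,
    ``converged``, ``n_iter`` of length n_voxels.  Identical signal rows are
    fitted once and broadcast back (the minimization is deterministic).
    """
    const = const or ModelConstants()
    opts = opts or FitOptions()
    bvals = np.asarray(bvals, dtype=float)
    sbar = np.atleast_2d(np.asarray(sbar, dtype=float))
    if bvals.size < 3:
        raise ValueError("need at least 3 nonzero shells")
    if not np.all(np.isfinite(sbar)):
        raise ValueError("non-finite signals passed to the fit")

    uniq, inverse = np.unique(sbar, axis=0, return_inverse=True)
    n = uniq.shape[0]
    starts = [np.tile(_initial_vertex(opts), (n, 1))]
    starts += _stripe_seeds(bvals, uniq, const)
    res = None
    for x0 in starts:
        res_new = _lm_batch(bvals, uniq, const, opts, x0)
        if res is None:
            res = res_new
        else:
            better = res_new["objective"] < res["objective"]
            res = {k: np.where(better, res_new[k], res[k]) for k in res}
    return {k: v[inverse] for k, v in res.items()}


def _stripe_seeds(bvals, targets, const, n_frac=21, n_diff=17):
    """Per-voxel starting points: the best coarse-grid point within each v_ic
    stripe, in transformed coordinates."""
    eps = 1e-3  # keep grid nodes strictly inside the open box for the transform
    vic = np.linspace(eps, 1 - eps, n_frac)
    viso = np.linspace(eps, 1 - eps, n_frac)
    de = np.linspace(eps * _D_SCALE, const.d_iso, n_diff)
    grid = np.stack([a.ravel() for a in np.meshgrid(vic, viso, de, indexing="ij")], axis=1)
    pred = predict_signal(
        bvals[None, :], grid[:, 0:1], grid[:, 1:2], grid[:, 2:3], const
    )  # (n_grid, n_shells)
    stripe_masks = [
        (grid[:, 0] >= lo) & (grid[:, 0] <= hi) for lo, hi in _VIC_STRIPES
    ]

    n = targets.shape[0]
    seeds = [np.empty((n, 3)) for _ in _VIC_STRIPES]
    for lo in range(0, n, 2048):
        chunk = targets[lo : lo + 2048]
        sse = np.sum((pred[None, :, :] - chunk[:, None, :]) ** 2, axis=2)
        for seed, m in zip(seeds, stripe_masks):
            masked = np.where(m[None, :], sse, np.inf)
            best = grid[np.argmin(masked, axis=1)]
            seed[lo : lo + 2048, 0] = _logit(best[:, 0])
            seed[lo : lo + 2048, 1] = _logit(best[:, 1])
            seed[lo : lo + 2048, 2] = _inv_softplus(best[:, 2] / _D_SCALE)
    return seeds


def _residual_and_jacobian(x, bvals, targets, const):
    """Model residuals and analytic Jacobian w.r.t. transformed coordinates."""
    vic = _sigmoid(x[:, 0:1])
    viso = _sigmoid(x[:, 1:2])
    de = _softplus(x[:, 2:3]) * _D_SCALE
    b = bvals[None, :]
    e_ic = np.exp(-b * vic * const.d_ic)
    e_ex = np.exp(-b * (1.0 - vic) * de)
    e_iso = np.exp(-b * const.d_iso)
    aniso = vic * e_ic + (1.0 - vic) * e_ex
    pred = (1.0 - viso) * aniso + viso * e_iso
    dp_dvic = (1.0 - viso) * (
        e_ic * (1.0 - b * vic * const.d_ic) + e_ex * (b * de * (1.0 - vic) - 1.0)
    )
    dp_dviso = e_iso - aniso
    dp_dde = -(1.0 - viso) * b * (1.0 - vic) ** 2 * e_ex
    # chain rule through sigmoid / softplus
    jac = np.stack(
        [
            dp_dvic * vic * (1.0 - vic),
            dp_dviso * viso * (1.0 - viso),
            dp_dde * _sigmoid(x[:, 2:3]) * _D_SCALE,
        ],
        axis=2,
    )
    return pred - targets, jac


def _lm_batch(bvals, targets, const, opts, x0):
    """Batched Levenberg-Marquardt over independent voxels.

    Damped normal-equation steps with per-voxel adaptive damping; a voxel
    stops once the relative objective improvement stays below ``opts.ftol``
    (converged) or at ``opts.max_iter``.  Converged voxels are compacted out
    of the working set.
    """
    n = targets.shape[0]
    x = np.asarray(x0, dtype=float).copy()
    if x.ndim == 1:
        x = np.tile(x, (n, 1))
    r, jac = _residual_and_jacobian(x, bvals, targets, const)
    sse = np.sum(r * r, axis=1)
    lam = np.full(n, 1e-3)
    stall = np.zeros(n, dtype=int)

    out_x = np.empty((n, 3))
    out_f = np.empty(n)
    out_it = np.zeros(n, dtype=int)
    out_conv = np.zeros(n, dtype=bool)
    active = np.arange(n)
    eye = np.eye(3)[None]
    tgt = targets
    it = 0
    while active.size and it < opts.max_iter:
        it += 1
        jtj = np.einsum("nbi,nbj->nij", jac, jac)
        grad = np.einsum("nbi,nb->ni", jac, r)
        diag = np.maximum(np.diagonal(jtj, axis1=1, axis2=2), 1e-14)
        a = jtj + lam[:, None, None] * eye * diag[:, None, :]
        step = np.linalg.solve(a, -grad[:, :, None])[:, :, 0]
        x_new = x + step
        r_new, jac_new = _residual_and_jacobian(x_new, bvals, tgt, const)
        sse_new = np.sum(r_new * r_new, axis=1)
        ok = sse_new < sse
        improvement = np.where(ok, sse - sse_new, 0.0)
        x = np.where(ok[:, None], x_new, x)
        r = np.where(ok[:, None], r_new, r)
        jac = np.where(ok[:, None, None], jac_new, jac)
        sse = np.where(ok, sse_new, sse)
        lam = np.clip(np.where(ok, lam / 3.0, lam * 4.0), 1e-12, 1e10)
        stall = np.where(improvement <= opts.ftol * (sse + 1e-30), stall + 1, 0)

        # patience of 8 lets the damping adapt through a run of rejected steps
        done = stall >= 8
        if done.any():
            gi = active[done]
            out_x[gi] = x[done]
            out_f[gi] = sse[done]
            out_it[gi] = it
            out_conv[gi] = True
            keep = ~done
            x, r, jac, sse, lam, stall, tgt, active = (
                x[keep], r[keep], jac[keep], sse[keep],
                lam[keep], stall[keep], tgt[keep], active[keep],
            )

    if active.size:  # hit max_iter
        out_x[active] = x
        out_f[active] = sse
        out_it[active] = it

    v_ic, v_iso, de = _to_params(out_x)
    return {
        "v_ic": v_ic,
        "v_iso": v_iso,
        "d_e_star": de,
        "objective": out_f,
        "converged": out_conv,
        "n_iter": out_it,
    }


def fit_voxel(
    bvals: np.ndarray,
    sbar: np.ndarray,
    s0: float,
    const: ModelConstants | None = None,
    opts: FitOptions | None = None,
) -> CompartmentFit:
    """Fit one voxel's per-shell direction averages.

    ``sbar`` holds the direction-averaged signal at each nonzero shell (same
    order as ``bvals``); ``s0`` is the signal without diffusion weighting.
    """
    if s0 is None or not np.isfinite(s0) or s0 <= 0:
        raise ValueError("S_0 must be positive and finite")
    sbar = np.asarray(sbar, dtype=float)
    if not np.all(np.isfinite(sbar)):
        raise ValueError("non-finite signals")
    res = fit_compartments(bvals, (sbar / s0)[None, :], const, opts)
    return CompartmentFit(
        v_ic=float(res["v_ic"][0]),
        v_iso=float(res["v_iso"][0]),
        d_e_star=float(res["d_e_star"][0]),
        objective=float(res["objective"][0]),
        converged=bool(res["converged"][0]),
        n_iter=int(res["n_iter"][0]),
    )


def fit_loo_mip(
    dwi: DwiSeries,
    const: ModelConstants | None = None,
    opts: FitOptions | None = None,
    mask: np.ndarray | None = None,
    keep_runs: bool = False,
) -> dict:
    """Leave-one-out fitting with maximum-intensity projection.

    With n gradient directions per shell there are exactly n subsets of n-1
    directions; run j averages the shell signals over all directions except j
    (the same excluded index at every shell, directions being matched across
    shells) and fits every voxel.  The final v_ic, v_iso and d_e* maps are the
    voxelwise maximum over the n runs.

    Returns a dict with the three MIP maps (ScalarVolume), the number of runs,
    a report of convergence counts, and optionally the per-run map stack.
    """
    const = const or ModelConstants()
    opts = opts or FitOptions()
    shells = dwi.gtab.shells()
    if len(shells) < 3:
        raise ValueError("need at least 3 nonzero shells")
    counts = {b: len(idx) for b, idx in shells.items()}
    n_set = set(counts.values())
    if len(n_set) != 1:
        raise ValueError(f"shells have mismatched direction counts: {counts}")
    n = n_set.pop()
    if n < 2:
        raise ValueError("need at least 2 directions per shell for leave-one-out")

    s0 = dwi.s0().data
    if mask is None:
        mask = np.isfinite(s0) & (s0 > 0)
    else:
        mask = np.asarray(mask, dtype=bool) & np.isfinite(s0) & (s0 > 0)
    bvals = np.array(sorted(shells))
    nvox = int(mask.sum())

    runs = np.full((n, 3, nvox), np.nan)
    conv = np.zeros((n, nvox), dtype=bool)
    n_iter_total = 0
    for j in range(n):
        subset = np.delete(np.arange(n), j)
        sbar = np.stack(
            [direction_average(dwi, b, subset).data[mask] for b in bvals], axis=1
        )
        sbar /= s0[mask][:, None]
        valid = np.all(np.isfinite(sbar), axis=1)
        res = fit_compartments(bvals, sbar[valid], const, opts)
        for k, key in enumerate(("v_ic", "v_iso", "d_e_star")):
            runs[j, k, valid] = res[key]
        conv[j, valid] = res["converged"]
        n_iter_total += int(res["n_iter"].sum())

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns stay NaN
        mip = np.nanmax(runs, axis=0)  # (3, nvox)
    all_failed = ~conv.any(axis=0)
    mip[:, all_failed] = UNDEFINED  # degenerate voxels: impute downstream

    def to_volume(flat):
        vol = np.full(dwi.shape, UNDEFINED)
        vol[mask] = flat
        return ScalarVolume(vol, dwi.affine.copy())

    out = {
        "v_ic": to_volume(mip[0]),
        "v_iso": to_volume(mip[1]),
        "d_e_star": to_volume(mip[2]),
        "n_runs": n,
        "report": {
            "n_voxels": nvox,
            "n_runs": n,
            "n_unconverged_voxels": int(all_failed.sum()),
            "total_iterations": n_iter_total,
        },
    }
    if keep_runs:
        out["runs"] = runs
        out["runs_mask"] = mask
    return out


def label_and_impute(
    volume: ScalarVolume,
    cutoff: float | None = 0.15,
    exclude_mask: np.ndarray | None = None,
    brain_mask: np.ndarray | None = None,
    axis: int = 2,
) -> tuple[ScalarVolume, dict]:
    """Label sub-physiological voxels and re-fill them by 2-D interpolation.

    In-brain voxels below ``cutoff`` (NaNs always count as invalid) are marked,
    except those in ``exclude_mask`` — used for v_ic, where CSF is legitimately
    zero and must not be labeled.  Invalid voxels are re-filled slice by slice
    (2-D planes perpendicular to ``axis``) by Delaunay triangulation of the
    valid voxels with linear interpolation; voxels outside the convex hull, or
    slices with fewer than 3 valid voxels, fall back to nearest-neighbor.
    """
    data = volume.data.astype(float).copy()
    if brain_mask is None:
        brain_mask = np.ones(data.shape, dtype=bool)
    else:
        brain_mask = np.asarray(brain_mask, dtype=bool)
    exclude = (
        np.zeros(data.shape, dtype=bool)
        if exclude_mask is None
        else np.asarray(exclude_mask, dtype=bool)
    )

    invalid = brain_mask & ~np.isfinite(data)
    if cutoff is not None:
        with np.errstate(invalid="ignore"):
            invalid |= brain_mask & ~exclude & (data < cutoff)
    valid = brain_mask & ~invalid & np.isfinite(data)

    n_nearest_fallback = 0
    moved = np.moveaxis(data, axis, 0)
    inv_m = np.moveaxis(invalid, axis, 0)
    val_m = np.moveaxis(valid, axis, 0)
    for sl in range(moved.shape[0]):
        bad = inv_m[sl]
        if not bad.any():
            continue
        good = val_m[sl]
        pts_bad = np.argwhere(bad)
        pts_good = np.argwhere(good)
        vals_good = moved[sl][good]
        if len(pts_good) < 3:
            if len(pts_good) == 0:
                continue  # nothing to interpolate from; leave undefined
            n_nearest_fallback += len(pts_bad)
            filled = griddata(pts_good, vals_good, pts_bad, method="nearest")
        else:
            filled = griddata(pts_good, vals_good, pts_bad, method="linear")
            outside = ~np.isfinite(filled)
            if outside.any():
                n_nearest_fallback += int(outside.sum())
                filled[outside] = griddata(
                    pts_good, vals_good, pts_bad[outside], method="nearest"
                )
        moved[sl][bad] = filled
    if n_nearest_fallback:
        warnings.warn(
            f"{n_nearest_fallback} voxels filled by nearest-neighbor fallback",
            stacklevel=2,
        )

    report = {
        "n_labeled": int(invalid.sum()),
        "n_nearest_fallback": n_nearest_fallback,
    }
    return volume.like(np.moveaxis(moved, 0, axis)), report


def derive_lf_params(
    v_ic: ScalarVolume,
    v_iso: ScalarVolume,
    d_e_star: ScalarVolume,
    const: ModelConstants | None = None,
) -> tuple[ScalarVolume, ScalarVolume, ScalarVolume, dict]:
    """Low-frequency model variables from the fitted compartment parameters:

        chi_e = (1 - v_iso) (1 - v_ic) + v_iso          extracellular fraction
        d_e   = [ (1 - v_iso) (1 - v_ic)^2 d_e* + v_iso d_iso ] / chi_e
        d_i   = v_ic d_ic

    Voxels where chi_e vanishes (v_iso = 0, v_ic = 1) leave d_e undefined;
    they are marked NaN and counted in the returned report.
    """
    c = const or ModelConstants()
    vic, viso, de_star = v_ic.data, v_iso.data, d_e_star.data
    chi_e = (1.0 - viso) * (1.0 - vic) + viso
    with np.errstate(divide="ignore", invalid="ignore"):
        d_e = ((1.0 - viso) * (1.0 - vic) ** 2 * de_star + viso * c.d_iso) / chi_e
    degenerate = np.isfinite(chi_e) & (chi_e == 0)
    d_e = np.where(degenerate, UNDEFINED, d_e)
    d_i = vic * c.d_ic
    report = {"n_degenerate_chi_e": int(degenerate.sum())}
    return v_ic.like(chi_e), v_ic.like(d_e), v_ic.like(d_i), report
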