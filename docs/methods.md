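# Methods

This package reconstructs the low-frequency (LF, ~10 Hz) electrical
conductivity tensor of brain tissue from two spin-echo images and a
multi-b-value diffusion series, without MR electrical properties tomography
(MR-EPT) and hence without the noise-sensitive Laplace operator.  This note
documents the model, the numerical choices, and what the synthetic phantom
does and does not establish.

## Model

**High-frequency conductivity from water content.**  The ratio of two
spin-echo images acquired at repetition times TR1 = 0.7 s and TR2 = 3.0 s is a
T1-weighted quantity; two calibrated exponential transfer functions map it to
the water volume fraction and onward to the conductivity at the Larmor
frequency:

    I_r      = S(TR1) / S(TR2)
    W        = w1 exp(-w2 I_r),            w1 = 1.525, w2 = 1.443
    sigma_HF = c1 + c2 exp(c3 W),          c1 = 0.286 S/m, c2 = 1.526e-5 S/m,
                                           c3 = 11.852

The second function is calibrated only for `0.6 <= W <= 1`.  Outside that
range the voxel is set to NaN and counted, never extrapolated: the exponential
would amplify water-estimation errors (its derivative grows as `exp(c3 W)`,
which is also why CSF values spread the most on real data).  The transfer
coefficients are plain dataclass fields and can be re-optimized when reference
conductivities are available.

**Direction-averaged compartment model.**  The diffusion signal averaged over
the gradient directions of each shell is fitted per voxel by a
three-compartment mixture with two fixed diffusivities
(d_ic = 1.7e-3, d_iso = 3.0e-3 mm^2/s) and three free parameters:

    S_b/S_0 = (1 - v_iso) [ v_ic exp(-b v_ic d_ic)
                          + (1 - v_ic) exp(-b (1 - v_ic) d_e*) ]
            + v_iso exp(-b d_iso)

with v_ic, v_iso in [0, 1] and d_e* >= 0.  The volume fractions appear inside
the exponents; the model is implemented exactly in this printed form.  The
derived LF variables are

    chi_e = (1 - v_iso)(1 - v_ic) + v_iso
    d_e   = [ (1 - v_iso)(1 - v_ic)^2 d_e* + v_iso d_iso ] / chi_e
    d_i   = v_ic d_ic

**Conductivity tensor.**  The diffusion tensor D is estimated on the b = 1000
s/mm^2 shell only, rescaled to the extracellular tensor D_e = eta D with
eta = 3 d_e / trace(D) (so trace(D_e) = 3 d_e and the eigenvectors are
shared), and assembled into

    C_LF = [ chi_e sigma_HF / (chi_e d_e + (1 - chi_e) d_i beta) ] D_e

with beta = 0.41 the intra-/extracellular ion-concentration ratio.  The
isotropic-equivalent map is the geometric mean of the eigenvalues of C_LF —
the conductivity of the isotropic ellipsoid of equal volume.

## Fitting: why multistart, and why Levenberg-Marquardt

Fitting three parameters to five or six shell averages is ill-conditioned, and
the cost surface is genuinely multimodal: local minima trade v_ic against d_e*
along nearly flat valleys.  Descent from the conventional starting point
(v_ic, v_iso, d_e*) = (0, 0.5, 0) reliably lands in an underestimating local
minimum — the same qualitative failure that motivates the leave-one-out MIP
stabilization in the first place.  Because downstream acceptance demands exact
noise-free recovery, the per-voxel minimization here is:

- a smooth change of variables (sigmoid for the fractions, softplus scaled by
  1e-3 mm^2/s for d_e*) mapping the constraint box onto R^3, avoiding
  projection artifacts at the bounds (starting values on the boundary are
  nudged to v_ic = 0.01, d_e* = 1e-5 mm^2/s);
- batched Levenberg-Marquardt with an analytic Jacobian, run from six starts:
  the conventional initial point plus the best point of a deterministic
  21 x 21 x 17 coarse grid within each of five v_ic stripes
  ([0,0.2), ..., [0.8,1]); the lowest residual wins.  Stripe seeding brackets
  every v_ic basin, which is what makes the multistart reliable — on 200
  random noise-free instances the global minimum is reached to SSE < 1e-14.
- convergence when the relative objective improvement stays below 1e-10 for
  eight consecutive iterations (the patience lets the damping adapt through
  rejected steps); damping multiplies by 4 on rejection, divides by 3 on
  acceptance.

Identical signal vectors across voxels are fitted once and broadcast, which
makes noise-free piecewise-constant phantoms essentially free.

**Structural degeneracy in CSF.**  At v_ic = 0, d_e* = d_iso the model signal
is exactly isotropic for *any* v_iso, so in pure free water the individual
parameters are not identifiable.  The derived LF variables are invariant along
this degenerate manifold (chi_e = 1, d_e = d_iso regardless of v_iso), so the
conductivity maps are unaffected; parameter-recovery checks are therefore
stated for GM and WM, and CSF is excluded from v_ic artifact labeling (its
true v_ic is zero, below any physiological cutoff).

## Leave-one-out MIP, labeling and imputation

With n = 16 directions per shell (matched across shells) there are exactly
C(16,15) = 16 leave-one-out subsets; run j excludes direction j at every
shell and refits every voxel, and the final v_ic, v_iso and d_e* maps are the
voxelwise maximum over the 16 runs.  Residual artifacts below the
physiological cutoff 0.15 (volume fractions only; d_e* is imputed only where
the fit failed) are re-filled slice by slice by Delaunay triangulation of the
valid voxels with linear interpolation; voxels outside the convex hull or on
slices with fewer than three valid voxels fall back to nearest-neighbor with a
counted warning.  The axial slice axis defaults to the third array axis and is
configurable.

## Tensor estimation choices

- D is fitted by log-linear least squares with one reweighting pass (weights =
  squared predicted signals), the standard WLS correction for log-transformed
  noise.  Exact parity with any external iterative implementation is not
  claimed.
- Non-positive diffusion signals are floored at 1e-12 and counted.
- Negative eigenvalues (noise) are clamped to zero and counted — conservative;
  the geometric mean then returns 0.  For symmetric PSD tensors the
  eigendecomposition coincides with an SVD; clamping rather than taking
  absolute singular values avoids sign-flipping noise into conductivity.
- Gradient vectors are interpreted in the image coordinate frame (FSL
  dialect).

## Evaluation

CSF is segmented by thresholding sigma_HF at 2 S/m (CSF sits near 2.2 S/m,
far above GM/WM).  Per-tissue distributions are summarized by mean, population
standard deviation and CV; the GM/WM coefficient of joint variation
CJV = (std_GM + std_WM)/(mean_GM - mean_WM) is reported in percent, in
GM-minus-WM orientation.  The resolution probe averages plain line
periodograms (no windowing or Welch segmenting) along one axis over all lines
with at least 16 in-mask samples — in-mask samples are compacted and
zero-padded to the axis length so all lines share one frequency grid — then
converts to dB and removes the DC bin; zero-power bins are floored at -120 dB.
Band-limited references are built by bilinear in-plane down-sampling to the
target spacing and up-sampling back (no anti-alias prefilter: plain linear
interpolation both ways, matching how such references are usually produced).

## The phantom: what it emulates and what it does not

The phantom is a concentric-shell geometry (CSF rim, cortical GM ribbon, WM
core, plus a cuboid CSF "ventricle") on a gapless isotropic grid with
per-tissue literature-typical 3 T values:

| tissue | W | T1 (s) | PD | v_ic | v_iso | d_e* (mm^2/s) |
|---|---|---|---|---|---|---|
| GM  | 0.846 | 1.30 | 1.0 | 0.4 | 0.2 | 1.2e-3 |
| WM  | 0.727 | 0.83 | 0.9 | 0.6 | 0.2 | 0.8e-3 |
| CSF | 0.990 | 4.00 | 1.1 | 0.0 | 1.0 | 3.0e-3 |

These W values map to sigma_HF of about 0.63, 0.37 and 2.19 S/m — inside the
transfer function's validity range and consistent with reported in vivo
values; they are defaults, not claims.  Spin-echo images follow saturation
recovery S = PD (1 - exp(-TR/T1)); the calibrated mode instead synthesizes
S(TR1) so the water round trip is exact, isolating downstream stages from T1
modeling.  DWI noise is Rician (magnitude of complex Gaussian), spin-echo
noise Gaussian, with sigma defaulting to SNR 40 at b = 0; all noise is seeded
and bit-reproducible.

Deliberate simplifications: no anatomical realism, no slice gaps (the ratio
method is per-slice, so resolution claims are unaffected), no susceptibility
distortion or motion, and — most importantly — no dispersion model linking the
direction-averaged compartment signal to an anisotropic tensor, because the
reconstruction model itself does not define one.  End-to-end checks therefore
use the spherical (direction-independent) forward model, where the fitted D is
isotropic and the closed-form composition of all transfer functions is exact;
the anisotropic tensor path is exercised separately with a mono-exponential
tensor forward model.  Consequently, passing phantom tests demonstrates the
correctness of the implemented chain of equations and estimators, not the
biological fidelity of the model on real tissue; in particular the raw Rician
noise floor at b = 4500 s/mm^2 biases high-b signals upward on the noisy
phantom exactly as it would on undenoised scanner data (denoising is upstream
preprocessing, outside this package).

## Problem sizes

Phantom tests and the acceptance script run at 32^3 voxels (about 12.5k brain
voxels; 16 leave-one-out fits each, noise-free runs collapse by signal
deduplication) and the resolution probe at 48 x 48 x 16; these sizes give
stable tissue medians while keeping a full run in minutes on one core.

## Known limitations

- No B1+ transmit-field correction: water maps inherit flip-angle bias,
  especially central ventricles.
- The image-ratio route is sensitive to inter-scan motion and gain changes (a
  CLI warning fires when the two spin-echo medians differ by more than 10x);
  a measured T1 map would be the rigorous alternative.
- beta = 0.41 is a fixed literature constant; it is not measurable by MRI.
- The 6-observation/3-parameter fit remains ill-conditioned near v_iso -> 1
  and for extreme v_ic; the MIP and imputation mitigate but do not remove
  this.
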