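"""Shared fixtures: phantoms, gradient tables and independent oracles."""

from __future__ import annotations

import numpy as np
import pytest

from cti import phantom
from cti.microstructure import ModelConstants, predict_signal
from cti.pipeline import reconstruct
from cti.tensor import CtiConstants
from cti.water import HfConductivityParams, WaterMapParams

PROTOCOL_BVALS = np.array([50.0, 150.0, 1000.0, 1800.0, 4500.0])


@pytest.fixture(scope="session")
def gtab16():
    """Protocol gradient table: one b0 + five shells x 16 matched directions."""
    return phantom.make_gradient_table()


@pytest.fixture(scope="session")
def spec32():
    """Noise-free 32^3 phantom specification."""
    return phantom.default_phantom_spec(grid_shape=(32, 32, 32))


@pytest.fixture(scope="session")
def noise_free_run(spec32, gtab16):
    """Full noise-free reconstruction on the 32^3 spherical-mode phantom,
    with calibrated spin-echo synthesis so the water round trip is exact."""
    se1, se2 = phantom.simulate_se_pair(spec32, calibrated=True)
    dwi = phantom.simulate_dwi(spec32, gtab16, mode="spherical")
    res = reconstruct(se1, se2, dwi, brain_mask=spec32.brain_mask())
    return {"spec": spec32, "dwi": dwi, "res": res}


# ---------------------------------------------------------------------------
# independent oracles (never call the code paths they check)


def closed_form_sigma_lf_iso(w, v_ic, v_iso, d_e_star):
    """Scalar oracle: compose the water, conductivity and compartment
    relations analytically for an isotropic diffusion environment.

    Written once, independently of the pipeline implementation: water ->
    sigma_HF by the exponential transfer function; (v_ic, v_iso, d_e*) ->
    (chi_e, d_e, d_i) by the mixture identities; conductivity scale applied
    to an isotropic extracellular tensor, whose eigenvalues are all d_e, so
    the geometric eigenvalue mean is the scale times d_e.
    """
    wp, hp, cc, mc = WaterMapParams(), HfConductivityParams(), CtiConstants(), ModelConstants()
    sigma_hf = hp.c1 + hp.c2 * np.exp(hp.c3 * w)
    chi_e = (1 - v_iso) * (1 - v_ic) + v_iso
    d_e = ((1 - v_iso) * (1 - v_ic) ** 2 * d_e_star + v_iso * mc.d_iso) / chi_e
    d_i = v_ic * mc.d_ic
    scale = chi_e * sigma_hf / (chi_e * d_e + (1 - chi_e) * d_i * cc.beta)
    return scale * d_e


def grid_search_oracle(bvals, target, n=201, d_max=3.0e-3):
    """Brute-force minimizer of the compartment-model cost over the box,
    discretized at n^3.  Exploits that the model is affine in v_iso so the
    cost is quadratic in it, which keeps the full 201^3 scan cheap.
    """
    mc = ModelConstants()
    vic = np.linspace(0.0, 1.0, n)
    viso = np.linspace(0.0, 1.0, n)
    de = np.linspace(0.0, d_max, n)
    aniso = (
        vic[:, None, None] * np.exp(-bvals[None, None, :] * vic[:, None, None] * mc.d_ic)
        + (1 - vic[:, None, None])
        * np.exp(-bvals[None, None, :] * (1 - vic[:, None, None]) * de[None, :, None])
    )  # (vic, de, b)
    iso = np.exp(-bvals * mc.d_iso)
    u = target[None, None, :] - aniso
    w = iso[None, None, :] - aniso
    su2 = np.sum(u * u, axis=-1)
    suw = np.sum(u * w, axis=-1)
    sw2 = np.sum(w * w, axis=-1)
    sse = (
        su2[:, :, None]
        - 2.0 * viso[None, None, :] * suw[:, :, None]
        + viso[None, None, :] ** 2 * sw2[:, :, None]
    )  # (vic, de, viso)
    i, j, k = np.unravel_index(np.argmin(sse), sse.shape)
    return (vic[i], viso[k], de[j]), float(sse[i, j, k])
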