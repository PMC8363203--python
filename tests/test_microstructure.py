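"""Compartment model: forward signal, fitting, MIP, imputation, LF variables."""

import numpy as np
import pytest

from cti import phantom
from cti.core import ScalarVolume
from cti.microstructure import (
    FitOptions,
    ModelConstants,
    derive_lf_params,
    direction_average,
    fit_loo_mip,
    fit_voxel,
    label_and_impute,
    predict_signal,
)
from .conftest import PROTOCOL_BVALS


class TestDirectionAverage:
    def test_mean_of_constant_directions(self, gtab16):
        spec = phantom.default_phantom_spec(grid_shape=(16, 16, 16))
        dwi = phantom.simulate_dwi(spec, gtab16, mode="spherical")
        idx = gtab16.shell_indices(1000.0)
        sbar = direction_average(dwi, 1000.0)
        np.testing.assert_allclose(sbar.data, dwi.data[..., idx[0]], rtol=1e-12)

    def test_arithmetic_mean(self, gtab16):
        spec = phantom.default_phantom_spec(grid_shape=(16, 16, 16))
        dwi = phantom.simulate_dwi(spec, gtab16, mode="spherical")
        idx = gtab16.shell_indices(1000.0)
        dwi.data[..., idx[0]] = 1.0
        dwi.data[..., idx[1]] = 2.0
        dwi.data[..., idx[2]] = 3.0
        sbar = direction_average(dwi, 1000.0, subset=[0, 1, 2])
        np.testing.assert_allclose(sbar.data, 2.0)

    def test_empty_subset_rejected(self, gtab16):
        spec = phantom.default_phantom_spec(grid_shape=(16, 16, 16))
        dwi = phantom.simulate_dwi(spec, gtab16, mode="spherical")
        with pytest.raises(ValueError, match="empty"):
            direction_average(dwi, 1000.0, subset=[])

    def test_missing_shell_rejected(self, gtab16):
        spec = phantom.default_phantom_spec(grid_shape=(16, 16, 16))
        dwi = phantom.simulate_dwi(spec, gtab16, mode="spherical")
        with pytest.raises(KeyError):
            direction_average(dwi, 700.0)


class TestPredictSignal:
    def test_unit_signal_at_b0_over_parameter_box(self):
        rng = np.random.default_rng(0)
        v_ic = rng.uniform(0, 1, 10_000)
        v_iso = rng.uniform(0, 1, 10_000)
        de = rng.uniform(0, 3e-3, 10_000)
        np.testing.assert_allclose(predict_signal(0.0, v_ic, v_iso, de), 1.0,
                                   atol=1e-12)

    def test_worked_example(self):
        val = predict_signal(1000.0, 0.5, 0.2, 1.0e-3)
        ref = 0.8 * (0.5 * np.exp(-0.85) + 0.5 * np.exp(-0.5)) + 0.2 * np.exp(-3.0)
        np.testing.assert_allclose(val, ref, rtol=1e-12)
        assert abs(val - 0.4236) < 1e-4

    def test_pure_isotropic_limit(self):
        np.testing.assert_allclose(
            predict_signal(1000.0, 0.3, 1.0, 1e-3), np.exp(-3.0), rtol=1e-12
        )

    def test_strictly_decreasing_in_b(self):
        rng = np.random.default_rng(1)
        b = np.linspace(0, 5000, 64)
        for _ in range(50):
            s = predict_signal(b, rng.uniform(0, 1), rng.uniform(0, 1),
                               rng.uniform(1e-5, 3e-3))
            assert np.all(np.diff(s) < 0)


class TestFitVoxel:
    def test_noise_free_recovery(self):
        truth = (0.6, 0.2, 0.8e-3)
        sig = predict_signal(PROTOCOL_BVALS, *truth)
        fit = fit_voxel(PROTOCOL_BVALS, sig, 1.0)
        assert abs(fit.v_ic - truth[0]) <= 1e-3
        assert abs(fit.v_iso - truth[1]) <= 1e-3
        assert abs(fit.d_e_star - truth[2]) / truth[2] <= 0.05
        assert fit.converged

    def test_s0_normalization(self):
        truth = (0.4, 0.2, 1.2e-3)
        sig = 7.5 * predict_signal(PROTOCOL_BVALS, *truth)
        fit = fit_voxel(PROTOCOL_BVALS, sig, 7.5)
        assert abs(fit.v_ic - truth[0]) <= 1e-3

    def test_pure_csf_limit_reproduces_isotropic_signal(self):
        """For pure free-water signals the fitted model must reproduce them.

        The parameters themselves are degenerate there (any v_iso fits once
        v_ic=0 and d_e*=d_iso), so the contract is on the fitted signal and
        the derived extracellular quantities, not on v_iso itself.
        """
        const = ModelConstants()
        sig = np.exp(-PROTOCOL_BVALS * const.d_iso)
        fit = fit_voxel(PROTOCOL_BVALS, sig, 1.0)
        assert fit.objective < 1e-12
        chi_e = (1 - fit.v_iso) * (1 - fit.v_ic) + fit.v_iso
        d_e = ((1 - fit.v_iso) * (1 - fit.v_ic) ** 2 * fit.d_e_star
               + fit.v_iso * const.d_iso) / chi_e
        assert abs(chi_e - 1.0) < 1e-3
        assert abs(d_e - const.d_iso) / const.d_iso < 0.01

    def test_nan_signal_rejected(self):
        sig = predict_signal(PROTOCOL_BVALS, 0.5, 0.2, 1e-3)
        sig[2] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fit_voxel(PROTOCOL_BVALS, sig, 1.0)

    def test_nonpositive_s0_rejected(self):
        sig = predict_signal(PROTOCOL_BVALS, 0.5, 0.2, 1e-3)
        with pytest.raises(ValueError, match="S_0"):
            fit_voxel(PROTOCOL_BVALS, sig, 0.0)

    def test_too_few_shells_rejected(self):
        with pytest.raises(ValueError, match="shells"):
            fit_voxel(np.array([1000.0, 1800.0]), np.array([0.5, 0.4]), 1.0)


class TestLooMip:
    def test_sixteen_runs_enumerated(self, gtab16):
        spec = phantom.default_phantom_spec(grid_shape=(16, 16, 16))
        dwi = phantom.simulate_dwi(spec, gtab16, mode="spherical")
        out = fit_loo_mip(dwi, mask=spec.brain_mask(), keep_runs=True)
        assert out["n_runs"] == 16
        assert out["runs"].shape[0] == 16

    def test_noise_free_mip_equals_single_run(self, gtab16):
        """All leave-one-out averages coincide without noise, so the MIP
        equals any individual run."""
        spec = phantom.default_phantom_spec(grid_shape=(16, 16, 16))
        dwi = phantom.simulate_dwi(spec, gtab16, mode="spherical")
        out = fit_loo_mip(dwi, mask=spec.brain_mask(), keep_runs=True)
        mask = out["runs_mask"]
        np.testing.assert_allclose(out["v_ic"].data[mask], out["runs"][0, 0],
                                   atol=1e-12)

    def test_mip_dominates_every_run(self, gtab16):
        spec = phantom.default_phantom_spec(
            grid_shape=(16, 16, 16), noise_model="rician", noise_sigma=0.02, seed=5
        )
        dwi = phantom.simulate_dwi(spec, gtab16, mode="spherical")
        out = fit_loo_mip(dwi, mask=spec.brain_mask(), keep_runs=True)
        mask = out["runs_mask"]
        for k, key in enumerate(("v_ic", "v_iso", "d_e_star")):
            final = out[key].data[mask]
            for j in range(out["n_runs"]):
                run = out["runs"][j, k]
                ok = np.isfinite(run)
                assert np.all(final[ok] >= run[ok] - 1e-12), (key, j)

    def test_mismatched_direction_counts_rejected(self):
        from cti.core import DwiSeries, GradientTable

        gtab = phantom.make_gradient_table()
        spec = phantom.default_phantom_spec(grid_shape=(16, 16, 16))
        dwi = phantom.simulate_dwi(spec, gtab, mode="spherical")
        trimmed = GradientTable(gtab.bvals[:-1], gtab.bvecs[:-1])  # drop one b=4500
        dwi = DwiSeries(dwi.data[..., :-1], trimmed, dwi.affine)
        with pytest.raises(ValueError, match="mismatched"):
            fit_loo_mip(dwi, mask=spec.brain_mask())


class TestLabelAndImpute:
    def test_identity_when_no_voxel_below_cutoff(self):
        data = np.full((8, 8, 4), 0.5)
        out, report = label_and_impute(ScalarVolume(data), cutoff=0.15)
        np.testing.assert_array_equal(out.data, data)
        assert report["n_labeled"] == 0

    def test_interior_invalid_on_constant_plane_refilled(self):
        data = np.full((9, 9, 3), 0.7)
        data[4, 4, 1] = 0.01  # below cutoff
        out, report = label_and_impute(ScalarVolume(data), cutoff=0.15)
        np.testing.assert_allclose(out.data[4, 4, 1], 0.7, rtol=1e-12)
        assert report["n_labeled"] == 1

    def test_linear_ramp_reproduced_exactly(self):
        """Linear interpolation on a Delaunay triangulation reproduces a
        planar ramp at an interior artifact voxel."""
        x = np.arange(11, dtype=float)
        data = np.broadcast_to(x[:, None, None], (11, 11, 3)).copy()
        data += 1.0  # keep everything above the cutoff
        data[5, 5, 1] = 0.0  # planted artifact
        out, _ = label_and_impute(ScalarVolume(data), cutoff=0.15)
        assert abs(out.data[5, 5, 1] - 6.0) < 1e-9

    def test_exclude_mask_suppresses_labeling(self):
        data = np.full((8, 8, 3), 0.5)
        data[2, 2, 1] = 0.0  # legitimately low (e.g. CSF v_ic)
        exclude = np.zeros(data.shape, bool)
        exclude[2, 2, 1] = True
        out, report = label_and_impute(ScalarVolume(data), cutoff=0.15,
                                       exclude_mask=exclude)
        assert out.data[2, 2, 1] == 0.0
        assert report["n_labeled"] == 0

    def test_nan_always_imputed_even_without_cutoff(self):
        data = np.full((8, 8, 3), 0.5)
        data[3, 3, 1] = np.nan
        out, report = label_and_impute(ScalarVolume(data), cutoff=None)
        np.testing.assert_allclose(out.data[3, 3, 1], 0.5)
        assert report["n_labeled"] == 1

    def test_sparse_slice_falls_back_to_nearest(self):
        data = np.full((6, 6, 1), np.nan)
        data[0, 0, 0] = 1.0
        data[5, 5, 0] = 1.0
        with pytest.warns(UserWarning, match="nearest"):
            out, report = label_and_impute(ScalarVolume(data), cutoff=None)
        assert np.isfinite(out.data).all()
        assert report["n_nearest_fallback"] > 0


class TestDeriveLfParams:
    @pytest.mark.parametrize(
        "v_ic, v_iso, de, chi_ref, d_e_ref, d_i_ref",
        [
            (0.3, 1.0, 1e-3, 1.0, 3.0e-3, 0.3 * 1.7e-3),  # CSF limit
            (0.0, 0.0, 1.1e-3, 1.0, 1.1e-3, 0.0),  # pure extracellular
            (0.5, 0.2, 1.0e-3, 0.6, 8.0e-4 / 0.6, 8.5e-4),  # mixed worked example
        ],
    )
    def test_limits_and_worked_example(self, v_ic, v_iso, de, chi_ref, d_e_ref, d_i_ref):
        mk = lambda v: ScalarVolume(np.full((3, 3, 3), v))
        chi_e, d_e, d_i, report = derive_lf_params(mk(v_ic), mk(v_iso), mk(de))
        np.testing.assert_allclose(chi_e.data, chi_ref, rtol=1e-12)
        np.testing.assert_allclose(d_e.data, d_e_ref, rtol=1e-12)
        np.testing.assert_allclose(d_i.data, d_i_ref, rtol=1e-12)
        assert report["n_degenerate_chi_e"] == 0

    def test_degenerate_chi_e_marked(self):
        mk = lambda v: ScalarVolume(np.full((2, 2, 2), v))
        chi_e, d_e, d_i, report = derive_lf_params(mk(1.0), mk(0.0), mk(1e-3))
        assert report["n_degenerate_chi_e"] == 8
        assert np.isnan(d_e.data).all()
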