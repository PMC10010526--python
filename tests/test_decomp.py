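import numpy as np
import pytest

import pcdct
from pcdct import decomp
from pcdct.decomp import (AtableModel, CalibrationSet, apply_atable,
                          apply_poly, fit_atable, fit_poly, mle_estimate,
                          simulate_calibration, synthesize_vmi)


@pytest.fixture(scope="module")
def mono_calib(basis, design10):
    """Calibration with effectively monoenergetic bins: linear physics."""
    spec = pcdct.Spectrum(np.array([60.0, 100.0]), np.array([0.5, 0.5]),
                          kvp=100.0)
    det = pcdct.DetectorModel(55.0, 95.0)
    return simulate_calibration(design10, spec, det, 1e7)


class TestSimulateCalibration:
    def test_blank_pair_gives_zero_projection(self, calib_nf):
        i = np.where((calib_nf.design.pairs == 0).all(axis=1))[0][0]
        np.testing.assert_allclose(calib_nf.projections[i], 0.0, atol=1e-12)

    def test_monoenergetic_bins_linear(self, mono_calib, basis):
        # P_k = mu_k1 A1 + mu_k2 A2 exactly
        mu = np.array([[basis.m1(60.0), basis.m2(60.0)],
                       [basis.m1(100.0), basis.m2(100.0)]])
        expected = mono_calib.design.pairs @ mu.T
        np.testing.assert_allclose(mono_calib.projections, expected,
                                   rtol=1e-10)

    def test_projections_increase_with_thickness(self, calib_nf):
        p = calib_nf.projections.reshape(10, 10, 2)
        assert np.all(np.diff(p, axis=0) > 0)  # more PMMA
        assert np.all(np.diff(p, axis=1) > 0)  # more Al

    def test_noisy_calibration_reproducible(self, design10, spectrum140,
                                            detector):
        a = simulate_calibration(design10, spectrum140, detector, 1e5, seed=3)
        b = simulate_calibration(design10, spectrum140, detector, 1e5, seed=3)
        np.testing.assert_array_equal(a.counts, b.counts)


class TestFitPoly:
    def test_plant_and_recover_quadratic(self, basis, design10):
        # synthesize projections, then thicknesses from a known reverse model
        rng = np.random.default_rng(1)
        p = rng.uniform(0.0, 3.0, size=(60, 2))
        d1 = np.array([0.5, 2.0, 0.3, 0.11, -0.05, 0.02])
        d2 = np.array([0.1, 0.2, 1.5, 0.01, 0.04, 0.06])
        X = np.stack([np.ones(60), p[:, 0], p[:, 1], p[:, 0] ** 2,
                      p[:, 0] * p[:, 1], p[:, 1] ** 2], axis=-1)
        pairs = np.column_stack([X @ d1, X @ d2])
        calib = CalibrationSet(
            pcdct.CalibrationDesign(pairs, basis), p,
            np.full((60, 2), 1e6))
        model = fit_poly(calib)
        np.testing.assert_allclose(model.d1, d1, rtol=1e-6, atol=1e-8)
        np.testing.assert_allclose(model.d2, d2, rtol=1e-6, atol=1e-8)
        assert model.fit_residual < 1e-8

    def test_monoenergetic_limit_is_linear(self, mono_calib):
        model = fit_poly(mono_calib)
        # quadratic coefficients vanish, residual ~ 0
        np.testing.assert_allclose(model.d1[3:], 0.0, atol=1e-6)
        np.testing.assert_allclose(model.d2[3:], 0.0, atol=1e-6)
        assert model.fit_residual < 1e-7

    def test_polychromatic_residual_regression(self, poly_model):
        # thickness RMS residual < 2% of the 50-cm maximum thickness
        assert poly_model.fit_residual < 0.02 * 50.0

    def test_too_few_points_rejected(self, basis, spectrum140, detector):
        d = pcdct.make_calibration_design(3, 3, 5.0, 2.0, basis)
        calib = simulate_calibration(d, spectrum140, detector, 1e7)
        sub = CalibrationSet(
            pcdct.CalibrationDesign(calib.design.pairs[:6:2].repeat(3, 0)
                                    + np.arange(9)[:, None] * 1e-6, basis),
            np.tile(calib.projections[0], (9, 1)),
            np.tile(calib.counts[0], (9, 1)))
        with pytest.raises(np.linalg.LinAlgError):
            fit_poly(sub)


class TestApplyPoly:
    def test_zero_model(self, basis):
        model = decomp.PolyModel(np.zeros(6), np.zeros(6), basis, 0.0)
        a1, a2 = apply_poly(model, 1.7, 2.9)
        assert a1 == 0.0 and a2 == 0.0

    def test_identity_passthrough(self, basis):
        d1 = np.array([0.0, 1.0, 0, 0, 0, 0])
        model = decomp.PolyModel(d1, np.zeros(6), basis, 0.0)
        a1, _ = apply_poly(model, 2.25, 0.4)
        assert a1 == pytest.approx(2.25)

    def test_calibration_points_within_residual(self, calib_nf, poly_model):
        a1, a2 = apply_poly(poly_model, calib_nf.projections[:, 0],
                            calib_nf.projections[:, 1])
        err = np.column_stack([a1, a2]) - calib_nf.design.pairs
        rms = np.sqrt(np.mean(err ** 2))
        assert rms <= poly_model.fit_residual * (1 + 1e-9)


class TestFitAtable:
    def test_monoenergetic_corrections_vanish(self, mono_calib):
        model = fit_atable(mono_calib)
        np.testing.assert_allclose(model.lut_values, 0.0, atol=1e-8)

    def test_blank_node_is_origin(self, atable_model, design10):
        i = np.where((design10.pairs == 0).all(axis=1))[0][0]
        np.testing.assert_allclose(atable_model.lut_nodes[i], 0.0, atol=1e-10)
        np.testing.assert_allclose(atable_model.lut_values[i], 0.0,
                                   atol=1e-10)

    def test_corrections_grow_toward_design_corner(self, atable_model):
        # beam hardening: |dA| vanishes at the origin and is largest at the
        # far diagonal corner of the design
        norms = np.linalg.norm(atable_model.lut_values.reshape(10, 10, 2),
                               axis=-1)
        diag = np.diag(norms)
        assert diag[0] == pytest.approx(0.0, abs=1e-10)
        assert diag[-1] == np.max(diag)
        assert diag[-1] > diag[1]

    def test_collinear_design_rejected(self, basis):
        pairs = np.column_stack([np.linspace(0, 5, 8),
                                 np.linspace(0, 5, 8) * 2])
        calib = CalibrationSet(pcdct.CalibrationDesign(pairs, basis),
                               np.ones((8, 2)), np.ones((8, 2)))
        with pytest.raises(np.linalg.LinAlgError):
            fit_atable(calib)


class TestMLE:
    def test_consistent_system_recovered_exactly(self, basis):
        M = np.array([[0.3, 1.1], [0.2, 0.5]])
        model = AtableModel(M, np.array([[0, 0], [1, 0], [0, 1], [1, 1.0]]),
                            np.zeros((4, 2)), basis)
        a_true = np.array([4.0, 1.5])
        p = M @ a_true
        est = mle_estimate(model, p, np.array([100.0, 100.0]))
        np.testing.assert_allclose(est, a_true, rtol=1e-12)

    def test_weight_scale_invariance(self, basis):
        M = np.array([[0.3, 1.1], [0.2, 0.5]])
        model = AtableModel(M, np.array([[0, 0], [1, 0], [0, 1], [1, 1.0]]),
                            np.zeros((4, 2)), basis)
        p = np.array([1.2, 0.7])
        a = mle_estimate(model, p, np.array([10.0, 500.0]))
        b = mle_estimate(model, p, np.array([20.0, 1000.0]))
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_identity_model(self, basis):
        model = AtableModel(np.eye(2),
                            np.array([[0, 0], [1, 0], [0, 1], [1, 1.0]]),
                            np.zeros((4, 2)), basis)
        p = np.array([0.8, 0.3])
        np.testing.assert_allclose(mle_estimate(model, p, np.array([5., 9.])),
                                   p, rtol=1e-12)


class TestApplyAtable:
    def test_exact_at_calibration_nodes(self, calib_nf, atable_model):
        est = apply_atable(atable_model, calib_nf.projections,
                           calib_nf.counts)
        np.testing.assert_allclose(est, calib_nf.design.pairs, atol=1e-9)

    def test_monoenergetic_equals_mle(self, mono_calib):
        model = fit_atable(mono_calib)
        p = np.array([[0.9, 0.5]])
        c = np.array([[1e4, 1e4]])
        a = apply_atable(model, p, c)
        b = mle_estimate(model, p, c)
        np.testing.assert_allclose(a, np.squeeze(b), atol=1e-7)


class TestDecomposeSinogram:
    def test_blank_sinogram_gives_zero_thickness(self, atable_model,
                                                 geom_small):
        blank = pcdct.BinnedSinogram(
            np.full((2, 4, 6), 1e5), np.array([1e5, 1e5]), geom_small)
        thick = decomp.decompose_sinogram(atable_model, blank)
        np.testing.assert_allclose(thick.thickness, 0.0, atol=1e-9)

    def test_pmma_disk_projects_onto_first_channel(
            self, atable_model, spectrum140, detector, geom_small):
        ph = pcdct.make_disk_phantom("pmma", 30.0, 0.5, n=160)
        paths = pcdct.trace_paths(ph, geom_small)
        raw = pcdct.expected_counts(paths, spectrum140, detector, 1e7)
        thick = decomp.decompose_sinogram(atable_model, raw)
        inside = paths.lengths[..., 1] > 0.5
        a1 = thick.thickness[..., 0][inside]
        a2 = thick.thickness[..., 1][inside]
        assert np.mean(np.abs(a2)) < 0.05 * np.mean(a1)

    def test_shape_contract(self, poly_model, geom_small):
        sino = pcdct.BinnedSinogram(
            np.full((2, 7, 5), 1e6), np.array([1e6, 1e6]), geom_small)
        thick = decomp.decompose_sinogram(poly_model, sino)
        assert thick.thickness.shape == (7, 5, 2)

    def test_single_bin_rejected(self, poly_model, geom_small):
        sino = pcdct.BinnedSinogram(np.full((1, 3, 3), 1e6),
                                    np.array([1e6]), geom_small)
        with pytest.raises(ValueError):
            decomp.decompose_sinogram(poly_model, sino)


class TestSynthesizeVMI:
    def test_single_material_limit(self, basis):
        thick = decomp.ThicknessSinogram(
            np.stack([np.full((3, 4), 2.0), np.zeros((3, 4))], axis=-1),
            basis)
        p = synthesize_vmi(thick, decomp.VMIRequest(100.0, basis))
        np.testing.assert_allclose(p, basis.m1(100.0) * 2.0, rtol=1e-12)

    def test_linearity_in_thickness(self, basis):
        rng = np.random.default_rng(2)
        t = rng.uniform(0, 5, size=(3, 4, 2))
        a = decomp.ThicknessSinogram(t, basis)
        b = decomp.ThicknessSinogram(2 * t, basis)
        req = decomp.VMIRequest(70.0, basis)
        np.testing.assert_allclose(2 * synthesize_vmi(a, req),
                                   synthesize_vmi(b, req), rtol=1e-12)

    def test_energy_bounds(self, basis):
        with pytest.raises(ValueError):
            decomp.VMIRequest(200.0, basis)
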