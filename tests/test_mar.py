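import numpy as np
import pytest

import pcdct
from pcdct import mar
from pcdct.mar import (MetalTrace, build_prior, lmar, metal_trace, nmar,
                       reinsert_metal, segment_metal)
from pcdct.recon import ReconImage


@pytest.fixture(scope="module")
def structured_chain(geom_small):
    """Noise-free monoenergetic scan of a water disk with a bone insert."""
    ph = pcdct.make_disk_phantom("water", 40.0, 0.5, n=192)
    lm = ph.label_map.copy()
    x, y = ph.coords()
    lm[(x - 15) ** 2 + y ** 2 <= 64] = 2
    ph = pcdct.PhantomImage(lm, ("air", "water", "bone"), 0.5)
    paths = pcdct.trace_paths(ph, geom_small)
    sino = pcdct.expected_counts(paths, pcdct.monoenergetic(80.0), None, 1e7)
    logp = pcdct.log_projections(sino)[0]
    img = pcdct.fbp_fan(logp, geom_small, 0.5, 192)
    hu = pcdct.to_hu(img, pcdct.get_material("water")(80.0))
    return ph, logp, hu


class TestSegmentMetal:
    def test_zero_image_empty_mask(self):
        img = ReconImage(np.zeros((32, 32)), 1.0)
        assert segment_metal(img).empty

    def test_threshold_above_max_empty(self):
        img = ReconImage(np.full((16, 16), 2000.0), 1.0)
        assert segment_metal(img, 3000.0).empty

    def test_burned_in_metal_recovered(self, geom_small):
        metal = pcdct.MetalSpec((pcdct.Disk((0.0, 10.0), 6.0),), "titanium")
        ph = pcdct.make_disk_phantom("water", 40.0, 0.5, n=192)
        lm = ph.label_map.copy()
        mats = ("air", "water", "titanium")
        base = pcdct.PhantomImage(lm, mats, 0.5)
        lm[metal.rasterize(base)] = 2
        ph = pcdct.PhantomImage(lm, mats, 0.5)
        paths = pcdct.trace_paths(ph, geom_small)
        sino = pcdct.expected_counts(paths, pcdct.monoenergetic(60.0), None,
                                     1e7)
        img = pcdct.fbp_fan(pcdct.log_projections(sino)[0], geom_small,
                            0.5, 192)
        hu = pcdct.to_hu(img, pcdct.get_material("water")(60.0))
        # half-maximum threshold recovers the true disk size; the 3000-HU
        # default is deliberately permissive and grabs the partial-volume rim
        mask = segment_metal(hu, hu.values.max() / 2)
        true_area = (ph.label_map == 2).sum()
        assert mask.mask.sum() == pytest.approx(true_area, rel=0.05)
        assert segment_metal(hu, 3000.0).mask.sum() >= mask.mask.sum()


class TestMetalTrace:
    def test_empty_mask_empty_trace(self, geom_small):
        mask = mar.MetalMask(np.zeros((64, 64), bool), 3000.0)
        assert metal_trace(mask, geom_small, 1.0).empty

    def test_centered_disk_constant_band(self, geom_small):
        mask = np.zeros((128, 128), bool)
        x = (np.arange(128) - 63.5)
        xx, yy = np.meshgrid(x, x)
        mask[xx ** 2 + yy ** 2 <= 100] = True
        tr = metal_trace(mar.MetalMask(mask, 0.0), geom_small, 1.0).trace
        widths = tr.sum(axis=1)
        assert np.all(widths > 0)
        assert widths.max() - widths.min() <= 2

    def test_off_center_disk_sinusoidal_band(self, geom_small):
        mask = np.zeros((128, 128), bool)
        cx_mm, cy_mm = 20.0, 0.0
        x = (np.arange(128) - 63.5) * 1.0
        xx = x[None, :]
        yy = -x[:, None]
        mask[(xx - cx_mm) ** 2 + (yy - cy_mm) ** 2 <= 64] = True
        tr = metal_trace(mar.MetalMask(mask, 0.0), geom_small, 1.0).trace
        s = geom_small.det_coords()
        centers = np.array([s[row].mean() for row in tr])
        # analytic projection of the disk center onto the detector
        sad, aid = geom_small.sad, geom_small.aid
        expected = []
        for ang in geom_small.view_angles:
            b = np.deg2rad(ang)
            u = sad - (cx_mm * np.cos(b) + cy_mm * np.sin(b))
            l = -cx_mm * np.sin(b) + cy_mm * np.cos(b)
            expected.append((sad + aid) * l / u)
        assert np.max(np.abs(centers - expected)) < 2 * geom_small.det_pitch


class TestLMAR:
    def test_empty_trace_identity(self):
        p = np.random.default_rng(0).normal(size=(10, 20))
        tr = MetalTrace(np.zeros((10, 20), bool))
        np.testing.assert_array_equal(lmar(p, tr), p)

    def test_constant_sinogram_unchanged(self):
        p = np.full((5, 30), 3.3)
        t = np.zeros((5, 30), bool)
        t[:, 10:15] = True
        np.testing.assert_allclose(lmar(p, MetalTrace(t)), p, rtol=1e-12)

    def test_linear_ramp_reproduced_exactly(self):
        ramp = np.tile(np.linspace(0, 5, 40), (3, 1))
        t = np.zeros((3, 40), bool)
        t[:, 12:20] = True
        np.testing.assert_allclose(lmar(ramp, MetalTrace(t)), ramp,
                                   rtol=1e-12)

    def test_outside_trace_bit_identical(self):
        rng = np.random.default_rng(5)
        p = rng.normal(size=(8, 50))
        t = np.zeros((8, 50), bool)
        t[:, 20:30] = True
        out = lmar(p, MetalTrace(t))
        assert np.array_equal(out[~t], p[~t])

    def test_full_row_trace_falls_back_to_mean(self):
        p = np.arange(20.0)[None, :]
        t = np.ones((1, 20), bool)
        out = lmar(p, MetalTrace(t))
        np.testing.assert_allclose(out, p.mean())


class TestBuildPrior:
    def test_uniform_soft_tissue(self):
        img = ReconImage(np.full((8, 8), 40.0), 1.0)
        prior = build_prior(img)
        np.testing.assert_allclose(prior.values, 0.0)

    def test_air_only(self):
        img = ReconImage(np.full((8, 8), -990.0), 1.0)
        np.testing.assert_allclose(build_prior(img).values, -1000.0)

    def test_three_class_map_matches_thresholds(self):
        v = np.array([[-900.0, 0.0, 80.0], [600.0, 1500.0, -501.0]])
        prior = build_prior(ReconImage(v, 1.0)).values
        expected = np.array([[-1000.0, 0.0, 0.0], [600.0, 1500.0, -1000.0]])
        np.testing.assert_allclose(prior, expected)


class TestNMAR:
    def test_empty_trace_identity(self, structured_chain, geom_small):
        ph, logp, hu = structured_chain
        tr = MetalTrace(np.zeros_like(logp, dtype=bool))
        np.testing.assert_array_equal(nmar(logp, tr, hu, geom_small), logp)

    def test_unit_prior_sinogram_reduces_to_lmar(self, structured_chain,
                                                 geom_small, monkeypatch):
        ph, logp, hu = structured_chain
        t = np.zeros_like(logp, dtype=bool)
        t[:, 60:68] = True
        monkeypatch.setattr(mar, "project_image",
                            lambda v, px, g: np.ones_like(logp))
        out = nmar(logp, MetalTrace(t), hu, geom_small)
        np.testing.assert_allclose(out, lmar(logp, MetalTrace(t)),
                                   rtol=1e-10)

    def test_perfect_prior_restores_truth(self, structured_chain,
                                          geom_small):
        ph, logp, hu = structured_chain
        t = np.zeros_like(logp, dtype=bool)
        t[:, 60:68] = True
        out = nmar(logp, MetalTrace(t), hu, geom_small)
        rmse = np.sqrt(np.mean((out[t] - logp[t]) ** 2))
        scale = np.sqrt(np.mean(logp[t] ** 2))
        assert rmse < 0.01 * scale

    def test_outside_trace_bit_identical(self, structured_chain, geom_small):
        ph, logp, hu = structured_chain
        t = np.zeros_like(logp, dtype=bool)
        t[:, 55:70] = True
        out = nmar(logp, MetalTrace(t), hu, geom_small)
        assert np.array_equal(out[~t], logp[~t])

    def test_beats_lmar_with_good_prior(self, structured_chain, geom_small):
        ph, logp, hu = structured_chain
        t = np.zeros_like(logp, dtype=bool)
        t[:, 52:64] = True  # band crossing the bone insert's sinusoid
        l = lmar(logp, MetalTrace(t))
        n = nmar(logp, MetalTrace(t), hu, geom_small)
        rmse_l = np.sqrt(np.mean((l[t] - logp[t]) ** 2))
        rmse_n = np.sqrt(np.mean((n[t] - logp[t]) ** 2))
        assert rmse_n < rmse_l


class TestReinsertMetal:
    def test_empty_mask_no_change(self):
        a = ReconImage(np.random.default_rng(0).normal(size=(8, 8)), 1.0)
        b = ReconImage(np.zeros((8, 8)), 1.0)
        mask = mar.MetalMask(np.zeros((8, 8), bool), 3000.0)
        np.testing.assert_array_equal(reinsert_metal(a, mask, b).values,
                                      a.values)

    def test_full_mask_returns_original(self):
        a = ReconImage(np.zeros((4, 4)), 1.0)
        b = ReconImage(np.full((4, 4), 7.0), 1.0)
        mask = mar.MetalMask(np.ones((4, 4), bool), 0.0)
        np.testing.assert_array_equal(reinsert_metal(a, mask, b).values,
                                      b.values)

    def test_disjoint_mask_untouched_elsewhere(self):
        rng = np.random.default_rng(1)
        a = ReconImage(rng.normal(size=(6, 6)), 1.0)
        b = ReconImage(rng.normal(size=(6, 6)), 1.0)
        m = np.zeros((6, 6), bool)
        m[2:4, 2:4] = True
        out = reinsert_metal(a, mar.MetalMask(m, 0.0), b)
        assert np.array_equal(out.values[~m], a.values[~m])
        assert np.array_equal(out.values[m], b.values[m])
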