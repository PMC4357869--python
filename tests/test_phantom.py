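import numpy as np
import pytest

from filanet import phantom
from filanet.imgio import rescale
from filanet.phantom import (
    GroundTruth,
    PhantomSpec,
    densify,
    make_rod_mesh,
    make_wlc_chains,
    mean_local_snr,
    rasterize,
    read_polylines,
    render,
    write_polylines,
)


class TestRodMesh:
    def test_determinism(self):
        a = make_rod_mesh((64, 64, 64), 4, (20, 40), seed=7)
        b = make_rod_mesh((64, 64, 64), 4, (20, 40), seed=7)
        assert len(a.polylines) == len(b.polylines)
        for pa, pb in zip(a.polylines, b.polylines):
            np.testing.assert_array_equal(pa, pb)

    def test_points_inside_box_and_densified(self):
        gt = make_rod_mesh((64, 64, 64), 6, (20, 40), seed=1)
        for poly in gt.polylines:
            assert np.all(poly >= 0) and np.all(poly <= 63)
            gaps = np.linalg.norm(np.diff(poly, axis=0), axis=1)
            assert gaps.max() <= 1.0 + 1e-9

    def test_axis_aligned_rod_has_constant_transverse_coords(self):
        pts = densify(np.array([[10.0, 30.0, 30.0], [50.0, 30.0, 30.0]]), 1.0)
        gt = GroundTruth([pts], (64, 64, 64))
        poly = gt.polylines[0]
        assert np.all(poly[:, 1] == 30.0) and np.all(poly[:, 2] == 30.0)

    def test_box_too_small_rejected(self):
        with pytest.raises(ValueError, match="box too small"):
            make_rod_mesh((16, 16, 16), 2, (40, 50), seed=0)


class TestCrossingRods:
    def test_share_an_intersection_voxel(self, crossing_gt):
        a, b = (np.round(p).astype(int) for p in crossing_gt.polylines)
        shared = set(map(tuple, a)) & set(map(tuple, b))
        assert shared  # the two filaments cross through a common voxel


class TestWlcChains:
    def test_infinite_lp_limit_is_straight(self):
        gt = make_wlc_chains((96, 96, 96), 3, 40.0, lp=1e9, seed=2)
        for poly in gt.polylines:
            chord = np.linalg.norm(poly[-1] - poly[0])
            arc = np.linalg.norm(np.diff(poly, axis=0), axis=1).sum()
            assert chord == pytest.approx(arc, rel=1e-6)

    def test_tangent_autocorrelation_decay(self):
        # <t(s) . t(s + D)> = exp(-D / lp) for the 3D worm-like chain
        lp, delta = 20.0, 5
        gt = make_wlc_chains((512, 512, 512), 300, 40.0, lp=lp, seed=3, margin=200)
        dots = []
        for poly in gt.polylines:
            t = np.diff(poly, axis=0)
            t /= np.linalg.norm(t, axis=1, keepdims=True)
            dots.extend(np.sum(t[:-delta] * t[delta:], axis=1))
        assert np.mean(dots) == pytest.approx(np.exp(-delta / lp), abs=0.03)

    def test_determinism(self):
        a = make_wlc_chains((64, 64, 64), 2, 25.0, lp=30.0, seed=9)
        b = make_wlc_chains((64, 64, 64), 2, 25.0, lp=30.0, seed=9)
        for pa, pb in zip(a.polylines, b.polylines):
            np.testing.assert_array_equal(pa, pb)

    def test_2d_chains_stay_in_plane(self):
        gt = make_wlc_chains((64, 64, 8), 2, 25.0, lp=30.0, dim=2, seed=4)
        for poly in gt.polylines:
            assert np.ptp(poly[:, 2]) == 0.0


class TestRender:
    def test_background_only_poisson_moments(self):
        # far from any filament the field is i.i.d. Poisson(30 * 0.4 = 12)
        pts = densify(np.array([[2.0, 2.0, 2.0], [10.0, 2.0, 2.0]]), 1.0)
        gt = GroundTruth([pts], (64, 64, 64))
        v = render(gt, PhantomSpec(seed=5))
        bg = v.data[32:, 32:, 32:]
        assert bg.mean() == pytest.approx(12.0, rel=0.02)
        assert bg.var() == pytest.approx(12.0, rel=0.05)

    def test_seeded_render_is_reproducible(self, rod_gt):
        spec = PhantomSpec(seed=11)
        np.testing.assert_array_equal(
            render(rod_gt, spec).data, render(rod_gt, spec).data
        )

    def test_noiseless_transverse_profile_is_gaussian(self, rod_gt):
        spec = PhantomSpec(noise_model="none")
        v = render(rod_gt, spec)
        # profile across the rod (along y at the rod center)
        prof = v.data[32, :, 32] - spec.intensity_scale * spec.background
        ys = np.arange(64, dtype=float)
        sigma = np.sqrt(np.sum(prof * (ys - 32) ** 2) / np.sum(prof))
        assert sigma == pytest.approx(spec.psf_sigma[1], rel=0.05)

    def test_rasterized_voxels_match_polyline(self, rod_gt):
        mask = rasterize(rod_gt, thickness=1.0)
        expect = set(map(tuple, np.round(rod_gt.polylines[0]).astype(int)))
        assert set(map(tuple, np.argwhere(mask))) == expect

    def test_empty_ground_truth_rejected(self):
        with pytest.raises(ValueError):
            render(GroundTruth([], (8, 8, 8)), PhantomSpec())


class TestMeanLocalSnr:
    def test_noiseless_snr_is_large(self, rod_gt):
        # with a narrow isotropic PSF the annulus sees clean background, so
        # sigma_b hits the floor and the SNR is huge but finite
        spec = PhantomSpec(
            kernel_norm="peak", noise_model="none", psf_sigma=(1.0, 1.0, 1.0)
        )
        v = rescale(render(rod_gt, spec))
        snr = mean_local_snr(v, rod_gt)
        assert np.isfinite(snr) and snr > 50

    def test_doubling_contrast_roughly_doubles_snr(self):
        # narrow PSF keeps the annulus on pure Poisson background, so the
        # estimator is linear in the foreground-background contrast
        gt = make_rod_mesh((64, 64, 64), 3, (25, 40), seed=6)
        psf = (1.0, 1.0, 1.0)
        lo = render(gt, PhantomSpec(foreground=60.0, kernel_norm="peak",
                                    psf_sigma=psf, seed=6))
        hi = render(gt, PhantomSpec(foreground=90.0, kernel_norm="peak",
                                    psf_sigma=psf, seed=6))
        ratio = mean_local_snr(hi, gt) / mean_local_snr(lo, gt)
        assert ratio == pytest.approx(2.0, rel=0.25)

    def test_pure_background_snr_near_zero(self):
        rng = np.random.default_rng(0)
        from filanet.imgio import Volume

        v = Volume(rng.poisson(12.0, size=(48, 48, 48)).astype(float))
        pts = densify(np.array([[16.0, 24.0, 24.0], [32.0, 24.0, 24.0]]), 1.0)
        gt = GroundTruth([pts], (48, 48, 48))
        assert mean_local_snr(v, gt) < 0.5


def test_polyline_file_roundtrip(tmp_path, crossing_gt):
    path = tmp_path / "gt.txt"
    write_polylines(crossing_gt, path)
    back = read_polylines(path)
    assert back.box == crossing_gt.box
    assert len(back.polylines) == 2
    for pa, pb in zip(back.polylines, crossing_gt.polylines):
        np.testing.assert_allclose(pa, pb, atol=1e-6)
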