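import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from filanet.dynamics import Snake
from filanet.imgio import Volume
from filanet.quantify import (
    curvature,
    fit_persistence_length,
    radial_angle,
    radial_profiles,
    sample_wlc_curvature,
    segment_orientation,
    spherocylinder_density,
    surface_fraction,
)
from filanet.topology import Network


class TestSegmentOrientation:
    @pytest.mark.parametrize(
        "a,phi,theta",
        [
            ((1, 1, 0), 45.0, 90.0),
            ((0, 0, 1), 0.0, 0.0),  # z-axis special case
            ((0, 0, -1), 0.0, 0.0),
            ((1, 0, 0), 0.0, 90.0),
            ((0, 1, 0), 90.0, 90.0),
            # x = 0, y != 0: invert when y < 0, phi = 90
            ((0, -2, 1), 90.0, np.degrees(np.arccos(-1 / np.sqrt(5)))),
        ],
    )
    def test_printed_conventions(self, a, phi, theta):
        got_phi, got_theta = segment_orientation(np.array(a, float))
        assert got_phi == pytest.approx(phi)
        assert got_theta == pytest.approx(theta)

    @settings(max_examples=100, deadline=None)
    @given(
        a=st.tuples(*[st.floats(-10, 10, allow_nan=False)] * 3).filter(
            lambda t: np.linalg.norm(t) > 1e-6
        )
    )
    def test_polarity_free_and_in_range(self, a):
        a = np.array(a)
        phi1, th1 = segment_orientation(a)
        phi2, th2 = segment_orientation(-a)
        assert phi1 == pytest.approx(phi2)
        assert th1 == pytest.approx(th2)
        assert -90 < phi1 <= 90
        assert 0 <= th1 < 180

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            segment_orientation(np.zeros(3))


class TestRadialAngle:
    def test_parallel_antiparallel_perpendicular(self):
        mid, ctr = np.array([5.0, 0, 0]), np.zeros(3)
        assert radial_angle(np.array([1.0, 0, 0]), mid, ctr) == pytest.approx(0.0)
        assert radial_angle(np.array([-1.0, 0, 0]), mid, ctr) == pytest.approx(0.0)
        assert radial_angle(np.array([0.0, 1, 0]), mid, ctr) == pytest.approx(90.0)


def _net_from_points(pts):
    return Network([Snake(np.asarray(pts, float), id=0)])


class TestRadialProfiles:
    def test_single_shell_density(self):
        # N points in shell (r, r+1] with r = 5: rho = N / (4 pi 25)
        rng = np.random.default_rng(0)
        dirs = rng.normal(size=(40, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        pts = 24.0 + 5.5 * dirs
        v = Volume(np.ones((48, 48, 48)))
        prof = radial_profiles(_net_from_points(pts), v, np.full(3, 24.0), 10)
        assert prof.counts[5] == 40
        assert prof.rho[5] == pytest.approx(40 / (4 * np.pi * 25))
        assert prof.counts.sum() == 40

    def test_density_conservation(self):
        # sum over shells of rho * 4 pi r^2 equals the point count
        rng = np.random.default_rng(1)
        dirs = rng.normal(size=(500, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        radii = 1.0 + 19.0 * rng.random(500) ** (1 / 3)
        pts = 32.0 + radii[:, None] * dirs
        v = Volume(np.ones((64, 64, 64)))
        prof = radial_profiles(_net_from_points(pts), v, np.full(3, 32.0), 24)
        total = np.sum(prof.rho[1:] * 4 * np.pi * prof.r[1:] ** 2) + prof.counts[0]
        assert total == pytest.approx(500)

    def test_uniform_ball_gives_flat_density(self):
        rng = np.random.default_rng(2)
        n = 20000
        pts = rng.random((n, 3)) * 2 - 1
        pts = pts[np.linalg.norm(pts, axis=1) <= 1.0] * 20 + 32
        v = Volume(np.ones((64, 64, 64)))
        prof = radial_profiles(_net_from_points(pts), v, np.full(3, 32.0), 20)
        inner = prof.rho[5:19]
        assert inner.std() / inner.mean() < 0.25

    def test_surface_fraction(self):
        rng = np.random.default_rng(3)
        dirs = rng.normal(size=(50, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        pts = 32.0 + 19.0 * dirs  # all at distance 19 = 0.95 R for R = 20
        assert surface_fraction(
            _net_from_points(pts), np.full(3, 32.0), 20.0
        ) == pytest.approx(1.0)


class TestCurvature:
    def test_straight_line_zero(self):
        pts = np.column_stack([np.arange(40.0), np.zeros(40), np.zeros(40)])
        ks = curvature(pts, delta_c=8.0)
        assert ks and all(s.kappa == pytest.approx(0.0, abs=1e-12) for s in ks)

    def test_circle_radius_50(self):
        theta = np.linspace(0, 2 * np.pi, 400, endpoint=False)
        pts = np.column_stack(
            [50 * np.cos(theta), 50 * np.sin(theta), np.zeros_like(theta)]
        )
        ks = np.array([s.kappa for s in curvature(pts, delta_c=8.0)])
        assert np.median(ks) == pytest.approx(0.02, rel=0.05)

    def test_reversal_invariance(self):
        rng = np.random.default_rng(4)
        pts = np.cumsum(rng.random((80, 3)), axis=0) * 2
        k1 = sorted(s.kappa for s in curvature(pts, 8.0))
        k2 = sorted(s.kappa for s in curvature(pts[::-1], 8.0))
        np.testing.assert_allclose(k1, k2, atol=1e-9)

    def test_short_snake_empty(self):
        pts = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
        assert curvature(pts, delta_c=8.0) == []


class TestPersistenceLength:
    def test_recovery_from_model_draws(self, rng):
        # kappa ~ Rayleigh with lp = 18 voxels, Dc = 1 (9 um at 0.5 um/px)
        lp, dc = 18.0, 1.0
        ks = sample_wlc_curvature(lp, dc, 5000, rng)
        est, (lo, hi) = fit_persistence_length(
            ks, dc, n_boot=100, rng=rng, chord_tangents=False
        )
        assert est == pytest.approx(lp, rel=0.10)
        assert lo < lp < hi

    def test_doubling_lp_halves_mean_square_kappa(self, rng):
        k1 = sample_wlc_curvature(10.0, 2.0, 40000, rng)
        k2 = sample_wlc_curvature(20.0, 2.0, 40000, rng)
        assert np.mean(k1**2) / np.mean(k2**2) == pytest.approx(2.0, rel=0.1)

    def test_pipeline_recovery_from_wlc_chains(self):
        # chains -> discrete curvature -> ML fit recovers the input lp
        from filanet.phantom import make_wlc_chains

        lp, dc = 20.0, 8.0
        gt = make_wlc_chains(
            (600, 600, 600), 120, 120.0, lp=lp, seed=8, margin=150
        )
        ks = []
        for poly in gt.polylines:
            ks.extend(s.kappa for s in curvature(poly, delta_c=dc))
        est, _ = fit_persistence_length(np.asarray(ks), dc, n_boot=50)
        assert est == pytest.approx(lp, rel=0.15)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            fit_persistence_length(np.zeros(100), 8.0)


class TestSpherocylinder:
    def test_axis_points_have_zero_radius(self):
        pts = np.column_stack(
            [np.linspace(10, 50, 30), np.full(30, 32.0), np.full(30, 32.0)]
        )
        prof = spherocylinder_density(
            _net_from_points(pts),
            np.array([10.0, 32, 32]),
            np.array([50.0, 32, 32]),
            R_c=5.0,
            n_r=5,
        )
        assert prof.counts[:, 1:].sum() == 0  # everything in the r=0 bin

    def test_point_at_tip_has_zero_xt(self):
        pts = np.array([[10.0, 32, 32], [30.0, 33.0, 32]])
        prof = spherocylinder_density(
            _net_from_points(pts),
            np.array([10.0, 32, 32]),
            np.array([50.0, 32, 32]),
            R_c=5.0,
            n_xt=20,
        )
        assert prof.counts[0].sum() >= 1  # tip point lands in the first x_t bin

    def test_uniform_cylinder_flat_density(self):
        rng = np.random.default_rng(5)
        n = 60000
        a = rng.random(n) * 40 + 10
        r = 5.0 * np.sqrt(rng.random(n))
        ang = rng.random(n) * 2 * np.pi
        pts = np.column_stack(
            [a, 32 + r * np.cos(ang), 32 + r * np.sin(ang)]
        )
        prof = spherocylinder_density(
            _net_from_points(pts),
            np.array([10.0, 32, 32]),
            np.array([50.0, 32, 32]),
            R_c=5.0,
            n_xt=4,
            n_r=4,
        )
        dens = prof.density
        assert dens.std() / dens.mean() < 0.1

    def test_identical_tips_rejected(self):
        with pytest.raises(ValueError):
            spherocylinder_density(
                _net_from_points(np.zeros((3, 3))),
                np.zeros(3),
                np.zeros(3),
                R_c=1.0,
            )
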