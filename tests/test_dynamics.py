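import numpy as np
import pytest

from filanet.dynamics import (
    FREE,
    ExtractionParams,
    Snake,
    _NetworkIndex,
    evolve_snake,
    extract_all,
    local_background,
    remove_overlap,
    resample_snake,
    stretch_magnitude,
)
from filanet.imgio import Volume, rescale
from filanet.phantom import GroundTruth, PhantomSpec, densify, render


def straight_snake(x0, x1, y=32.0, z=32.0, sid=0):
    n = int(x1 - x0) + 1
    pts = np.column_stack(
        [np.linspace(x0, x1, n), np.full(n, y), np.full(n, z)]
    )
    return Snake(pts, id=sid)


class TestStretchMagnitude:
    @pytest.mark.parametrize(
        "i_f,i_b,k,expected",
        [
            (0.5, 0.5, 1.0, 0.0),  # zero contrast
            (0.6, 0.3, 0.2, 0.1),  # printed formula
            (0.3, 0.6, 1.0, 0.0),  # negative contrast clamps
            (0.5, 0.0, 1.0, 0.0),  # no background signal: stop
        ],
    )
    def test_values(self, i_f, i_b, k, expected):
        assert stretch_magnitude(i_f, i_b, k) == pytest.approx(expected)


class TestLocalBackground:
    def test_constant_image(self):
        v = Volume(np.full((32, 32, 32), 0.7), rescaled=True)
        i_f, i_b, sig = local_background(
            v, np.array([16.0, 16.0, 16.0]), np.array([1.0, 0.0, 0.0])
        )
        assert i_f == pytest.approx(0.7)
        assert i_b == pytest.approx(0.7)
        assert sig == pytest.approx(0.0, abs=1e-12)

    def test_tip_on_noiseless_filament(self, rod_volume):
        # on-axis intensity is high, annulus beyond the PSF profile is low
        i_f, i_b, _ = local_background(
            rod_volume, np.array([32.0, 32.0, 32.0]), np.array([1.0, 0.0, 0.0]),
            bg_radii=(12.0, 16.0),
        )
        assert i_f > 5 * max(i_b, 1e-6)

    def test_2d_volume_samples_flanking_segments(self):
        data = np.zeros((32, 32, 1))
        data[:, 10, 0] = 1.0  # bright line y=10
        data[:, 16, 0] = 0.5  # the filament under study at y=16
        v = Volume(data, rescaled=True)
        i_f, i_b, _ = local_background(
            v, np.array([16.0, 16.0, 0.0]), np.array([1.0, 0.0, 0.0]),
            bg_radii=(4.0, 8.0),
        )
        # the flanking segments at y in [8,12] and [20,24] catch the line
        assert i_f == pytest.approx(0.5)
        assert i_b > 0.0


class TestEvolveSnake:
    def test_centerline_seed_is_fixed_point(self, rod_volume):
        p = ExtractionParams(k_str=0.0)
        seed = straight_snake(20, 45)
        out, tjs = evolve_snake(seed, rod_volume, p)
        assert tjs == []
        d = np.linalg.norm(out.points - np.array([0, 32.0, 32.0]), axis=1)
        # stays on the centerline (y=z=32)
        off = np.linalg.norm(out.points[:, 1:] - 32.0, axis=1)
        assert off.max() < 0.5

    def test_half_seed_elongates_to_filament_ends(self, rod_volume, rod_gt):
        p = ExtractionParams(k_str=0.4)
        seed = straight_snake(25, 40)  # covers the middle of the 12..52 rod
        out, _ = evolve_snake(seed, rod_volume, p)
        xs = out.points[:, 0]
        assert xs.min() == pytest.approx(12.0, abs=2.0)
        assert xs.max() == pytest.approx(52.0, abs=2.0)

    def test_tip_collision_freezes_and_records_junction(self, crossing_volume):
        # a seed on one arm elongating into the other's body forms a T-junction
        p = ExtractionParams(k_str=0.3)
        net = _NetworkIndex()
        c = 31.5
        arm1 = densify(
            np.array([[c - 16, c - 16, 8.0], [c + 16, c + 16, 8.0]]), 1.0
        )
        net.add(Snake(arm1, id=0))
        # seed on the second arm, stopping short of the crossing
        arm2_seed = densify(
            np.array([[c - 16, c + 16, 8.0], [c - 5, c + 5, 8.0]]), 1.0
        )
        out, tjs = evolve_snake(Snake(arm2_seed, id=1), crossing_volume, p, net)
        assert len(tjs) >= 1
        tj = tjs[0]
        assert tj.tip_snake[0] == 1 and tj.body_snake[0] == 0
        assert np.linalg.norm(tj.position - np.array([c, c, 8.0])) < 3.0

    def test_damp_z_zeroes_stretch_for_z_aligned_tip(self):
        # purely z-aligned snake in a z-invariant image: no elongation
        data = np.zeros((32, 32, 32))
        data[16, 16, :] = 1.0
        from scipy.ndimage import gaussian_filter

        v = Volume(gaussian_filter(data, 1.5), rescaled=True)
        pts = np.column_stack(
            [np.full(11, 16.0), np.full(11, 16.0), np.linspace(10, 20, 11)]
        )
        p = ExtractionParams(k_str=1.0, damp_z=True, max_iter=300)
        out, _ = evolve_snake(Snake(pts, id=0), v, p)
        assert out.length() <= 11.0  # no z elongation happened


class TestRemoveOverlap:
    def _net_with(self, snake):
        net = _NetworkIndex()
        net.add(snake)
        return net

    def test_identical_snake_fully_removed(self):
        s = straight_snake(10, 40, sid=0)
        net = self._net_with(straight_snake(10, 40, sid=1))
        assert remove_overlap(s, net, 1.0, 5) == []

    def test_disjoint_snake_unchanged(self):
        s = straight_snake(10, 40, y=10.0, sid=0)
        net = self._net_with(straight_snake(10, 40, y=40.0, sid=1))
        frags = remove_overlap(s, net, 1.0, 5)
        assert len(frags) == 1
        np.testing.assert_array_equal(frags[0].points, s.points)

    def test_middle_overlap_splits_into_two_fragments(self):
        s = straight_snake(0, 59, sid=0)
        net = self._net_with(straight_snake(20, 40, y=32.5, sid=1))
        frags = remove_overlap(s, net, 1.0, min_snake_length=5)
        assert len(frags) == 2
        for f in frags:
            assert f.n_points >= 5
        # brute-force check: every surviving point is > overlap_dist away
        other = net.snakes[0].points
        for f in frags:
            d = np.min(
                np.linalg.norm(f.points[:, None] - other[None], axis=2), axis=1
            )
            assert np.all(d > 1.0)

    def test_total_length_non_increasing(self, rng):
        s = straight_snake(0, 59, sid=0)
        net = self._net_with(
            Snake(rng.random((30, 3)) * 60.0, id=1)
        )
        frags = remove_overlap(s, net, 1.5, 3)
        assert sum(f.length() for f in frags) <= s.length() + 1e-9


class TestExtractAll:
    def test_blank_image_yields_nothing(self):
        v = Volume(np.full((24, 24, 24), 0.5), rescaled=True)
        snakes, tjs = extract_all(v, ExtractionParams())
        assert snakes == [] and tjs == []

    def test_single_filament_gives_one_snake(self, rod_volume):
        p = ExtractionParams(tau=0.02, k_str=0.14)
        snakes, _ = extract_all(rod_volume, p)
        long_snakes = [s for s in snakes if s.length() > 10]
        assert len(long_snakes) == 1

    def test_deterministic(self, rod_volume):
        p = ExtractionParams(tau=0.02, k_str=0.14)
        a, _ = extract_all(rod_volume, p)
        b, _ = extract_all(rod_volume, p)
        assert len(a) == len(b)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.points, sb.points)


def test_resample_preserves_endpoints_and_spacing(rng):
    pts = np.cumsum(rng.random((20, 3)), axis=0)
    out = resample_snake(pts, 1.0)
    np.testing.assert_allclose(out[0], pts[0])
    np.testing.assert_allclose(out[-1], pts[-1])
    seg = np.linalg.norm(np.diff(out, axis=0), axis=1)
    assert seg.max() <= 1.5 and seg.min() >= 0.5 * seg.max()


def test_extraction_params_validation():
    with pytest.raises(ValueError):
        ExtractionParams(k_img=2.0)
    with pytest.raises(ValueError):
        ExtractionParams(intensity_range=(0.8, 0.2))
    with pytest.raises(ValueError):
        ExtractionParams(step=-1.0)
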