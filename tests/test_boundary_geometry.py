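"""Boundary tracing, smoothing and polar parameterisation."""

import numpy as np
import pytest

import explantmetrics as em
from explantmetrics import boundary_geometry as bg
from tests.conftest import disc_mask, ellipse_mask


def shoelace_area(points):
    """Brute-force enclosed area oracle in the (x=col, y=-row) frame."""
    x, y = points[:, 1], -points[:, 0]
    return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


class TestRetainContiguous:
    def _masks(self):
        explant = disc_mask((200, 200), (100, 100), 20)
        neurite = np.zeros((200, 200), bool)
        neurite[80:120, 118:150] = True  # touches the body
        neurite[10:20, 10:20] = True  # distant debris
        return em.BinaryMask(neurite), explant

    def test_distant_blob_removed(self):
        neurite, explant = self._masks()
        kept = bg.retain_contiguous(neurite, explant)
        assert kept.pixels[90, 130]
        assert not kept.pixels[15, 15]

    def test_disjoint_neurite_gives_empty(self):
        explant = disc_mask((100, 100), (50, 50), 10)
        neurite = np.zeros((100, 100), bool)
        neurite[5:10, 5:10] = True
        assert bg.retain_contiguous(em.BinaryMask(neurite), explant).is_empty

    def test_8_neighbour_contact_counts(self):
        explant = np.zeros((10, 10), bool)
        explant[4, 4] = True
        neurite = np.zeros((10, 10), bool)
        neurite[5, 5] = True  # diagonal neighbour only
        kept = bg.retain_contiguous(em.BinaryMask(neurite), em.BinaryMask(explant))
        assert kept.pixels[5, 5]

    def test_idempotent(self):
        neurite, explant = self._masks()
        once = bg.retain_contiguous(neurite, explant)
        twice = bg.retain_contiguous(once, explant)
        assert np.array_equal(once.pixels, twice.pixels)

    def test_empty_explant_rejected(self):
        with pytest.raises(em.EmptyMaskError):
            bg.retain_contiguous(
                em.BinaryMask(np.ones((5, 5), bool)), em.BinaryMask(np.zeros((5, 5), bool))
            )


class TestTraceOuterBoundary:
    def test_single_pixel(self):
        m = np.zeros((5, 5), bool)
        m[2, 3] = True
        curve = bg.trace_outer_boundary(em.BinaryMask(m))
        assert np.array_equal(curve.points, [[2.0, 3.0]])

    def test_filled_square_perimeter(self):
        # brute-force oracle: pixels of a filled 10x10 square with a
        # 4-connected background neighbour
        m = np.pad(np.ones((10, 10), bool), 3)
        curve = bg.trace_outer_boundary(em.BinaryMask(m))
        assert len(curve) == 36
        interior = np.pad(np.ones((8, 8), bool), 4)
        expected = set(map(tuple, np.argwhere(m & ~interior)))
        assert set(map(tuple, curve.points.astype(int))) == expected

    def test_disc_radii_within_one_pixel(self):
        curve = bg.trace_outer_boundary(disc_mask((201, 201), (100, 100), 50))
        radii = np.hypot(curve.points[:, 0] - 100, curve.points[:, 1] - 100)
        assert np.all(np.abs(radii - 50) <= 1.0)

    def test_counter_clockwise_orientation(self):
        curve = bg.trace_outer_boundary(disc_mask((101, 101), (50, 50), 20))
        assert curve.signed_area() > 0

    def test_largest_component_selected(self):
        m = np.zeros((60, 60), bool)
        m[5:10, 5:10] = True
        m[20:50, 20:50] = True
        curve = bg.trace_outer_boundary(em.BinaryMask(m))
        assert curve.points[:, 0].min() >= 20

    def test_consecutive_points_8_connected(self):
        curve = bg.trace_outer_boundary(disc_mask((101, 101), (50, 50), 22))
        steps = np.abs(np.diff(np.vstack([curve.points, curve.points[:1]]), axis=0))
        assert steps.max() <= 1

    def test_empty_mask_rejected(self):
        with pytest.raises(em.EmptyMaskError):
            bg.trace_outer_boundary(em.BinaryMask(np.zeros((5, 5), bool)))


class TestCentroid:
    def test_two_pixels(self):
        m = np.zeros((3, 12), bool)
        m[0, 0] = m[0, 10] = True
        assert bg.centroid(em.BinaryMask(m)) == (0.0, 5.0)

    def test_symmetric_disc(self):
        r, c = bg.centroid(disc_mask((201, 201), (100, 100), 40))
        assert abs(r - 100) < 0.5 and abs(c - 100) < 0.5

    def test_matches_brute_force_mean(self):
        rng = np.random.default_rng(7)
        m = rng.random((30, 40)) > 0.7
        rows, cols = np.nonzero(m)
        assert bg.centroid(em.BinaryMask(m)) == (rows.mean(), cols.mean())


class TestSmoothBoundary:
    def test_width_one_is_identity(self):
        curve = bg.trace_outer_boundary(disc_mask((101, 101), (50, 50), 20))
        out = bg.smooth_boundary(curve, 1)
        assert np.array_equal(out.points, curve.points)

    def test_circle_shrinks_by_analytic_attenuation(self):
        # circular moving average multiplies the first harmonic (the
        # coordinates of a circle) by sin(pi*w/M) / (w*sin(pi/M))
        m, w, r = 400, 45, 100.0
        t = 2 * np.pi * np.arange(m) / m
        curve = bg.BoundaryCurve(np.column_stack([r * np.sin(t), r * np.cos(t)]))
        sm = bg.smooth_boundary(curve, w)
        radii = np.hypot(sm.points[:, 0], sm.points[:, 1])
        lam = np.sin(np.pi * w / m) / (w * np.sin(np.pi / m))
        assert np.allclose(radii, lam * r, atol=1e-9)
        assert radii.max() < r  # strict shrinkage

    def test_square_area_strictly_decreases(self):
        curve = bg.trace_outer_boundary(em.BinaryMask(np.pad(np.ones((20, 20), bool), 5)))
        sm = bg.smooth_boundary(curve, 9)
        assert shoelace_area(sm.points) < shoelace_area(curve.points)
        assert len(sm) == len(curve)

    def test_width_exceeding_length_rejected(self):
        curve = bg.trace_outer_boundary(disc_mask((21, 21), (10, 10), 3))
        with pytest.raises(ValueError, match="width"):
            bg.smooth_boundary(curve, 1000)


class TestRadialProfile:
    def test_concentric_circles_constant(self):
        soma = bg.trace_outer_boundary(disc_mask((301, 301), (150, 150), 30))
        outer = bg.trace_outer_boundary(disc_mask((301, 301), (150, 150), 80))
        prof = bg.radial_profile(soma, outer, (150.0, 150.0))
        assert prof.n_angles == 360
        assert np.all(np.abs(prof.values - 50.0) <= 1.0)

    def test_identical_curves_zero(self):
        c = bg.trace_outer_boundary(disc_mask((101, 101), (50, 50), 30))
        prof = bg.radial_profile(c, c, (50.0, 50.0))
        assert np.all(prof.values == 0.0)

    def test_ellipse_matches_analytic_polar_radius(self):
        centre = (200.0, 200.0)
        soma = bg.trace_outer_boundary(disc_mask((401, 401), centre, 40))
        outer = bg.trace_outer_boundary(ellipse_mask((401, 401), centre, 120, 160))
        prof = bg.radial_profile(soma, outer, centre)
        theta = prof.thetas
        # semi-axis 160 along x (cols), 120 along y (rows)
        a, b = 160.0, 120.0
        analytic = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
        assert np.all(np.abs(prof.values - (analytic - 40.0)) <= 1.0)

    def test_translation_equivariance(self):
        shape = (301, 301)
        soma = disc_mask(shape, (120, 130), 25)
        outer = disc_mask(shape, (120, 130), 70)

        def profile(soma_m, outer_m, origin):
            return bg.radial_profile(
                bg.trace_outer_boundary(soma_m), bg.trace_outer_boundary(outer_m), origin
            ).values

        base = profile(soma, outer, (120.0, 130.0))
        soma_t = em.BinaryMask(np.roll(np.roll(soma.pixels, 30, axis=0), -20, axis=1))
        outer_t = em.BinaryMask(np.roll(np.roll(outer.pixels, 30, axis=0), -20, axis=1))
        shifted = profile(soma_t, outer_t, (150.0, 110.0))
        assert np.allclose(base, shifted)

    def test_quarter_turn_shifts_profile(self):
        """90 deg CCW rotation cyclically shifts R by N/4 samples (+/-1)."""
        truth = em.SyntheticTruth(a0=90.0, b1=20.0, a2=8.0, noise_amplitude=5.0, seed=5)
        explant, neurite, _ = em.generate_explant(truth, shape=(1024, 1024))
        res = em.quantify_explant(neurite, explant)
        rot = em.quantify_explant(
            em.BinaryMask(np.rot90(neurite.pixels)), em.BinaryMask(np.rot90(explant.pixels))
        )
        base = res.outgrowth_coeffs
        n = base.n_angles
        prof = em.reconstruct(base, n // 2)
        prof_rot = em.reconstruct(rot.outgrowth_coeffs, n // 2)
        best = min(
            np.max(np.abs(np.roll(prof, n // 4 + d) - prof_rot)) for d in (-1, 0, 1)
        )
        assert best <= 2.0

    def test_odd_angle_count_rejected(self):
        c = bg.trace_outer_boundary(disc_mask((101, 101), (50, 50), 30))
        with pytest.raises(ValueError):
            bg.radial_profile(c, c, (50.0, 50.0), n_angles=359)

    def test_nonnegative_even_when_outer_inside(self):
        soma = bg.trace_outer_boundary(disc_mask((101, 101), (50, 50), 30))
        inner = bg.trace_outer_boundary(disc_mask((101, 101), (50, 50), 10))
        prof = bg.radial_profile(soma, inner, (50.0, 50.0))
        assert np.all(prof.values >= 0)
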