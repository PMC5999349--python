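"""Geometric feature extraction against closed forms and pixel oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rtdcstats import (
    Contour,
    ImagePatch,
    compute_area,
    compute_area_ratio,
    compute_bounding_box,
    compute_brightness,
    compute_deformation,
    compute_haralick,
    compute_inertia_ratio,
    compute_orientation,
    compute_symmetry,
    compute_volume,
    equivalent_diameter,
    extract_features,
    gen_contour,
)
from rtdcstats.features import DegenerateContourError, HARALICK_NAMES, _glcm, _mask_for


def shoelace(points):
    x, y = points[:, 0], points[:, 1]
    return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def rotate90(contour):
    pts = contour.points[:, ::-1].copy()
    pts[:, 0] *= -1  # (x, y) -> (-y, x)
    return Contour(pts, contour.pixel_size)


class TestArea:
    def test_unit_square(self, unit_square):
        assert compute_area(unit_square) == pytest.approx(1.0)

    def test_circle_matches_pi_r2(self, circle_360):
        assert compute_area(circle_360) == pytest.approx(math.pi * 100, rel=1e-3)

    def test_pixel_size_scaling(self):
        sq = Contour(np.array([[0, 0], [10, 0], [10, 10], [0, 10]], float),
                     pixel_size=0.34)
        assert compute_area(sq) == pytest.approx(11.56)

    def test_degenerate_contour_raises(self):
        collinear = Contour(np.array([[0, 0], [1, 1], [2, 2]], float))
        with pytest.raises(DegenerateContourError):
            compute_area(collinear)


class TestBoundingBox:
    def test_unit_square(self, unit_square):
        assert compute_bounding_box(unit_square) == (1.0, 1.0)

    def test_ellipse_extents(self, ellipse_8_4):
        lx, ly = compute_bounding_box(ellipse_8_4)
        assert lx == pytest.approx(16.0, abs=0.1)
        assert ly == pytest.approx(8.0, abs=0.1)

    def test_rotation_by_90_swaps(self, ellipse_8_4):
        lx, ly = compute_bounding_box(ellipse_8_4)
        lx2, ly2 = compute_bounding_box(rotate90(ellipse_8_4))
        assert (lx2, ly2) == pytest.approx((ly, lx))


class TestDeformation:
    def test_circle_near_zero(self, circle_360):
        _, d, _ = compute_deformation(circle_360)
        assert 0 <= d < 1e-3

    def test_ellipse_against_dense_perimeter(self):
        a, b = 8.0, 4.0
        contour = gen_contour("ellipse", a=a, b=b, n_vertices=2000)
        t = np.linspace(0, 2 * math.pi, 200001)
        dense = np.column_stack([a * np.cos(t), b * np.sin(t)])
        perim = np.sum(np.hypot(*np.diff(dense, axis=0).T))
        expected_c = 2 * math.sqrt(math.pi * compute_area(contour)) / perim
        c, d, _ = compute_deformation(contour)
        assert c == pytest.approx(expected_c, abs=1e-3)
        assert d == pytest.approx(1 - expected_c, abs=1e-3)

    def test_hull_reduces_deformation_for_star(self, star_5):
        c_hull, d_hull, hull = compute_deformation(star_5)
        raw_perimeter = np.sum(np.hypot(
            *np.diff(np.vstack([star_5.points, star_5.points[:1]]), axis=0).T))
        a = compute_area(star_5)
        d_raw = 1 - 2 * math.sqrt(math.pi * a) / raw_perimeter
        assert d_hull < d_raw


class TestVolume:
    def test_sphere(self, circle_360):
        contour = gen_contour("circle", radius=5.0, n_vertices=360)
        assert compute_volume(contour) == pytest.approx(4 / 3 * math.pi * 125,
                                                        rel=0.01)

    def test_spheroid(self, ellipse_8_4):
        # revolution about the flow axis: V = 4/3 pi a b^2
        assert compute_volume(ellipse_8_4) == pytest.approx(
            4 / 3 * math.pi * 8 * 16, rel=0.01)

    def test_vertex_count_convergence(self):
        errs = []
        for n in (60, 180, 720):
            c = gen_contour("circle", radius=5.0, n_vertices=n)
            errs.append(abs(compute_volume(c) - 4 / 3 * math.pi * 125))
        assert errs[0] > errs[1] > errs[2]
        assert errs[1] < 0.01 * 4 / 3 * math.pi * 125

    def test_mirror_symmetric_halves_agree(self):
        # a mirror-symmetric contour gives identical estimates from the
        # upper and the lower half, so averaging changes nothing
        c = gen_contour("ellipse", a=6.0, b=3.0, n_vertices=360)
        v = compute_volume(c)
        flipped = Contour(c.points * [1, -1], c.pixel_size)
        assert compute_volume(flipped) == pytest.approx(v, rel=1e-12)


def rasterized_moment_oracle(a, b, phi=0.0, n=2001):
    """Pixel-integration of the area's second moments for an ellipse."""
    span = max(a, b) * 1.2
    g = np.linspace(-span, span, n)
    xx, yy = np.meshgrid(g, g, indexing="ij")
    c, s = math.cos(phi), math.sin(phi)
    u = xx * c + yy * s
    v = -xx * s + yy * c
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1
    ixx = np.sum(yy[inside] ** 2)
    iyy = np.sum(xx[inside] ** 2)
    return iyy / ixx


class TestInertiaAndOrientation:
    def test_circle_is_isotropic(self, circle_360):
        assert compute_inertia_ratio(circle_360) == pytest.approx(1.0, abs=1e-3)
        assert compute_orientation(circle_360) == 0.0

    def test_unit_square(self, unit_square):
        assert compute_inertia_ratio(unit_square) == pytest.approx(1.0)

    def test_ellipse_ratio_vs_pixel_oracle(self, ellipse_8_4):
        got = compute_inertia_ratio(ellipse_8_4)
        assert got == pytest.approx(4.0, rel=0.01)  # (a/b)^2
        assert got == pytest.approx(rasterized_moment_oracle(8, 4), rel=0.01)

    def test_rotation_by_90_inverts(self, ellipse_8_4):
        i = compute_inertia_ratio(ellipse_8_4)
        assert compute_inertia_ratio(rotate90(ellipse_8_4)) == pytest.approx(
            1 / i, rel=1e-9)

    def test_axis_aligned_orientation_zero(self, ellipse_8_4):
        assert compute_orientation(ellipse_8_4) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("angle", [math.pi / 6, -math.pi / 8, 1.2])
    def test_rotated_ellipse_orientation(self, angle):
        c = gen_contour("ellipse", a=8.0, b=4.0, n_vertices=720, rotation=angle)
        expected = angle
        while expected > math.pi / 2:
            expected -= math.pi
        while expected <= -math.pi / 2:
            expected += math.pi
        assert compute_orientation(c) == pytest.approx(expected, abs=1e-2)

    def test_translation_invariance(self, ellipse_8_4):
        shifted = Contour(ellipse_8_4.points + [123.0, -45.0])
        assert compute_inertia_ratio(shifted) == pytest.approx(
            compute_inertia_ratio(ellipse_8_4), rel=1e-9)
        assert compute_orientation(shifted) == pytest.approx(
            compute_orientation(ellipse_8_4), abs=1e-9)


class TestAreaRatio:
    def test_convex_is_one(self, circle_360):
        assert compute_area_ratio(circle_360) == pytest.approx(1.0, abs=1e-6)

    def test_star_matches_hull_oracle(self, star_5):
        from scipy.spatial import ConvexHull

        hull = ConvexHull(star_5.points)
        expected = hull.volume / shoelace(star_5.points)  # volume == area in 2D
        got = compute_area_ratio(star_5)
        assert got > 1
        assert got == pytest.approx(expected, abs=1e-6)

    def test_modulus_gate_excludes_corrugated(self, star_5):
        from rtdcstats.surrogate import AREA_RATIO_GATE

        lo, hi = AREA_RATIO_GATE
        assert not lo <= 1.06 <= hi
        assert not lo <= compute_area_ratio(star_5) <= hi


class TestSymmetry:
    def test_mirror_symmetric_is_zero(self, ellipse_8_4):
        sx, sy = compute_symmetry(ellipse_8_4)
        assert sx == pytest.approx(0.0, abs=1e-6)
        assert sy == pytest.approx(0.0, abs=1e-6)

    def test_asymmetric_blob_vs_pixel_oracle(self):
        contour = gen_contour("blob", radius=20.0, roughness=0.25, seed=7,
                              n_vertices=240)
        sx, sy = compute_symmetry(contour)
        # rasterized area counting above/below the centroid axes
        cx, cy = contour.centroid()
        n = 4001
        span = np.abs(contour.points - [cx, cy]).max() * 1.1
        g = np.linspace(-span, span, n)
        xx, yy = np.meshgrid(g + cx, g + cy, indexing="ij")
        from matplotlib.path import Path

        inside = Path(contour.points).contains_points(
            np.column_stack([xx.ravel(), yy.ravel()])).reshape(xx.shape)
        a_up = np.sum(inside & (yy < cy))
        a_low = np.sum(inside & (yy >= cy))
        assert sx == pytest.approx((a_up - a_low) / (a_up + a_low), abs=0.01)
        a_left = np.sum(inside & (xx < cx))
        a_right = np.sum(inside & (xx >= cx))
        assert sy == pytest.approx((a_left - a_right) / (a_left + a_right),
                                   abs=0.01)
        assert abs(sx) <= 1 and abs(sy) <= 1

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_bounded_for_random_blobs(self, seed):
        contour = gen_contour("blob", radius=10.0, roughness=0.2, seed=seed,
                              n_vertices=60)
        sx, sy = compute_symmetry(contour)
        assert -1 <= sx <= 1
        assert -1 <= sy <= 1


class TestBrightness:
    def patch(self, values):
        return ImagePatch(np.asarray(values, dtype=np.uint8), origin=(0.0, 0.0))

    def square_contour(self):
        return Contour(np.array([[0.5, 0.5], [8.5, 0.5], [8.5, 8.5], [0.5, 8.5]]))

    def test_uniform(self):
        img = self.patch(np.full((10, 10), 100))
        b, bstd = compute_brightness(img, self.square_contour())
        assert (b, bstd) == (100.0, 0.0)

    def test_bimodal(self):
        vals = np.zeros((10, 10), dtype=np.uint8)
        vals[:, ::2] = 200
        img = self.patch(vals)
        contour = Contour(np.array([[-0.5, -0.5], [9.5, -0.5],
                                    [9.5, 9.5], [-0.5, 9.5]]))
        b, bstd = compute_brightness(img, contour)
        assert b == pytest.approx(100.0)
        assert bstd == pytest.approx(100.0)

    def test_outside_pixels_ignored(self):
        rng = np.random.default_rng(3)
        vals = rng.integers(0, 256, size=(20, 20)).astype(np.uint8)
        img = self.patch(vals)
        contour = Contour(np.array([[4.5, 4.5], [14.5, 4.5],
                                    [14.5, 14.5], [4.5, 14.5]]))
        b, bstd = compute_brightness(img, contour)
        mask = np.zeros((20, 20), bool)
        mask[5:15, 5:15] = True  # brute-force: pixel centers strictly inside
        assert b == pytest.approx(vals[mask].mean())
        assert bstd == pytest.approx(vals[mask].std())

    def test_empty_mask_raises(self):
        img = self.patch(np.full((5, 5), 7))
        tiny = Contour(np.array([[0.1, 0.1], [0.2, 0.1], [0.2, 0.2]]))
        with pytest.raises(ValueError):
            compute_brightness(img, tiny)


def brute_force_glcm(binned, mask, levels):
    """Naive loop oracle: symmetric normalized co-occurrence counts."""
    counts = np.zeros((levels, levels))
    rows, cols = binned.shape
    for r in range(rows):
        for c in range(cols):
            if not mask[r, c]:
                continue
            for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < rows and 0 <= c2 < cols and mask[r2, c2]:
                    counts[binned[r, c], binned[r2, c2]] += 1
                    counts[binned[r2, c2], binned[r, c]] += 1
    return counts / counts.sum()


class TestHaralick:
    def test_uniform_patch(self):
        img = ImagePatch(np.full((12, 12), 77, dtype=np.uint8))
        contour = Contour(np.array([[0.5, 0.5], [10.5, 0.5],
                                    [10.5, 10.5], [0.5, 10.5]]))
        h = compute_haralick(img, contour)
        feats = dict(zip(HARALICK_NAMES, h))
        assert feats["asm"] == pytest.approx(1.0)
        assert feats["entropy"] == pytest.approx(0.0)

    def test_glcm_matches_brute_force(self):
        rng = np.random.default_rng(11)
        vals = rng.integers(0, 256, size=(8, 8)).astype(np.uint8)
        img = ImagePatch(vals)
        contour = Contour(np.array([[0.5, 0.5], [6.5, 0.5],
                                    [6.5, 6.5], [0.5, 6.5]]))
        mask = _mask_for(img, contour)
        levels = 16
        got = _glcm(img, mask, levels)
        binned = (vals.astype(int) * levels) >> 8
        expected = brute_force_glcm(binned, mask, levels)
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_vector_has_13_entries(self):
        rng = np.random.default_rng(1)
        img = ImagePatch(rng.integers(0, 256, size=(10, 10)).astype(np.uint8))
        contour = Contour(np.array([[0.5, 0.5], [8.5, 0.5],
                                    [8.5, 8.5], [0.5, 8.5]]))
        assert compute_haralick(img, contour).shape == (13,)

    def test_mask_too_small_raises(self):
        img = ImagePatch(np.full((5, 5), 9, dtype=np.uint8))
        # one isolated pixel center inside -> no neighbor pair
        tiny = Contour(np.array([[1.6, 1.6], [2.4, 1.6], [2.4, 2.4], [1.6, 2.4]]))
        with pytest.raises(ValueError):
            compute_haralick(img, tiny)


class TestEquivalentDiameter:
    @pytest.mark.parametrize("area,expected,tol", [
        (174.0, 14.9, 0.05),
        (281.0, 18.91, 0.01),  # exact value 18.915, printed to 0.01
        (math.pi, 2.0, 1e-12),
    ])
    def test_values(self, area, expected, tol):
        assert equivalent_diameter(area) == pytest.approx(expected, abs=tol)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            equivalent_diameter(0.0)


class TestFullRecord:
    def test_feature_record_invariants(self):
        contour, image = gen_contour("blob", radius=15.0, roughness=0.1,
                                     seed=5, texture=(120.0, 10.0))
        rec = extract_features(contour, image)
        assert rec.A > 0 and rec.V > 0
        assert 0 < rec.C <= 1 and rec.D == pytest.approx(1 - rec.C)
        assert rec.I > 0 and rec.Delta >= 1 - 1e-9
        assert -1 <= rec.Sx <= 1 and -1 <= rec.Sy <= 1
        assert rec.Lx > 0 and rec.Ly > 0
        assert np.all(np.isfinite(rec.haralick))

    def test_translation_changes_nothing(self):
        c1 = gen_contour("blob", radius=12.0, roughness=0.15, seed=9)
        c2 = Contour(c1.points + [37.0, 11.0])
        r1, r2 = extract_features(c1), extract_features(c2)
        for key in ("A", "V", "C", "D", "I", "Delta", "Sx", "Sy"):
            assert getattr(r1, key) == pytest.approx(getattr(r2, key), rel=1e-9)
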