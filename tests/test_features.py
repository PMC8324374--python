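import math

import numpy as np
import pytest

from conftest import component_from_mask, disk_mask, ellipse_mask
from polylobe.features import (
    Ellipse,
    aspect_ratio,
    bounding_rectangle,
    component_area,
    eccentricity,
    ellipse_plumpness,
    feature_vector,
    fit_ellipse,
    rect_plumpness,
)
from polylobe.segmentation import Component


def _component(pixels):
    coords = np.array(sorted(pixels))
    return Component(label=1, coords=coords, area=len(coords))


class TestAreaAndRectangle:
    def test_filled_rectangle_area(self):
        mask = np.zeros((10, 10), bool)
        mask[2:5, 3:7] = True  # 3 rows x 4 cols
        c = component_from_mask(mask)
        assert component_area(c) == 12

    def test_single_pixel(self):
        c = _component([(4, 4)])
        assert component_area(c) == 1
        r = bounding_rectangle(c)
        assert (r.a1, r.b1) == (1, 1)

    def test_two_pixels_same_row(self):
        # pixels at columns 2 and 5 in one row: horizontal extent 4, vertical 1
        c = _component([(3, 2), (3, 5)])
        r = bounding_rectangle(c)
        assert (r.a1, r.b1) == (4, 1)

    def test_wide_rectangle_extents(self):
        mask = np.zeros((12, 16), bool)
        mask[4:8, 2:12] = True  # 10 wide x 4 tall
        r = bounding_rectangle(component_from_mask(mask))
        assert (r.a1, r.b1) == (10, 4)

    def test_area_matches_mask_sum_on_random_blobs(self, rng):
        for _ in range(10):
            mask = rng.random((15, 15)) > 0.4
            from polylobe.segmentation import label_components

            for c in label_components(mask, 8).components:
                m = c.mask(mask.shape)
                assert component_area(c) == int(m.sum())


class TestPlumpnessAndAspect:
    def test_filled_rectangle_p1_exactly_one(self):
        mask = np.zeros((20, 20), bool)
        mask[3:9, 5:17] = True
        assert rect_plumpness(component_from_mask(mask)) == 1.0

    def test_diagonal_line_p1(self):
        c = _component([(i, i) for i in range(5)])
        assert rect_plumpness(c) == pytest.approx(5 / 25)

    def test_disk_p1_approaches_pi_over_4(self):
        # box is (2r+1)^2, so P1 = pi*r^2/(2r+1)^2 converges from below
        c = component_from_mask(disk_mask(40))
        assert rect_plumpness(c) == pytest.approx(math.pi / 4, abs=0.02)

    def test_aspect_ratio_values(self):
        from polylobe.features import Rect

        assert aspect_ratio(Rect(a1=10, b1=4, origin=(0, 0))) == pytest.approx(0.4)
        assert aspect_ratio(Rect(a1=7, b1=7, origin=(0, 0))) == 1.0
        assert aspect_ratio(Rect(a1=4, b1=10, origin=(0, 0))) == pytest.approx(2.5)

    def test_aspect_ratio_transpose_inverts(self, rng):
        from polylobe.features import Rect

        for _ in range(10):
            a1, b1 = rng.integers(1, 50, size=2)
            r = Rect(a1=int(a1), b1=int(b1), origin=(0, 0))
            rt = Rect(a1=int(b1), b1=int(a1), origin=(0, 0))
            assert aspect_ratio(r) * aspect_ratio(rt) == pytest.approx(1.0)


class TestMomentEllipse:
    def test_disk_recovers_radius(self):
        c = component_from_mask(disk_mask(20))
        el = fit_ellipse(c)
        assert el.a2 == pytest.approx(20, rel=0.03)
        assert el.b2 == pytest.approx(20, rel=0.03)

    def test_axis_aligned_ellipse_recovers_axes(self):
        c = component_from_mask(ellipse_mask(30, 10))
        el = fit_ellipse(c)
        assert el.a2 == pytest.approx(30, rel=0.03)
        assert el.b2 == pytest.approx(10, rel=0.03)
        assert abs(el.orientation) < 0.05

    def test_rotation_by_90_preserves_axes(self):
        mask = ellipse_mask(25, 8)
        a = fit_ellipse(component_from_mask(mask))
        b = fit_ellipse(component_from_mask(mask.T))
        assert b.a2 == pytest.approx(a.a2, rel=1e-6)
        assert b.b2 == pytest.approx(a.b2, rel=1e-6)
        assert abs(abs(a.orientation - b.orientation) - math.pi / 2) < 1e-6

    def test_degenerate_single_pixel_flagged(self):
        el = fit_ellipse(_component([(2, 2)]))
        assert el.degenerate and el.b2 == 0.5

    def test_collinear_pixels_flagged(self):
        el = fit_ellipse(_component([(0, i) for i in range(6)]))
        assert el.degenerate

    def test_matches_skimage_regionprops(self):
        from skimage.measure import regionprops

        mask = ellipse_mask(22, 13)
        c = component_from_mask(mask)
        el = fit_ellipse(c)
        props = regionprops(mask.astype(int))[0]
        # regionprops omits the unit-square pixel term; agree to ~2%
        assert el.a2 == pytest.approx(props.axis_major_length / 2, rel=0.02)
        assert el.b2 == pytest.approx(props.axis_minor_length / 2, rel=0.02)
        assert eccentricity(el) == pytest.approx(props.eccentricity, abs=0.02)


class TestEllipsePlumpnessAndEccentricity:
    def test_ideal_ellipse_p2_near_one(self):
        c = component_from_mask(ellipse_mask(30, 10))
        assert ellipse_plumpness(c) == pytest.approx(1.0, abs=0.03)

    def test_disk_p2_near_one(self):
        c = component_from_mask(disk_mask(20))
        assert ellipse_plumpness(c) == pytest.approx(1.0, abs=0.03)

    def test_two_distant_disks_p2_low(self):
        mask = np.zeros((40, 100), bool)
        yy, xx = np.mgrid[:40, :100]
        mask |= (yy - 20) ** 2 + (xx - 15) ** 2 <= 100
        mask |= (yy - 20) ** 2 + (xx - 85) ** 2 <= 100
        mask[20, 15:86] = True  # thin bridge keeps it one component
        c = component_from_mask(mask)
        assert ellipse_plumpness(c) < 0.5

    def test_degenerate_p2_raises(self):
        with pytest.raises(ValueError):
            ellipse_plumpness(_component([(2, 2)]))

    def test_circle_eccentricity_zero(self):
        assert eccentricity(Ellipse(a2=5, b2=5, center=(0, 0), orientation=0)) == 0.0

    def test_five_three_ellipse(self):
        el = Ellipse(a2=5, b2=3, center=(0, 0), orientation=0)
        assert eccentricity(el) == pytest.approx(0.8)

    def test_flat_limit_approaches_one(self):
        el = Ellipse(a2=1.0, b2=1e-6, center=(0, 0), orientation=0)
        assert eccentricity(el) == pytest.approx(1.0, abs=1e-6)

    def test_invalid_axes_raise(self):
        with pytest.raises(ValueError):
            eccentricity(Ellipse(a2=3, b2=5, center=(0, 0), orientation=0))


class TestFeatureVector:
    def test_filled_square(self):
        mask = np.zeros((14, 14), bool)
        mask[2:12, 2:12] = True
        f = feature_vector(component_from_mask(mask))
        assert f.A == 100 and f.P1 == 1.0 and f.s == 1.0
        assert f.e == pytest.approx(0.0, abs=1e-9)

    def test_wide_rectangle(self):
        mask = np.zeros((16, 36), bool)
        mask[3:13, 3:33] = True  # 30 wide x 10 tall
        f = feature_vector(component_from_mask(mask))
        assert f.P1 == 1.0 and f.s == pytest.approx(1 / 3)

    def test_fields_match_per_formula_recomputation(self, rng):
        from polylobe.segmentation import label_components

        mask = rng.random((25, 25)) > 0.3
        comps = label_components(mask, 8).components
        big = max(comps, key=lambda c: c.area)
        f = feature_vector(big)
        r = bounding_rectangle(big)
        el = fit_ellipse(big)
        assert f.A == big.area
        assert f.P1 == pytest.approx(big.area / (r.a1 * r.b1))
        assert f.s == pytest.approx(r.b1 / r.a1)
        assert f.P2 == pytest.approx(big.area / (math.pi * el.a2 * el.b2))
        assert f.e == pytest.approx(eccentricity(el))

    def test_invariants_on_random_blobs(self, rng):
        from polylobe.segmentation import label_components

        for _ in range(15):
            mask = rng.random((20, 20)) > 0.5
            for c in label_components(mask, 8).components:
                f = feature_vector(c)
                assert 0 < f.P1 <= 1.0
                assert 0 <= f.e < 1
                assert f.P2 > 0

    def test_translation_invariance(self):
        mask = np.zeros((30, 30), bool)
        mask[4:12, 5:19] = True
        mask[6, 2:5] = True
        f0 = feature_vector(component_from_mask(mask))
        shifted = np.roll(np.roll(mask, 7, axis=0), 3, axis=1)
        f1 = feature_vector(component_from_mask(shifted))
        for attr in ("A", "P1", "s", "P2", "e"):
            assert getattr(f0, attr) == pytest.approx(getattr(f1, attr), abs=1e-12)

    def test_rotation_90_maps_s_to_inverse(self):
        mask = np.zeros((20, 40), bool)
        mask[5:15, 4:36] = True
        mask[7:9, 2:4] = True
        f0 = feature_vector(component_from_mask(mask))
        f1 = feature_vector(component_from_mask(mask.T))
        assert f1.s == pytest.approx(1 / f0.s)
        for attr in ("A", "P1", "P2", "e"):
            assert getattr(f0, attr) == pytest.approx(getattr(f1, attr), abs=1e-9)

    @pytest.mark.parametrize("r", [10, 20, 40])
    def test_disk_calibration_tightens_with_radius(self, r):
        # discretization error of both P1 and e shrinks roughly like 1/r
        f = feature_vector(component_from_mask(disk_mask(r)))
        assert abs(f.P1 - math.pi / 4) < 1.4 / r
        assert f.e < 0.8 / r
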