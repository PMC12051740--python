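"""Segmentation recovery and morphological shape descriptors."""

import numpy as np
import pytest
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon

from mechspheroid.io import BrillouinMap, MechSpheroidError, SegmentationError
from mechspheroid.segment import (SpheroidMask, aspect_ratio, circularity,
                                  cv_hull_radii, morphological_features,
                                  projection_area, segment_spheroid, solidity)
from mechspheroid.sim import default_phenotype_table, generate_spheroid_map


def _jaccard(a, b):
    return (a & b).sum() / (a | b).sum()


class TestSegmentation:
    def test_recovers_ground_truth_masks(self):
        """Default-parameter maps are segmented with high overlap."""
        jaccards = []
        for (line, day) in [("normal", 2), ("normal", 8),
                            ("cancer", 2), ("cancer", 8)]:
            params = default_phenotype_table()[(line, day)]
            for seed in range(5):
                bmap, truth, _ = generate_spheroid_map(params, 1.0, seed=seed)
                recovered = segment_spheroid(bmap)
                jaccards.append(_jaccard(recovered.mask, truth))
        assert np.mean(jaccards) >= 0.95
        assert min(jaccards) >= 0.85

    def test_uniform_image_fails_cleanly(self):
        flat = BrillouinMap(np.full((64, 64), 5.0), 1.0)
        with pytest.raises(SegmentationError) as err:
            segment_spheroid(flat)
        assert err.value.threshold is not None

    def test_idempotent_on_binary_contrast(self, disk_mask):
        shifts = np.where(disk_mask, 5.3, 5.0)
        bmap = BrillouinMap(shifts, 1.0)
        recovered = segment_spheroid(bmap)
        assert np.array_equal(recovered.mask, disk_mask)

    def test_mask_invariants_enforced(self):
        two = np.zeros((64, 64), bool)
        two[5:15, 5:15] = True
        two[40:50, 40:50] = True
        with pytest.raises(MechSpheroidError):
            SpheroidMask(two, 1.0)
        holey = np.zeros((64, 64), bool)
        holey[10:40, 10:40] = True
        holey[20:25, 20:25] = False
        with pytest.raises(MechSpheroidError):
            SpheroidMask(holey, 1.0)

    def test_equivalent_radius_definition(self, disk_mask):
        mask = SpheroidMask(disk_mask, 2.0)
        area_um2 = disk_mask.sum() * 4.0
        assert mask.equivalent_radius == pytest.approx(
            np.sqrt(area_um2 / np.pi))


class TestProjectionArea:
    def test_square_pixel_count(self, square_mask):
        assert projection_area(square_mask, 1.0) == 900.0

    def test_scales_with_pixel_size_squared(self, square_mask):
        assert projection_area(square_mask, 2.0) == 3600.0

    def test_rasterized_disk_near_analytic(self, disk_mask):
        assert projection_area(disk_mask, 1.0) == pytest.approx(
            np.pi * 40 ** 2, rel=0.02)


class TestCircularity:
    def test_disk_is_maximal(self, disk_mask):
        assert circularity(disk_mask) == pytest.approx(1.0, abs=0.05)

    def test_square_closed_form(self, square_mask):
        # 4*pi*s^2 / (4s)^2 = pi/4
        assert circularity(square_mask) == pytest.approx(np.pi / 4, abs=0.05)

    def test_rectangle_closed_form(self):
        rect = np.zeros((60, 20), bool)
        rect[10:50, 5:15] = True
        # 4*pi*ab/(2a+2b)^2 with a=4, b=1 units
        assert circularity(rect) == pytest.approx(16 * np.pi / 100, abs=0.05)

    def test_degenerate_mask_rejected(self):
        single = np.zeros((20, 20), bool)
        single[10, 10] = True
        with pytest.raises(MechSpheroidError):
            circularity(single)


class TestSolidity:
    def test_square_is_convex(self, square_mask):
        assert solidity(square_mask) == pytest.approx(1.0, abs=0.01)

    def test_plus_cross_closed_form(self):
        # plus sign of five s x s blocks: hull area 7 s^2, area 5 s^2
        s = 15
        cross = np.zeros((3 * s + 10, 3 * s + 10), bool)
        cross[5 + s:5 + 2 * s, 5:5 + 3 * s] = True
        cross[5:5 + 3 * s, 5 + s:5 + 2 * s] = True
        assert solidity(cross) == pytest.approx(5 / 7, abs=0.02)

    def test_protrusion_lowers_solidity(self, disk_mask):
        spiky = disk_mask.copy()
        spiky[50:53, 90:99] = True  # thin radial spike
        assert solidity(spiky) < solidity(disk_mask)


class TestAspectRatio:
    def test_disk_isotropic(self, disk_mask):
        assert aspect_ratio(disk_mask) == pytest.approx(1.0, abs=0.02)

    def test_rectangle_axis_ratio(self):
        rect = np.zeros((60, 30), bool)
        rect[10:50, 10:20] = True  # 40 x 10
        assert aspect_ratio(rect) == pytest.approx(4.0, rel=0.02)

    def test_rotation_invariant(self):
        rect = np.zeros((60, 60), bool)
        rect[10:50, 20:35] = True
        assert aspect_ratio(rect) == pytest.approx(
            aspect_ratio(np.rot90(rect)), abs=1e-6)


class TestCvHullRadii:
    def test_square_corners_equidistant(self, square_mask):
        assert cv_hull_radii(square_mask) == pytest.approx(0.0, abs=1e-9)

    def test_regular_hexagon_near_zero(self):
        angles = np.arange(6) * np.pi / 3
        rr, cc = draw_polygon(40 + 30 * np.sin(angles),
                              40 + 30 * np.cos(angles))
        hexagon = np.zeros((81, 81), bool)
        hexagon[rr, cc] = True
        assert cv_hull_radii(hexagon) < 0.05

    def test_l_shape_positive(self):
        ell = np.zeros((40, 40), bool)
        ell[5:35, 5:15] = True
        ell[25:35, 5:35] = True
        assert cv_hull_radii(ell) > 0.05

    def test_too_few_pixels_rejected(self):
        tiny = np.zeros((10, 10), bool)
        tiny[2, 2] = True
        tiny[3, 3] = True
        with pytest.raises(MechSpheroidError):
            cv_hull_radii(tiny)


class TestFeatureInvariances:
    FEATURES = [circularity, solidity, aspect_ratio, cv_hull_radii]

    @pytest.fixture
    def blob(self):
        mask = np.zeros((120, 120), bool)
        rr, cc = draw_disk((60, 60), 30)
        mask[rr, cc] = True
        rr, cc = draw_disk((60, 88), 8)
        mask[rr, cc] = True  # lobe: breaks symmetry
        return mask

    def test_translation_invariance(self, blob):
        shifted = np.roll(blob, (7, -9), axis=(0, 1))
        for feat in self.FEATURES:
            tol = 0.02 * abs(feat(blob)) + 1e-9 \
                if feat is circularity else 1e-6
            assert abs(feat(shifted) - feat(blob)) <= tol + 1e-6

    def test_rot90_invariance(self, blob):
        rotated = np.rot90(blob)
        for feat in self.FEATURES:
            rel = abs(feat(rotated) - feat(blob)) / abs(feat(blob))
            assert rel < (0.02 if feat is circularity else 1e-6)

    @pytest.mark.parametrize("s", [2, 3])
    def test_upsampling_scaling(self, blob, s):
        up = np.kron(blob, np.ones((s, s), dtype=bool))
        assert projection_area(up, 1.0) == pytest.approx(
            s ** 2 * projection_area(blob, 1.0))
        assert circularity(up) == pytest.approx(circularity(blob), rel=0.02)
        assert solidity(up) == pytest.approx(solidity(blob), rel=0.01)
        assert aspect_ratio(up) == pytest.approx(aspect_ratio(blob), rel=0.01)
        assert cv_hull_radii(up) == pytest.approx(cv_hull_radii(blob),
                                                  abs=0.005)

    def test_solidity_and_aspect_ratio_bounds(self, features40):
        assert (features40["solidity"] <= 1.01).all()
        assert (features40["aspect_ratio"] >= 1.0).all()

    def test_projection_area_grows_with_day(self, features40):
        for line in ("normal", "cancer"):
            means = (features40[features40["line"] == line]
                     .groupby("day")["area"].mean())
            assert means[2] < means[5] < means[8]


def test_morphological_features_bundle(disk_mask):
    feats = morphological_features(SpheroidMask(disk_mask, 1.0))
    assert feats.area == pytest.approx(np.pi * 40 ** 2, rel=0.02)
    assert feats.circularity == pytest.approx(1.0, abs=0.05)
    assert feats.solidity > 0.97
    assert feats.aspect_ratio == pytest.approx(1.0, abs=0.02)
    assert feats.cv_hull_radii < 0.02
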