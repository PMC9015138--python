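"""The 31-feature extractor: statistics, NGTDM, shape, location, normalization."""

import numpy as np
import pytest

from petlymph.crop import CropBoundaries
from petlymph.features import (FEATURE_NAMES, LOCATION_FEATURES, NGTDM_EPS,
                               SHAPE_FEATURES, SUV_FEATURES,
                               compute_feature_vector, location_features,
                               ngtdm_features, normalize_features,
                               outside_difference, shape_features,
                               suv_statistics)
from petlymph.segment import SegmentedRegion, TextureUndefinedError, quantize_suv

from conftest import make_volume

B = CropBoundaries(z_top=2, z_bottom=22, top_found=True, bottom_found=True)


def region_from_mask(mask, spacing=(4, 4, 4)):
    return SegmentedRegion(1, np.argwhere(mask), spacing)


# ---------------------------------------------------------------------------
# independent NGTDM oracle: literal per-voxel neighbour-average enumeration


def brute_force_ngtdm(vol, region, eps=NGTDM_EPS):
    coords = {tuple(c) for c in region.coords}
    q = {c: int(quantize_suv(np.array([vol.voxels[c]]))[0]) for c in coords}
    offsets = [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
               for dz in (-1, 0, 1) if (dx, dy, dz) != (0, 0, 0)]
    s, n = {}, {}
    n_valid = 0
    for c in coords:
        nb = [q[(c[0] + o[0], c[1] + o[1], c[2] + o[2])] for o in offsets
              if (c[0] + o[0], c[1] + o[1], c[2] + o[2]) in coords]
        if not nb:
            continue
        n_valid += 1
        i = q[c]
        s[i] = s.get(i, 0.0) + abs(i - sum(nb) / len(nb))
        n[i] = n.get(i, 0) + 1
    p = {i: n[i] / n_valid for i in n}
    present = sorted(p)
    ps = sum(p[i] * s[i] for i in present)
    coarseness = 1.0 / max(ps, eps)
    if len(present) > 1:
        ngp = len(present)
        contrast = (sum(p[i] * p[j] * (i - j) ** 2 for i in present for j in present)
                    / (ngp * (ngp - 1)) * sum(s.values()) / n_valid)
        den = sum(abs(i * p[i] - j * p[j]) for i in present for j in present)
        busyness = ps / den if den > 0 else 0.0
        complexity = sum(abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
                         for i in present for j in present) / n_valid
    else:
        contrast = busyness = complexity = 0.0
    return coarseness, contrast, busyness, complexity


class TestSuvStatistics:
    def test_hand_values(self):
        arr = np.zeros((3, 1, 1))
        arr[:, 0, 0] = [2.5, 3.5, 4.5]
        region = region_from_mask(np.ones((3, 1, 1), bool))
        s = suv_statistics(make_volume(arr), region)
        assert s["suv_max"] == 4.5
        assert s["suv_min"] == 2.5
        assert s["suv_mean"] == pytest.approx(3.5)
        assert s["suv_median"] == 3.5
        assert s["suv_range"] == pytest.approx(2.0)
        assert s["suv_energy"] == pytest.approx(2.5**2 + 3.5**2 + 4.5**2)

    def test_constant_region(self):
        region = region_from_mask(np.ones((2, 2, 2), bool))
        s = suv_statistics(make_volume(np.full((2, 2, 2), 3.0)), region)
        assert s["suv_variance"] == 0.0
        assert s["suv_std"] == 0.0
        assert s["suv_mad"] == 0.0
        assert s["suv_entropy"] == 0.0
        assert s["suv_uniformity"] == 1.0
        assert s["suv_rms"] == pytest.approx(3.0)
        assert s["suv_skewness"] == 0.0
        assert s["suv_kurtosis"] == 0.0

    def test_skewness_antisymmetry(self, rng):
        vals = rng.uniform(3, 8, size=20)
        mirrored = 2 * vals.mean() - vals
        arr1 = np.zeros((20, 1, 1)); arr1[:, 0, 0] = vals
        arr2 = np.zeros((20, 1, 1)); arr2[:, 0, 0] = mirrored
        region = region_from_mask(np.ones((20, 1, 1), bool))
        s1 = suv_statistics(make_volume(arr1), region)
        s2 = suv_statistics(make_volume(arr2), region)
        assert s1["suv_skewness"] == pytest.approx(-s2["suv_skewness"])

    def test_against_naive_reference(self, rng):
        # independent recomputation over the raw value list
        arr = rng.uniform(2.5, 9, size=(4, 4, 4))
        mask = rng.random((4, 4, 4)) > 0.4
        mask[0, 0, 0] = True
        region = region_from_mask(mask)
        v = arr[mask]
        s = suv_statistics(make_volume(arr), region)
        assert s["suv_mean"] == pytest.approx(sum(v) / len(v))
        assert s["suv_variance"] == pytest.approx(
            sum((x - v.mean()) ** 2 for x in v) / len(v))
        assert s["suv_rms"] == pytest.approx(np.sqrt(sum(x * x for x in v) / len(v)))
        assert s["suv_mad"] == pytest.approx(sum(abs(x - v.mean()) for x in v) / len(v))
        # Pearson kurtosis: normal scores 3, computed from central moments
        m2 = sum((x - v.mean()) ** 2 for x in v) / len(v)
        m4 = sum((x - v.mean()) ** 4 for x in v) / len(v)
        assert s["suv_kurtosis"] == pytest.approx(m4 / m2 ** 2)


class TestNgtdm:
    def test_constant_region_guards(self):
        region = region_from_mask(np.ones((3, 3, 3), bool))
        f = ngtdm_features(make_volume(np.full((3, 3, 3), 4.0)), region)
        assert f["ngtdm_coarseness"] == pytest.approx(1.0 / NGTDM_EPS)
        assert f["ngtdm_contrast"] == 0.0
        assert f["ngtdm_busyness"] == 0.0
        assert f["ngtdm_complexity"] == 0.0

    def test_two_tone_matches_brute_force(self, rng):
        arr = np.where(rng.random((3, 3, 3)) > 0.5, 3.0, 4.1)
        region = region_from_mask(np.ones((3, 3, 3), bool))
        vol = make_volume(arr)
        f = ngtdm_features(vol, region)
        co, cn, bu, cx = brute_force_ngtdm(vol, region)
        assert f["ngtdm_coarseness"] == pytest.approx(co)
        assert f["ngtdm_contrast"] == pytest.approx(cn)
        assert f["ngtdm_busyness"] == pytest.approx(bu)
        assert f["ngtdm_complexity"] == pytest.approx(cx)

    def test_oracle_equivalence_on_random_regions(self, rng):
        for _ in range(15):
            shape = tuple(rng.integers(2, 5, size=3))
            arr = rng.uniform(2.5, 7.5, size=shape)
            mask = rng.random(shape) > 0.3
            if mask.sum() < 2:
                continue
            region = region_from_mask(mask)
            vol = make_volume(arr)
            try:
                f = ngtdm_features(vol, region)
            except TextureUndefinedError:
                continue
            co, cn, bu, cx = brute_force_ngtdm(vol, region)
            assert f["ngtdm_coarseness"] == pytest.approx(co)
            assert f["ngtdm_contrast"] == pytest.approx(cn)
            assert f["ngtdm_busyness"] == pytest.approx(bu)
            assert f["ngtdm_complexity"] == pytest.approx(cx)

    def test_rotation_invariance(self, rng):
        arr = rng.uniform(2.5, 7.5, size=(4, 4, 4))
        region = region_from_mask(np.ones((4, 4, 4), bool))
        f1 = ngtdm_features(make_volume(arr), region)
        f2 = ngtdm_features(make_volume(np.rot90(arr, axes=(0, 1)).copy()), region)
        for k in f1:
            assert f1[k] == pytest.approx(f2[k])


class TestOutsideDifference:
    def test_two_level_phantom(self):
        arr = np.full((7, 7, 7), 2.0)
        arr[2:5, 2:5, 2:5] = 6.0
        region = region_from_mask(arr == 6.0)
        assert outside_difference(make_volume(arr), region) == pytest.approx(4.0)

    def test_identical_levels_give_zero(self):
        arr = np.full((6, 6, 6), 3.0)
        mask = np.zeros((6, 6, 6), bool)
        mask[2:4, 2:4, 2:4] = True
        assert outside_difference(make_volume(arr), region_from_mask(mask)) == 0.0

    def test_antisymmetry(self):
        arr = np.full((7, 7, 7), 2.0)
        arr[2:5, 2:5, 2:5] = 6.0
        inv = np.full((7, 7, 7), 6.0)
        inv[2:5, 2:5, 2:5] = 2.0
        region = region_from_mask(arr == 6.0)
        d1 = outside_difference(make_volume(arr), region)
        d2 = outside_difference(make_volume(inv), region)
        assert d1 == pytest.approx(-d2)

    def test_other_regions_excluded_from_shell(self):
        arr = np.full((8, 4, 4), 2.0)
        arr[2:4, 1:3, 1:3] = 6.0
        arr[4:6, 1:3, 1:3] = 100.0   # a second region right next door
        region = region_from_mask(arr == 6.0)
        other = arr == 100.0
        d = outside_difference(make_volume(arr), region, other_regions_mask=other)
        assert d == pytest.approx(4.0)


class TestShapeFeatures:
    def test_single_voxel(self):
        region = SegmentedRegion(1, np.array([[1, 1, 1]]), (4, 4, 4))
        f = shape_features(region)
        assert f["volume_ml"] == pytest.approx(0.064)
        assert f["surface_mm2"] == pytest.approx(96.0)   # 6 faces of 16 mm^2
        assert f["max_diameter_mm"] == 0.0
        assert f["surface_difference"] == 1.0

    def test_cube_surface_and_ratio(self):
        mask = np.ones((3, 3, 3), bool)
        f = shape_features(region_from_mask(mask))
        # 12 mm cube: S = 6 * 144, V = 1728
        assert f["surface_mm2"] == pytest.approx(6 * 144.0)
        assert f["area_surface_ratio"] == pytest.approx(1728.0 / 864.0)

    def test_ball_more_compact_than_rod(self):
        grids = np.ix_(*(np.arange(9) for _ in range(3)))
        ball = sum((g - 4.0) ** 2 for g in grids) <= 16.0
        n = int(ball.sum())
        rod = np.zeros((n, 1, 1), bool)
        rod[:, 0, 0] = True
        f_ball = shape_features(region_from_mask(ball))
        f_rod = shape_features(region_from_mask(rod))
        assert f_ball["volume_ml"] == f_rod["volume_ml"]
        assert f_ball["compactness"] > f_rod["compactness"]
        assert f_ball["compactness"] <= 1.5  # near the spherical bound

    def test_straight_rod_surface_difference_is_one(self):
        rod = np.zeros((10, 1, 1), bool)
        rod[:, 0, 0] = True
        f = shape_features(region_from_mask(rod))
        assert f["surface_difference"] == pytest.approx(1.0)

    def test_surface_difference_bounded(self, rng):
        mask = rng.random((6, 6, 6)) > 0.5
        mask[0, 0, 0] = True
        f = shape_features(region_from_mask(mask))
        assert 0.0 < f["surface_difference"] <= 1.0 + 1e-9

    def test_max_diameter_rod(self):
        rod = np.zeros((10, 1, 1), bool)
        rod[:, 0, 0] = True
        f = shape_features(region_from_mask(rod))
        assert f["max_diameter_mm"] == pytest.approx(9 * 4.0)


class TestLocationFeatures:
    def test_centred_region(self):
        mask = np.zeros((11, 11, 25), bool)
        mask[4:7, 4:7, 11:14] = True
        region = region_from_mask(mask)
        f = location_features(region, B, (11, 11, 25))
        assert f["centroid_x"] == pytest.approx(0.5, abs=0.01)
        assert f["centroid_y"] == pytest.approx(0.5, abs=0.01)
        assert f["centroid_z"] == pytest.approx(0.5, abs=0.01)

    def test_rod_along_x_axis(self):
        rod = np.zeros((12, 5, 5), bool)
        rod[1:11, 2, 2] = True
        f = location_features(region_from_mask(rod), B, (12, 5, 5))
        assert abs(f["axis_x"]) == pytest.approx(1.0, abs=1e-6)
        assert f["axis_x"] == pytest.approx(1.0)  # sign fixed positive
        assert f["axis_y"] == pytest.approx(0.0, abs=1e-6)
        assert f["axis_z"] == pytest.approx(0.0, abs=1e-6)

    def test_axis_is_unit_vector_and_z_nonnegative(self, rng):
        for _ in range(8):
            mask = rng.random((8, 8, 8)) > 0.6
            if mask.sum() < 3:
                continue
            f = location_features(region_from_mask(mask), B, (8, 8, 8))
            norm = f["axis_x"]**2 + f["axis_y"]**2 + f["axis_z"]**2
            assert norm == pytest.approx(1.0)
            assert f["axis_z"] >= -1e-9

    def test_isotropic_region_defaults_to_z(self):
        region = SegmentedRegion(1, np.array([[3, 3, 12]]), (4, 4, 4))
        f = location_features(region, B, (7, 7, 25))
        assert (f["axis_x"], f["axis_y"], f["axis_z"]) == (0.0, 0.0, 1.0)

    def test_interior_centroid_in_unit_box(self, rng):
        for _ in range(5):
            mask = np.zeros((9, 9, 25), bool)
            x, y, z = rng.integers(0, 9), rng.integers(0, 9), rng.integers(3, 22)
            mask[x, y, z] = True
            f = location_features(region_from_mask(mask), B, (9, 9, 25))
            assert 0.0 <= f["centroid_x"] <= 1.0
            assert 0.0 <= f["centroid_y"] <= 1.0
            assert 0.0 <= f["centroid_z"] <= 1.0


class TestNormalization:
    def _sphere_region(self, radius_mm, spacing):
        half = int(np.ceil(radius_mm / min(spacing))) + 2
        n = 2 * half + 1
        grids = np.ix_(*(np.arange(n) for _ in range(3)))
        r2 = sum(((g - half) * s) ** 2 for g, s in zip(grids, spacing))
        return region_from_mask(r2 <= radius_mm ** 2, spacing)

    def test_scaled_volume_resolution_invariant(self):
        # one 20 mm sphere, discretized at 2 mm and at 4 mm
        fine = self._sphere_region(20.0, (2, 2, 2))
        coarse = self._sphere_region(20.0, (4, 4, 4))
        b = CropBoundaries(0, 150, True, True)
        f_fine = normalize_features(shape_features(fine), (2, 2, 2),
                                    CropBoundaries(0, 300, True, True))
        f_coarse = normalize_features(shape_features(coarse), (4, 4, 4), b)
        # both crops span 600 mm of body
        assert f_fine["scaled_volume"] == pytest.approx(
            f_coarse["scaled_volume"], rel=0.10)

    def test_doubling_body_length_halves_max_diameter(self):
        region = self._sphere_region(16.0, (4, 4, 4))
        raw = shape_features(region)
        short = normalize_features(raw, (4, 4, 4), CropBoundaries(0, 100, True, True))
        long = normalize_features(raw, (4, 4, 4), CropBoundaries(0, 200, True, True))
        assert long["max_diameter"] == pytest.approx(short["max_diameter"] / 2)

    def test_deterministic_and_idempotent_inputs(self):
        region = self._sphere_region(12.0, (4, 4, 4))
        b = CropBoundaries(0, 120, True, True)
        f1 = normalize_features(shape_features(region), (4, 4, 4), b)
        f2 = normalize_features(shape_features(region), (4, 4, 4), b)
        assert f1 == f2


class TestFeatureVector:
    def _toy_volume(self):
        arr = np.full((12, 12, 26), 1.0)
        arr[4:8, 4:8, 10:14] = 6.0
        arr[5, 5, 11] = 7.0
        return make_volume(arr), region_from_mask(arr >= 6.0)

    def test_exactly_31_features_with_family_split(self):
        assert len(FEATURE_NAMES) == 31
        assert len(SUV_FEATURES) == 19
        assert len(SHAPE_FEATURES) == 6
        assert len(LOCATION_FEATURES) == 6
        vol, region = self._toy_volume()
        fv = compute_feature_vector(vol, region, CropBoundaries(2, 24, True, True))
        assert list(fv) == FEATURE_NAMES
        assert all(np.isfinite(v) for v in fv.values())

    def test_translation_invariance_of_non_location_features(self):
        arr = np.full((14, 14, 26), 1.0)
        arr[2:6, 2:6, 6:10] = 6.0
        arr[3, 3, 7] = 7.5
        shifted = np.full((14, 14, 26), 1.0)
        shifted[6:10, 7:11, 14:18] = 6.0
        shifted[7, 8, 15] = 7.5
        b = CropBoundaries(1, 25, True, True)
        fv1 = compute_feature_vector(make_volume(arr), region_from_mask(arr >= 6),
                                     b)
        fv2 = compute_feature_vector(make_volume(shifted),
                                     region_from_mask(shifted >= 6), b)
        for name in SUV_FEATURES + SHAPE_FEATURES:
            assert fv1[name] == pytest.approx(fv2[name]), name
        assert fv1["centroid_z"] != pytest.approx(fv2["centroid_z"])
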