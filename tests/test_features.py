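"""Radiomic feature extraction: catalog closure, hand values, oracles."""

import numpy as np
import pytest

from radpet.errors import DegenerateRegionError
from radpet.features import (DIRECTIONS_3D, FIRST_ORDER_NAMES, GLCM_STAT_NAMES,
                             SHAPE_NAMES, discretize, extract_features,
                             extract_patient, first_order_features,
                             glcm_features, glcm_matrix, shape_features)
from radpet.grids import RoiMask, VoxelGrid

from conftest import full_mask, grid_from
from oracles import bf_glcm, bf_glcm_stats, bf_moment_skewness


class TestDiscretize:
    def test_equal_width_halves(self):
        assert list(discretize(np.array([0, 1, 2, 3]), 2)) == [1, 1, 2, 2]

    def test_constant_input_maps_to_one(self):
        assert set(discretize(np.full(5, 3.3), 8)) == {1}

    def test_full_range_used(self, rng):
        levels = discretize(rng.uniform(2, 9, 500), 16)
        assert levels.min() == 1 and levels.max() == 16


class TestFirstOrder:
    def test_hand_computed_skewness(self):
        g = grid_from([1, 1, 1, 5])
        feats = first_order_features(g, full_mask(g))
        assert feats["Skewness"] == pytest.approx(2 / np.sqrt(3), abs=1e-12)
        assert feats["Mean"] == 2.0
        assert feats["Variance"] == pytest.approx(3.0)

    def test_symmetric_values_have_zero_skewness(self):
        g = grid_from([1, 2, 3])
        assert abs(first_order_features(g, full_mask(g))["Skewness"]) < 1e-12

    def test_percentile_conventions(self):
        g = grid_from([1, 2, 3, 4])
        feats = first_order_features(g, full_mask(g))
        assert feats["Median"] == 2.5
        assert feats["P25"] == 1.75 and feats["P75"] == 3.25
        assert feats["InterquartileRange"] == pytest.approx(1.5)

    def test_single_voxel_is_degenerate(self):
        g = grid_from([5.0])
        with pytest.raises(DegenerateRegionError):
            first_order_features(g, full_mask(g))

    def test_matches_direct_recomputation_on_random_regions(self, rng):
        for _ in range(20):
            data = rng.uniform(1, 10, size=(7, 6, 5))
            mask = rng.random((7, 6, 5)) > 0.4
            if mask.sum() < 3:
                continue
            g = VoxelGrid(data, (4, 4, 4))
            feats = first_order_features(g, RoiMask(mask, g.spacing))
            x = data[mask]
            assert feats["Mean"] == pytest.approx(x.mean(), abs=1e-9)
            assert feats["Median"] == pytest.approx(np.median(x), abs=1e-9)
            assert feats["Skewness"] == pytest.approx(bf_moment_skewness(x),
                                                      abs=1e-9)


class TestShape:
    def test_single_voxel_volume_and_mesh_area(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        feats = shape_features(RoiMask(mask, (4.0, 4.0, 4.0)))
        assert feats["VolumeMl"] == pytest.approx(0.064)
        # marching-cubes isosurface of one voxel is the octahedron through
        # its face centers: area sqrt(3) * spacing^2
        assert feats["SurfaceArea"] == pytest.approx(16 * np.sqrt(3), rel=1e-6)

    def test_digital_ball_approaches_unit_sphericity(self):
        r = 15
        n = 2 * r + 3
        zz, yy, xx = np.indices((n, n, n))
        c = n // 2
        ball = ((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2) <= r ** 2
        feats = shape_features(RoiMask(ball, (1.0, 1.0, 1.0)))
        assert feats["Sphericity"] >= 0.9
        assert feats["Maximum3DDiameter"] == pytest.approx(2 * r, rel=0.1)

    def test_translation_invariance(self, rng):
        base = rng.random((6, 6, 6)) > 0.5
        mask = np.zeros((14, 14, 14), bool)
        mask[1:7, 1:7, 1:7] = base
        shifted = np.zeros_like(mask)
        shifted[5:11, 6:12, 7:13] = base
        f1 = shape_features(RoiMask(mask, (4, 4, 4)))
        f2 = shape_features(RoiMask(shifted, (4, 4, 4)))
        for name in SHAPE_NAMES:
            assert f1[name] == pytest.approx(f2[name], abs=1e-9)


class TestGlcm:
    def test_hand_counted_line_matrix(self):
        levels = np.array([1, 1, 2, 2]).reshape(1, 4, 1)
        mask = np.ones((1, 4, 1), bool)
        m = glcm_matrix(levels, mask, (0, 1, 0))
        assert m.matrix == pytest.approx(np.array([[2, 1], [1, 2]]) / 6)

    def test_constant_region_single_entry(self):
        levels = np.ones((2, 2, 2), int)
        m = glcm_matrix(levels, np.ones((2, 2, 2), bool), (0, 0, 1))
        assert m.matrix == pytest.approx(np.array([[1.0]]))

    def test_symmetry_on_random_input(self, rng):
        levels = rng.integers(1, 6, size=(5, 5, 5))
        mask = rng.random((5, 5, 5)) > 0.3
        m = glcm_matrix(levels, mask, (1, 0, -1), n_levels=5)
        assert np.allclose(m.matrix, m.matrix.T)

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(6):
            levels = rng.integers(1, 5, size=(6, 6, 6))
            mask = rng.random((6, 6, 6)) > 0.35
            for offset in [(0, 0, 1), (1, 0, 0), (1, 1, 0), (2, 0, 0), (1, -1, 1)]:
                expected = bf_glcm(levels, mask, offset, 4)
                if expected.sum() == 0:
                    continue
                got = glcm_matrix(levels, mask, offset, n_levels=4)
                assert got.matrix == pytest.approx(expected, abs=1e-9)


class TestGlcmFeatures:
    def test_hand_evaluated_statistics(self):
        # 1x4x1 line [1,1,2,2]: only the (0,1,0) direction has pairs, so the
        # direction-averaged matrix at distance 1 is [[2,1],[1,2]]/6.
        g = grid_from([0.0, 1.0, 2.0, 3.0], spacing=(1, 1, 1))
        feats = glcm_features(g, full_mask(g), bin_count=2, distances=(1,))
        assert feats["GLCM-JointEnergy-d1"] == pytest.approx(10 / 36)
        assert feats["GLCM-Contrast-d1"] == pytest.approx(1 / 3)
        assert feats["GLCM-MaximumProbability-d1"] == pytest.approx(1 / 3)
        assert feats["GLCM-Correlation-d1"] == pytest.approx(1 / 3)

    def test_constant_region_conventions(self):
        g = VoxelGrid(np.full((3, 3, 3), 4.0), (1, 1, 1))
        feats = glcm_features(g, RoiMask(np.ones((3, 3, 3), bool), g.spacing),
                              bin_count=8)
        assert feats["GLCM-Contrast-d1"] == 0.0
        assert feats["GLCM-JointEnergy-d1"] == pytest.approx(1.0)
        assert feats["GLCM-Correlation-d1"] == 0.0  # undefined -> 0

    def test_checkerboard_axis_contrast(self):
        zz, yy, xx = np.indices((4, 4, 4))
        board = (zz + yy + xx) % 2  # alternating levels {1,2} after +1
        levels = board + 1
        mask = np.ones((4, 4, 4), bool)
        for offset in [(1, 0, 0), (0, 1, 0), (0, 0, 1)]:
            m = glcm_matrix(levels, mask, offset, n_levels=2)
            assert m.matrix == pytest.approx(np.array([[0, 0.5], [0.5, 0]]))
            assert bf_glcm_stats(m.matrix)["Contrast"] == pytest.approx(1.0)

    def test_statistics_match_brute_force_on_random_volumes(self, rng):
        from radpet.features import _glcm_statistics
        for _ in range(8):
            ng = int(rng.integers(2, 7))
            raw = rng.random((ng, ng))
            P = raw + raw.T
            P /= P.sum()
            mine = _glcm_statistics(P)
            ref = bf_glcm_stats(P)
            for name, val in ref.items():
                assert mine[name] == pytest.approx(val, abs=1e-9), name

    def test_rotation_invariance_of_direction_average(self, rng):
        data = rng.uniform(0, 10, size=(6, 6, 6))
        mask = rng.random((6, 6, 6)) > 0.3
        g = VoxelGrid(data, (1, 1, 1))
        feats = glcm_features(g, RoiMask(mask, g.spacing), bin_count=8)
        for axes in [(0, 1), (0, 2), (1, 2)]:
            gr = VoxelGrid(np.rot90(data, axes=axes).copy(), (1, 1, 1))
            mr = RoiMask(np.rot90(mask, axes=axes).copy(), (1, 1, 1))
            rot = glcm_features(gr, mr, bin_count=8)
            for name, val in feats.items():
                assert rot[name] == pytest.approx(val, abs=1e-9), name


class TestExtraction:
    def test_catalog_closure_84_features(self, phantom):
        pet_f, ct_f = extract_patient(phantom.pet, phantom.ct,
                                      phantom.tumor_mask_reader1)
        assert len(pet_f) == len(ct_f) == 84
        assert len(SHAPE_NAMES) == 12
        assert len(FIRST_ORDER_NAMES) == 24
        assert len(GLCM_STAT_NAMES) * 2 == 48
        assert "PET-Skewness" in pet_f and "PET-Median" in pet_f

    def test_shared_mask_gives_identical_shape_blocks(self, phantom):
        pet_f, ct_f = extract_patient(phantom.pet, phantom.ct,
                                      phantom.tumor_mask_reader1)
        for name in SHAPE_NAMES:
            assert pet_f[f"PET-{name}"] == ct_f[f"CT-{name}"]

    def test_skewness_scale_invariance(self, phantom):
        scaled = VoxelGrid(phantom.pet.data * 3.7, phantom.pet.spacing)
        f1 = extract_features(phantom.pet, phantom.tumor_mask_reader1)
        f2 = extract_features(scaled, phantom.tumor_mask_reader1)
        assert f2["Skewness"] == pytest.approx(f1["Skewness"], abs=1e-9)

    def test_deterministic_for_fixed_inputs(self, phantom):
        a = extract_patient(phantom.pet, phantom.ct, phantom.tumor_mask_reader2)
        b = extract_patient(phantom.pet, phantom.ct, phantom.tumor_mask_reader2)
        assert a == b

    def test_thirteen_unique_directions(self):
        assert len(DIRECTIONS_3D) == 13
        seen = {tuple(d) for d in DIRECTIONS_3D}
        assert all(tuple(-d) not in seen for d in DIRECTIONS_3D)
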