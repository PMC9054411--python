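import numpy as np
import pytest

from tacerad import radiomics as rad
from tacerad.imaging_io import EmptyMaskError, PhaseVolume, VOIMask, quantize

import oracles
from conftest import make_quantized, make_stack, random_voi


# ---------------------------------------------------------------------------
# First-order
# ---------------------------------------------------------------------------

class TestFirstOrder:
    def _fo(self, values, G=4):
        vals = np.asarray(values, dtype=float).reshape(-1, 1, 1)
        vol = PhaseVolume(vals, (1, 1, 1), "arterial_early")
        mask = VOIMask(np.ones(vals.shape))
        q = quantize(vol, mask, G=G)
        return rad.first_order_features(q, vals.ravel())

    def test_constant_voi_degenerate_conventions(self):
        f = self._fo([5.0] * 8)
        assert f["variance"] == 0 and f["skewness"] == 0 and f["kurtosis"] == 0
        assert f["entropy"] == 0 and f["energy"] == 1 and f["uniformity"] == 1

    def test_simple_arithmetic(self):
        f = self._fo([1, 2, 3, 4])
        assert f["mean"] == 2.5 and f["range"] == 3 and f["median"] == 2.5

    def test_moments_against_direct_computation(self):
        f = self._fo([1, 1, 3, 3])
        assert f["variance"] == pytest.approx(1.0)
        assert f["skewness"] == pytest.approx(0.0)
        # population excess kurtosis of a symmetric two-point distribution
        assert f["kurtosis"] == pytest.approx(-2.0)

    def test_registry_complete_and_ordered(self):
        f = self._fo([1, 2, 3])
        assert tuple(f) == rad.FIRST_ORDER_NAMES
        assert len(f) == 12


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

class TestGLCM:
    def test_constant_voi_single_cell(self):
        q = make_quantized(np.ones((4, 4, 1)), G=64)
        M = rad.glcm(q, 0)
        f = rad.glcm_features(M)
        assert M.P[0, 0] == 1.0
        assert f["glcm_energy"] == 1 and f["glcm_entropy"] == 0 and f["glcm_contrast"] == 0

    def test_vertical_pairs_hand_enumeration(self):
        # [[1,2],[1,2]] with vertical offset: pairs (1,1) and (2,2) once each
        q = make_quantized(np.array([[1, 2], [1, 2]]), G=2)
        M = rad.glcm(q, 90)
        np.testing.assert_allclose(M.P, np.diag([0.5, 0.5]))
        f = rad.glcm_features(M)
        assert f["glcm_contrast"] == 0 and f["glcm_energy"] == 0.5

    def test_sum_entropy_of_diagonal_pairs_is_one_bit(self):
        q = make_quantized(np.array([[1, 2], [1, 2]]), G=2)
        f = rad.glcm_features(rad.glcm(q, 90))
        assert f["glcm_sum_entropy"] == pytest.approx(1.0)

    def test_no_valid_pair_gives_degenerate_limits(self):
        q = make_quantized(np.ones((1, 1, 1)), G=4)
        f = rad.glcm_features(rad.glcm(q, 0))
        assert f["glcm_energy"] == 0 and f["glcm_correlation"] == 1

    def test_matches_oracle_on_random_vois(self, rng):
        for _ in range(8):
            q = random_voi(rng)
            for d in rad.DIRECTION_ORDER:
                P = rad.glcm(q, d).P
                P_o = oracles.naive_glcm(q.levels, q.mask, rad.DIRECTIONS[d], q.G)
                np.testing.assert_allclose(P, P_o, atol=1e-12)
                f, fo = rad.glcm_features(rad.glcm(q, d)), oracles.naive_glcm_features(P_o)
                for k in rad.GLCM_NAMES:
                    assert f[k] == pytest.approx(fo[k], rel=1e-9, abs=1e-12)

    def test_shift_invariance_of_quantized_texture(self, rng):
        vals = rng.normal(size=(6, 6, 3)) * 40
        mask = np.ones(vals.shape, dtype=bool)
        f = {}
        for shift in (0.0, 500.0):
            vol = PhaseVolume(vals + shift, (1, 1, 1), "arterial_early")
            q = quantize(vol, VOIMask(mask), G=8)
            f[shift] = rad.glcm_features(rad.glcm(q, 45))
        assert f[0.0] == f[500.0]

    def test_in_plane_rotation_permutes_directions(self, rng):
        lev = rng.integers(1, 5, size=(5, 7, 2)).astype(np.int32)
        q = make_quantized(lev, G=4)
        q_rot = make_quantized(np.rot90(lev, axes=(0, 1)).copy(), G=4)
        feats = {d: rad.glcm_features(rad.glcm(q, d)) for d in rad.DIRECTION_ORDER}
        feats_rot = {d: rad.glcm_features(rad.glcm(q_rot, d)) for d in rad.DIRECTION_ORDER}
        for a, b in ((0, 90), (90, 0), (45, 135), (135, 45)):
            for k in rad.GLCM_NAMES:
                assert feats[a][k] == pytest.approx(feats_rot[b][k], rel=1e-12)


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

class TestGLRLM:
    def test_single_maximal_run(self):
        q = make_quantized(np.ones((1, 4, 1)), G=4)
        f = rad.glrlm_features(rad.glrlm(q, 0))
        assert f["glrlm_run_percentage"] == pytest.approx(0.25)

    def test_alternating_line_all_unit_runs(self):
        q = make_quantized(np.array([[1, 2, 1, 2]]), G=2)
        f = rad.glrlm_features(rad.glrlm(q, 0))
        assert f["glrlm_short_run_emphasis"] == 1 and f["glrlm_long_run_emphasis"] == 1

    def test_run_length_nonuniformity_two_equal_runs(self):
        q = make_quantized(np.array([[1, 1, 2, 2]]), G=2)
        f = rad.glrlm_features(rad.glrlm(q, 0))
        assert f["glrlm_run_length_nonuniformity"] == pytest.approx(2.0)

    def test_voxel_accounting_invariant(self, rng):
        # every in-mask voxel belongs to exactly one maximal run per direction
        for _ in range(5):
            q = random_voi(rng)
            for d in rad.DIRECTION_ORDER:
                R = rad.glrlm(q, d).R
                assert (R * np.arange(R.shape[1])).sum() == q.mask.sum()

    def test_matches_oracle_on_random_vois(self, rng):
        for _ in range(8):
            q = random_voi(rng)
            n_vox = int(q.mask.sum())
            for d in rad.DIRECTION_ORDER:
                f = rad.glrlm_features(rad.glrlm(q, d))
                runs = oracles.naive_runs(q.levels, q.mask, d)
                fo = oracles.naive_glrlm_features(runs, n_vox)
                for k in rad.GLRLM_NAMES:
                    assert f[k] == pytest.approx(fo[k], rel=1e-9, abs=1e-12)


# ---------------------------------------------------------------------------
# GLZSM
# ---------------------------------------------------------------------------

class TestGLZSM:
    def test_constant_voi_single_zone(self):
        q = make_quantized(np.ones((3, 3, 3)), G=4)
        M = rad.glzsm(q)
        f = rad.glzsm_features(M)
        assert M.Z.sum() == 1 and M.Z[0, 27] == 1
        assert f["glzsm_low_intensity_emphasis"] == pytest.approx(1.0)

    def test_two_disjoint_blobs_hand_matrix(self):
        lev = np.zeros((7, 3, 3), dtype=np.int32)
        lev[:3] = 1
        lev[4:] = 8
        mask = lev > 0
        q = make_quantized(lev, mask, G=8)
        f = rad.glzsm_features(rad.glzsm(q))
        # zones: (level 1, 27 voxels), (level 8, 27 voxels)
        fo = oracles.naive_glzsm_features([(1, 27), (8, 27)])
        assert f == pytest.approx(fo)
        assert f["glzsm_high_intensity_emphasis"] == pytest.approx((1 + 64) / 2)

    def test_isolated_voxels_give_unit_zones(self, rng):
        # stride-2 mask: no two in-mask voxels are 26-adjacent
        lev = rng.integers(1, 3, size=(5, 5, 5)).astype(np.int32)
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[::2, ::2, ::2] = True
        q = make_quantized(lev, mask, G=2)
        assert all(s == 1 for _, s in oracles.naive_zones(q.levels, q.mask))
        f = rad.glzsm_features(rad.glzsm(q))
        # all zones have size 1, so large-area emphases equal their plain versions
        assert f["glzsm_high_intensity_large_area_emphasis"] == pytest.approx(
            f["glzsm_high_intensity_emphasis"])
        assert f["glzsm_low_intensity_large_area_emphasis"] == pytest.approx(
            f["glzsm_low_intensity_emphasis"])

    def test_matches_flood_fill_oracle_on_random_vois(self, rng):
        for _ in range(6):
            q = random_voi(rng)
            f = rad.glzsm_features(rad.glzsm(q))
            fo = oracles.naive_glzsm_features(oracles.naive_zones(q.levels, q.mask))
            for k in rad.GLZSM_NAMES:
                assert f[k] == pytest.approx(fo[k], rel=1e-9)

    def test_zone_voxel_accounting(self, rng):
        q = random_voi(rng)
        Z = rad.glzsm(q).Z
        assert (Z * np.arange(Z.shape[1])).sum() == q.mask.sum()


# ---------------------------------------------------------------------------
# Morphology
# ---------------------------------------------------------------------------

class TestMorphology:
    def test_single_voxel_unit_cube(self):
        mask = np.zeros((3, 3, 3))
        mask[1, 1, 1] = 1
        f = rad.morphology_features(VOIMask(mask), (1, 1, 1), np.array([50.0]))
        assert f["volume"] == 1 and f["surface_area"] == 6
        assert f["density"] == 50

    def test_cube_sphericity_closed_form(self):
        mask = np.zeros((12, 12, 12))
        mask[1:11, 1:11, 1:11] = 1
        f = rad.morphology_features(VOIMask(mask), (1, 1, 1), np.ones(1000))
        assert f["volume"] == 1000 and f["surface_area"] == 600
        expected = np.pi ** (1 / 3) * (6 * 1000) ** (2 / 3) / 600
        assert f["sphericity"] == pytest.approx(expected)
        assert f["sphericity"] == pytest.approx(0.806, abs=5e-4)
        # corner-to-corner diagonal of the 10-cube of voxel centers
        assert f["maximum_diameter"] == pytest.approx(9 * np.sqrt(3))

    def test_scaling_laws(self):
        mask = np.zeros((10, 10, 10))
        mask[2:8, 2:8, 2:8] = 1
        f1 = rad.morphology_features(VOIMask(mask), (1, 1, 1), np.ones(216))
        f2 = rad.morphology_features(VOIMask(mask), (2, 2, 2), np.ones(216))
        assert f2["volume"] == pytest.approx(8 * f1["volume"])
        assert f2["surface_area"] == pytest.approx(4 * f1["surface_area"])
        assert f2["sphericity"] == pytest.approx(f1["sphericity"])

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptyMaskError):
            rad.morphology_features(VOIMask(np.zeros((2, 2, 2))), (1, 1, 1), np.array([]))


# ---------------------------------------------------------------------------
# Phase block
# ---------------------------------------------------------------------------

class TestPhaseBlock:
    def test_block_has_exactly_43_features(self, small_phantom_case):
        b = rad.phase_block(small_phantom_case, "arterial_early", G=16)
        assert len(b.as_dict()) == 43
        assert len(b.first_order) == 12 and len(b.texture) == 24 and len(b.morphology) == 7

    def test_96_directional_evaluations_before_averaging(self, small_phantom_case):
        b = rad.phase_block(small_phantom_case, "arterial_mid", G=16)
        assert b.n_directional_evaluations == 96

    def test_directional_average_matches_explicit_mean(self, small_phantom_case):
        from tacerad.imaging_io import quantize as q_

        stack = small_phantom_case
        q = q_(stack.phases["arterial_late"], stack.mask, G=16)
        per_dir = rad.texture_features_by_direction(q)
        b = rad.phase_block(stack, "arterial_late", G=16)
        for name in rad.TEXTURE_NAMES:
            expected = np.mean([per_dir[d][name] for d in rad.DIRECTION_ORDER])
            assert b.texture[name] == pytest.approx(expected)

    def test_constant_voi_direction_symmetries(self):
        # GLCM and GLZSM features are direction-identical on a constant VOI;
        # run features agree between the axis pair (0, 90) and the diagonal
        # pair (45, 135), whose scan-line geometries match on a square slice.
        vols = [np.full((6, 6, 6), 10.0 * (i + 1)) for i in range(4)]
        mask = np.zeros((6, 6, 6))
        mask[1:5, 1:5, 1:5] = 1
        stack = make_stack(vols, mask)
        q = quantize(stack.phases["arterial_early"], stack.mask, G=8)
        per_dir = rad.texture_features_by_direction(q)
        for name in rad.GLCM_NAMES + rad.GLZSM_NAMES:
            vals = [per_dir[d][name] for d in rad.DIRECTION_ORDER]
            assert max(vals) - min(vals) == 0
        for name in rad.GLRLM_NAMES:
            assert per_dir[0][name] == per_dir[90][name]
            assert per_dir[45][name] == per_dir[135][name]
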