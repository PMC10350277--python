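"""Feature extractor: discretization, first-order, texture, shape, wavelet."""

import numpy as np
import pytest

from _oracles import (brute_glcm_matrix, brute_glrlm_matrix,
                      naive_glcm_subset, naive_glrlm_subset)
from conftest import random_discretized_roi
from radpipe import ImageVolume, RoiMask
from radpipe.radiomics import (ALL_DIRECTIONS_3D, ExtractionConfig,
                               discretize_fixed_bin_count, extract_all,
                               feature_name_inventory, first_order_features,
                               glcm_features, glcm_matrix, glrlm_features,
                               glrlm_matrix, shape_features, wavelet_subbands)


def _cube(data, spacing=(1, 1, 1), modality="T2w"):
    return ImageVolume(np.asarray(data, dtype=float), spacing, modality)


class TestDiscretize:
    def test_extremes_map_to_first_and_last_bin(self):
        data = np.array([[[0.0, 1.0]]])
        d = discretize_fixed_bin_count(data, np.ones_like(data, bool), 32)
        assert sorted(d.roi_bins()) == [1, 32]

    def test_constant_roi_goes_to_bin_one(self):
        data = np.full((2, 2, 2), 9.0)
        d = discretize_fixed_bin_count(data, np.ones_like(data, bool), 32)
        assert set(d.roi_bins()) == {1}

    def test_half_open_bin_convention(self):
        data = np.array([[[0.0, 0.5, 1.0]]])
        d = discretize_fixed_bin_count(data, np.ones_like(data, bool), 2)
        assert list(d.roi_bins()) == [1, 2, 2]

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            discretize_fixed_bin_count(np.zeros((2, 2, 2)),
                                       np.zeros((2, 2, 2), bool))


class TestFirstOrder:
    def test_constant_roi(self):
        data = np.full((3, 3, 3), 4.2)
        f = first_order_features(data, np.ones_like(data, bool))
        assert f["Range"] == 0 and f["Variance"] == 0
        assert f["Mean"] == pytest.approx(4.2)
        assert f["Uniformity"] == 1.0

    def test_hand_arithmetic_1234(self):
        data = np.array([[[1.0, 2.0, 3.0, 4.0]]])
        f = first_order_features(data, np.ones_like(data, bool),
                                 voxel_volume=2.0)
        assert f["Mean"] == pytest.approx(2.5)
        assert f["Range"] == pytest.approx(3.0)
        assert f["Variance"] == pytest.approx(1.25)  # population variance
        assert f["Energy"] == pytest.approx(30.0)
        assert f["TotalEnergy"] == pytest.approx(60.0)
        assert f["RootMeanSquared"] == pytest.approx(np.sqrt(7.5))

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            first_order_features(np.zeros((2, 2, 2)), np.zeros((2, 2, 2), bool))


class TestGlcm:
    def test_constant_roi_entropy_zero(self):
        data = np.full((3, 3, 3), 2.0)
        d = discretize_fixed_bin_count(data, np.ones_like(data, bool), 32)
        f = glcm_features(d)
        assert f["JointEntropy"] == pytest.approx(0.0, abs=1e-12)
        assert f["MaximumProbability"] == pytest.approx(1.0)

    def test_hand_enumerated_2x2(self):
        """[[1,2],[1,2]] along the horizontal direction: P(1,2)=P(2,1)=0.5,
        Contrast = 1."""
        data = np.array([[1.0, 2.0], [1.0, 2.0]])[:, :, None]
        d = discretize_fixed_bin_count(data, np.ones_like(data, bool), 2)
        p = glcm_matrix(d, (0, 1, 0))
        np.testing.assert_allclose(p, [[0, 0.5], [0.5, 0]])
        f = glcm_features(d, directions=((0, 1, 0),))
        assert f["Contrast"] == pytest.approx(1.0)

    def test_checkerboard_perfect_anticorrelation(self):
        data = (np.indices((6, 6, 6)).sum(axis=0) % 2).astype(float)
        d = discretize_fixed_bin_count(data, np.ones_like(data, bool), 2)
        f = glcm_features(d, directions=((1, 0, 0),))
        assert f["Correlation"] == pytest.approx(-1.0, abs=1e-10)

    def test_too_small_roi_rejected(self):
        data = np.ones((1, 1, 1))
        d = discretize_fixed_bin_count(data, np.ones_like(data, bool), 2)
        with pytest.raises(ValueError):
            glcm_features(d)


class TestGlrlm:
    def test_hand_enumerated_two_runs(self):
        """[[1,1],[2,2]] horizontally: two runs of length 2."""
        data = np.array([[1.0, 1.0], [2.0, 2.0]])[:, :, None]
        d = discretize_fixed_bin_count(data, np.ones_like(data, bool), 2)
        f = glrlm_features(d, directions=((0, 1, 0),))
        assert f["ShortRunEmphasis"] == pytest.approx(0.25)
        assert f["LongRunEmphasis"] == pytest.approx(4.0)
        assert f["RunPercentage"] == pytest.approx(0.5)
        assert f["RunVariance"] == pytest.approx(0.0)

    def test_all_distinct_bins_all_unit_runs(self, rng):
        data = np.arange(27, dtype=float).reshape(3, 3, 3)
        d = discretize_fixed_bin_count(data, np.ones_like(data, bool), 27)
        f = glrlm_features(d)
        assert f["RunPercentage"] == pytest.approx(1.0)
        assert f["LongRunEmphasis"] == pytest.approx(1.0)
        assert f["ShortRunEmphasis"] == pytest.approx(1.0)

    def test_constant_line_single_run(self):
        data = np.ones((4, 1, 1))
        d = discretize_fixed_bin_count(data, np.ones_like(data, bool), 32)
        f = glrlm_features(d, directions=((1, 0, 0),))
        assert f["LongRunEmphasis"] == pytest.approx(16.0)

    def test_run_conservation_on_random_masks(self, rng):
        """sum_g sum_r r R(g,r) = ROI voxel count, every direction,
        against the brute-force run enumerator."""
        for _ in range(20):
            d = random_discretized_roi(rng)
            for direction in ALL_DIRECTIONS_3D:
                mat = glrlm_matrix(d, direction)
                r = np.arange(1, mat.shape[1] + 1)
                assert (mat * r).sum() == d.n_voxels
                brute = brute_glrlm_matrix(d.bins, direction, d.n_bins)
                assert mat.shape == brute.shape
                np.testing.assert_array_equal(mat, brute)


class TestTextureOracles:
    def test_matrices_and_features_match_bruteforce(self, rng):
        """GLCM and GLRLM agree with the naive enumerators on small
        random ROIs, matrices exactly and features to 1e-10."""
        for _ in range(40):
            d = random_discretized_roi(rng)
            glcm_ok = False
            for direction in ALL_DIRECTIONS_3D[::4]:
                mine = glcm_matrix(d, direction)
                brute = brute_glcm_matrix(d.bins, direction, d.n_bins)
                np.testing.assert_allclose(mine, brute, atol=1e-12)
                if brute.sum() > 0:
                    glcm_ok = True
            if d.n_voxels >= 2 and glcm_ok:
                mine_f = glcm_features(d)
                per_dir = [naive_glcm_subset(
                    brute_glcm_matrix(d.bins, dd, d.n_bins))
                    for dd in ALL_DIRECTIONS_3D
                    if brute_glcm_matrix(d.bins, dd, d.n_bins).sum() > 0]
                for key in ("Contrast", "JointEntropy", "Correlation",
                            "SumSquares", "MaximumProbability"):
                    ref = np.mean([f[key] for f in per_dir])
                    assert mine_f[key] == pytest.approx(ref, abs=1e-10)
            mine_g = glrlm_features(d)
            per_dir = [naive_glrlm_subset(
                brute_glrlm_matrix(d.bins, dd, d.n_bins), d.n_voxels)
                for dd in ALL_DIRECTIONS_3D]
            for key in ("ShortRunEmphasis", "LongRunEmphasis",
                        "RunPercentage", "RunVariance"):
                ref = np.mean([f[key] for f in per_dir])
                assert mine_g[key] == pytest.approx(ref, abs=1e-10)


class TestShape:
    def test_digital_sphere_volume_and_sphericity(self):
        r, n = 10, 25
        g = np.indices((n, n, n)) - (n - 1) / 2
        mask = RoiMask((g ** 2).sum(axis=0) <= r * r, (1, 1, 1))
        f = shape_features(mask)
        true_v = 4 / 3 * np.pi * r ** 3
        assert abs(f["MeshVolume"] - true_v) / true_v < 0.02
        assert 0.97 < f["Sphericity"] <= 1.0

    def test_single_voxel_volume(self):
        m = np.zeros((5, 5, 5))
        m[2, 2, 2] = 1
        f = shape_features(RoiMask(m, (0.6, 0.7, 3.0)))
        assert f["VoxelVolume"] == pytest.approx(0.6 * 0.7 * 3.0)

    def test_axis_ordering_and_anisotropy(self):
        """An elongated box has Major >= Minor >= Least and Elongation,
        Flatness in (0, 1]."""
        m = np.zeros((30, 20, 12), bool)
        m[5:25, 5:15, 4:8] = True
        f = shape_features(RoiMask(m, (1, 1, 1)))
        assert f["MajorAxisLength"] >= f["MinorAxisLength"] >= f["LeastAxisLength"]
        assert 0 < f["Flatness"] <= f["Elongation"] <= 1.0
        assert f["Maximum3DDiameter"] >= f["Maximum2DDiameterSlice"]

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            shape_features(RoiMask(np.zeros((3, 3, 3)), (1, 1, 1)))


class TestWavelet:
    def test_constant_volume_subbands(self):
        v = _cube(np.full((8, 8, 8), 3.0))
        bands = wavelet_subbands(v)
        for label, band in bands.items():
            if "H" in label:
                np.testing.assert_allclose(band.data, 0.0, atol=1e-10)
        lll = bands["LLL"].data
        np.testing.assert_allclose(lll, lll.flat[0], atol=1e-10)

    def test_perfect_reconstruction(self, rng):
        import pywt

        v = _cube(rng.standard_normal((8, 10, 12)))
        bands = wavelet_subbands(v)
        coeffs = {"".join("a" if c == "L" else "d" for c in k): b.data
                  for k, b in bands.items()}
        rec = pywt.iswtn([coeffs], "coif1")
        np.testing.assert_allclose(rec, v.data, atol=1e-8)

    def test_label_axis_convention(self):
        """A volume varying only along axis 0 has all its detail energy
        in H-on-axis-0 sub-bands."""
        data = np.tile(np.arange(16.0)[:, None, None] ** 2, (1, 8, 8))
        bands = wavelet_subbands(_cube(data))
        assert np.abs(bands["LLH"].data).max() < 1e-9
        assert np.abs(bands["LHL"].data).max() < 1e-9
        assert np.abs(bands["HLL"].data).max() > 1.0

    def test_too_small_volume_rejected(self):
        with pytest.raises(ValueError, match="filter"):
            wavelet_subbands(_cube(np.zeros((4, 8, 8))))


class TestFullExtraction:
    def test_cardinalities_and_unique_names(self, preprocessed_patient):
        t1, t2, mask = preprocessed_patient
        vec = extract_all(t1, t2, mask)
        assert len(vec) == 1072
        assert vec.index.is_unique
        t2_names = [n for n in vec.index if n.startswith("T_T2_")]
        assert len(t2_names) == 536
        wavelet_names = [n for n in t2_names if "_wavelet" in n]
        assert len(wavelet_names) == 464  # 8 x (18 + 40)
        texture = [n for n in t2_names if "_original_glcm_" in n
                   or "_original_glrlm_" in n]
        assert len(texture) == 40  # 24 GLCM + 16 GLRLM
        shape = [n for n in t2_names if "_shape_" in n]
        assert len(shape) == 14
        assert "T_T2_waveletLLL_glrlm_LongRunEmphasis" in vec.index
        assert list(vec.index) == feature_name_inventory()

    def test_intensity_shift_leaves_texture_unchanged(self, rng):
        """Fixed-bin-count discretization makes GLCM/GLRLM invariant to
        adding a constant to the image."""
        data = rng.standard_normal((6, 6, 6))
        mask = np.ones((6, 6, 6), bool)
        d1 = discretize_fixed_bin_count(data, mask, 8)
        d2 = discretize_fixed_bin_count(data + 57.0, mask, 8)
        f1, f2 = glcm_features(d1), glcm_features(d2)
        g1, g2 = glrlm_features(d1), glrlm_features(d2)
        for k in f1:
            assert f1[k] == pytest.approx(f2[k], abs=1e-12)
        for k in g1:
            assert g1[k] == pytest.approx(g2[k], abs=1e-12)

    def test_rotation_invariance_of_direction_averaged_texture(self, rng):
        """90-degree in-plane rotation permutes the 13 directions among
        themselves, so direction-averaged features are unchanged."""
        data = rng.standard_normal((7, 7, 7))
        mask = rng.random((7, 7, 7)) < 0.6
        mask[3, 3, 3] = True
        d1 = discretize_fixed_bin_count(data, mask, 6)
        d2 = discretize_fixed_bin_count(np.rot90(data, axes=(0, 1)),
                                        np.rot90(mask, axes=(0, 1)), 6)
        f1, f2 = glcm_features(d1), glcm_features(d2)
        g1, g2 = glrlm_features(d1), glrlm_features(d2)
        for k in f1:
            assert f1[k] == pytest.approx(f2[k], abs=1e-8)
        for k in g1:
            assert g1[k] == pytest.approx(g2[k], abs=1e-8)
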