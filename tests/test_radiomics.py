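"""Radiomics engine: registry counts, filters, and family-level oracles."""

import numpy as np
import pytest

from gliomets.radiomics import (
    DIRECTIONS_13,
    FeatureRegistry,
    FilterConfig,
    discretize,
    extract_case,
    first_order_features,
    glcm_matrix,
    log_filter,
    shape_features,
    texture_features,
    wavelet_decompose,
)
from gliomets.radiomics.shape import DegenerateROIError
from gliomets.radiomics.texture import glcm_features_single
from gliomets.roi import whole_roi
from gliomets.volume import Volume

from .conftest import make_ball_mask


def brute_force_glcm(bins, n_levels, direction):
    """Independent oracle: explicit pair enumeration over all voxels."""
    mat = np.zeros((n_levels, n_levels))
    shape = bins.shape
    for idx in np.ndindex(shape):
        j = tuple(i + d for i, d in zip(idx, direction))
        if all(0 <= jj < s for jj, s in zip(j, shape)):
            a, b = bins[idx], bins[j]
            if a > 0 and b > 0:
                mat[a - 1, b - 1] += 1
                mat[b - 1, a - 1] += 1
    return mat


class TestRegistry:
    def test_family_counts(self):
        reg = FeatureRegistry()
        assert len(reg.shape) == 14
        assert len(reg.first_order) == 18
        assert len(reg.glcm) + len(reg.gldm) + len(reg.glrlm) + len(reg.glszm) == 68

    def test_960_per_sequence(self):
        reg = FeatureRegistry()
        assert reg.features_per_sequence == 960
        # 14 + (18 + 68) * 11 = 960
        assert len(reg.image_types) == 11

    def test_case_vector_length(self):
        assert len(FeatureRegistry().case_feature_names()) == 2 * 960 + 1

    def test_sigma_levels_give_two_image_types(self):
        reg = FeatureRegistry(log_sigmas_mm=(3.0, 5.0))
        assert "log-sigma-3-0-mm" in reg.image_types
        assert "log-sigma-5-0-mm" in reg.image_types

    def test_bad_counts_rejected(self):
        with pytest.raises(ValueError):
            FeatureRegistry(shape=("a", "b"))


class TestFilters:
    def test_log_constant_image_is_zero(self):
        vol = Volume(data=np.full((20, 20, 20), 40.0), spacing=(1, 1, 1))
        out = log_filter(vol, 3.0)
        assert np.max(np.abs(out.data)) <= 1e-6 * 40.0

    def test_log_impulse_matches_analytic_kernel(self):
        """Impulse response equals the analytic Laplacian-of-Gaussian."""
        n = 33
        sigma = 2.5
        data = np.zeros((n, n, n))
        data[n // 2, n // 2, n // 2] = 1.0
        out = log_filter(Volume(data=data, spacing=(1, 1, 1)), sigma).data
        coords = np.meshgrid(*[np.arange(n) - n // 2] * 3, indexing="ij")
        r2 = sum(c.astype(float) ** 2 for c in coords)
        gauss = np.exp(-r2 / (2 * sigma**2)) / (2 * np.pi * sigma**2) ** 1.5
        analytic = gauss * (r2 - 3 * sigma**2) / sigma**4
        assert out[n // 2, n // 2, n // 2] < 0
        np.testing.assert_allclose(out, analytic, atol=2e-4)

    def test_log_rejects_bad_sigma(self):
        vol = Volume(data=np.zeros((8, 8, 8)), spacing=(1, 1, 1))
        with pytest.raises(ValueError):
            log_filter(vol, 0.0)

    def test_wavelet_eight_subbands_on_grid(self):
        rng = np.random.default_rng(0)
        vol = Volume(data=rng.normal(size=(16, 14, 12)), spacing=(1, 1, 1))
        subs = wavelet_decompose(vol)
        assert len(subs) == 8
        assert all(s.shape == vol.shape for s in subs.values())

    def test_wavelet_detail_of_constant_vanishes(self):
        vol = Volume(data=np.full((16, 16, 16), 7.0), spacing=(1, 1, 1))
        subs = wavelet_decompose(vol, family="haar")
        for name, sub in subs.items():
            if "H" in name:
                interior = sub.data[4:-4, 4:-4, 4:-4]
                assert np.max(np.abs(interior)) < 1e-9

    def test_wavelet_deterministic(self):
        rng = np.random.default_rng(1)
        vol = Volume(data=rng.normal(size=(12, 12, 12)), spacing=(1, 1, 1))
        a = wavelet_decompose(vol)["HLH"].data
        b = wavelet_decompose(vol)["HLH"].data
        np.testing.assert_array_equal(a, b)

    def test_wavelet_degenerate_axis(self):
        vol = Volume(data=np.zeros((3, 16, 16)), spacing=(1, 1, 1))
        with pytest.raises(ValueError, match="axis"):
            wavelet_decompose(vol)

    def test_discretize_example(self):
        data = np.array([0.0, 24.9, 25.0, 50.0]).reshape(4, 1, 1)
        roi = np.ones((4, 1, 1), dtype=bool)
        bins, n = discretize(data, roi, 25.0)
        assert list(bins[:, 0, 0]) == [1, 1, 2, 3]
        assert n == 3

    def test_discretize_constant_single_bin(self):
        data = np.full((3, 3, 3), 9.0)
        bins, n = discretize(data, np.ones((3, 3, 3), bool), 25.0)
        assert n == 1
        assert set(np.unique(bins)) == {1}

    def test_discretize_bad_width(self):
        with pytest.raises(ValueError):
            discretize(np.zeros((2, 2, 2)), np.ones((2, 2, 2), bool), 0.0)


class TestShape:
    def test_exactly_14_entries(self):
        vals = shape_features(whole_roi(make_ball_mask(6.0, (20, 20, 20))), (1, 1, 1))
        assert len(vals) == 14

    def test_ball_sphericity_and_flatness(self):
        roi = whole_roi(make_ball_mask(10.0, (32, 32, 32)))
        vals = shape_features(roi, (1, 1, 1))
        assert 0.95 <= vals["Sphericity"] <= 1.0
        assert 0.95 <= vals["Flatness"] <= 1.0

    def test_two_voxel_maximum_diameter(self):
        """Voxel centers (0,0,0) and (3,4,0) mm are 5 mm apart."""
        roi = np.zeros((8, 8, 4), dtype=bool)
        roi[0, 0, 0] = True
        roi[3, 4, 0] = True
        vals = shape_features(roi, (1, 1, 1))
        assert vals["Maximum3DDiameter"] == pytest.approx(5.0)
        assert vals["Maximum2DDiameterSlice"] == pytest.approx(5.0)

    def test_degenerate_roi_raises(self):
        roi = np.zeros((4, 4, 4), dtype=bool)
        with pytest.raises(DegenerateROIError):
            shape_features(roi, (1, 1, 1))
        roi[1, 1, 1] = True
        with pytest.raises(DegenerateROIError):
            shape_features(roi, (1, 1, 1))

    def test_spacing_scales_volume(self):
        roi = whole_roi(make_ball_mask(6.0, (20, 20, 20)))
        v1 = shape_features(roi, (1, 1, 1))["VoxelVolume"]
        v2 = shape_features(roi, (2, 2, 2))["VoxelVolume"]
        assert v2 == pytest.approx(8 * v1)


class TestFirstOrder:
    def test_exactly_18_entries_and_hand_values(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0])
        bins = np.array([1, 1, 2, 2])
        out = first_order_features(vals, bins, 1.0)
        assert len(out) == 18
        assert out["Mean"] == pytest.approx(2.5)
        assert out["Variance"] == pytest.approx(1.25)  # population
        assert out["Range"] == pytest.approx(3.0)
        assert out["Energy"] == pytest.approx(30.0)
        assert out["RootMeanSquared"] == pytest.approx(np.sqrt(7.5))

    def test_constant_roi_conventions(self):
        vals = np.full(20, 4.0)
        bins = np.ones(20, dtype=int)
        out = first_order_features(vals, bins, 1.0)
        assert out["Variance"] == 0.0
        assert out["Uniformity"] == 1.0
        assert out["Entropy"] == 0.0
        assert out["Skewness"] == 0.0

    def test_mean_variance_against_direct_summation(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(10, 3, 500)
        bins = np.ones(500, dtype=int)
        out = first_order_features(vals, bins, 1.0)
        assert abs(out["Mean"] - np.sum(vals) / 500) <= 1e-9
        assert abs(out["Variance"] - np.sum((vals - vals.mean()) ** 2) / 500) <= 1e-9


class TestTexture:
    def test_glcm_matrix_matches_brute_force(self):
        """4x4x1 toy grid: vectorized co-occurrences = explicit pair counting."""
        bins = np.array(
            [[1, 2, 5, 2], [3, 2, 1, 3], [1, 3, 5, 5], [3, 1, 1, 1]]
        ).reshape(4, 4, 1)
        for d in DIRECTIONS_13:
            fast = glcm_matrix(bins, 5, d)
            slow = brute_force_glcm(bins, 5, d)
            np.testing.assert_array_equal(fast, slow)

    def test_glcm_contrast_hand_value(self):
        """2x2x1 grid [[1,2],[2,2]], direction (1,0,0): pairs (1,2),(2,2)."""
        bins = np.array([[1, 2], [2, 2]]).reshape(2, 2, 1)
        mat = glcm_matrix(bins, 2, (1, 0, 0))
        # symmetric counts: (1,2)+(2,1) once each, (2,2) twice
        np.testing.assert_array_equal(mat, [[0, 1], [1, 2]])
        feats = glcm_features_single(mat / mat.sum())
        assert feats["Contrast"] == pytest.approx(2 * 1 / 4)  # sum (i-j)^2 p

    def test_exactly_68_texture_values(self):
        rng = np.random.default_rng(4)
        bins = np.zeros((6, 6, 6), dtype=np.int64)
        bins[1:5, 1:5, 1:5] = rng.integers(1, 5, (4, 4, 4))
        fams = texture_features(bins, 4)
        assert sum(len(v) for v in fams.values()) == 68

    def test_constant_roi_limits(self):
        bins = np.zeros((6, 6, 6), dtype=np.int64)
        bins[1:5, 1:5, 1:5] = 1
        fams = texture_features(bins, 1)
        assert fams["glcm"]["JointEnergy"] == pytest.approx(1.0)
        assert fams["glcm"]["Contrast"] == pytest.approx(0.0)
        assert fams["glrlm"]["GrayLevelNonUniformityNormalized"] == pytest.approx(1.0)

    def test_direction_average_axis_permutation_invariant(self):
        """Features of an axis-symmetric ROI survive axis permutation."""
        rng = np.random.default_rng(5)
        n = 7
        sym = rng.integers(1, 4, (n, n, n))
        sym = sym + sym.transpose(1, 0, 2) + sym.transpose(2, 1, 0)  # symmetrize
        sym = sym + sym.transpose(0, 2, 1)
        bins = np.asarray(sym % 3 + 1, dtype=np.int64)
        base = texture_features(bins, 3)
        perm = texture_features(np.ascontiguousarray(bins.transpose(2, 0, 1)), 3)
        for fam in base:
            for k in base[fam]:
                assert base[fam][k] == pytest.approx(perm[fam][k], abs=1e-9), (fam, k)


class TestExtraction:
    def test_counts_and_determinism(self, glioma_case_normalized):
        case, t1, fl = glioma_case_normalized
        cfg = FilterConfig(bin_width=0.25)
        roi = whole_roi(case.truth_mask)
        vec = extract_case(t1, fl, roi, case.lesion_count_truth, config=cfg)
        assert len(vec) == 1921
        assert np.isfinite(vec.to_numpy()).all()
        t1_cols = [c for c in vec.index if c.startswith("t1ce_")]
        assert len(t1_cols) == 960
        vec2 = extract_case(t1, fl, roi, case.lesion_count_truth, config=cfg)
        np.testing.assert_array_equal(vec.to_numpy(), vec2.to_numpy())

    def test_shape_intensity_invariance(self, glioma_case_normalized):
        case, t1, fl = glioma_case_normalized
        cfg = FilterConfig(bin_width=0.25)
        roi = whole_roi(case.truth_mask)
        a = extract_case(t1, fl, roi, 1, config=cfg)
        b = extract_case(
            t1.with_data(t1.data * 10), fl.with_data(fl.data * 10), roi, 1, config=cfg
        )
        shape_cols = [c for c in a.index if "_shape_" in c]
        np.testing.assert_array_equal(a[shape_cols].to_numpy(), b[shape_cols].to_numpy())
        assert a["t1ce_original_firstorder_Energy"] != b["t1ce_original_firstorder_Energy"]

    def test_empty_roi_errors(self, glioma_case_normalized):
        from gliomets.radiomics import FeatureExtractionError

        case, t1, fl = glioma_case_normalized
        with pytest.raises(FeatureExtractionError):
            extract_case(t1, fl, np.zeros(t1.shape, bool), 0)
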