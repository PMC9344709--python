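"""Moment statistics, quantization, GLCM construction and its features."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import stats as sps

from adctexture.adc import ADCMap, PixelSample, ROIMask
from adctexture.errors import (
    AdcTextureError,
    DegenerateSampleError,
    FeatureExtractionError,
)
from adctexture.texture import (
    IMAGE_FEATURE_NAMES,
    compute_glcm,
    extract_image_features,
    glcm_features,
    orientation_offsets,
    quantize,
    roi_mean,
    standardized_moment,
)


class TestMoments:
    def test_mean_examples(self):
        assert roi_mean(PixelSample([5, 5, 5])) == 5
        assert roi_mean(PixelSample([1, 2, 3, 4])) == 2.5

    def test_mean_of_large_normal_sample(self):
        rng = np.random.default_rng(42)
        mu, sigma, n = 800e-6, 50e-6, 10_000
        m = roi_mean(PixelSample(rng.normal(mu, sigma, n)))
        assert abs(m - mu) < 3 * sigma / np.sqrt(n)

    def test_skewness_of_symmetric_sample_is_zero(self):
        assert standardized_moment(PixelSample([-2, -1, 0, 1, 2]), 3) == pytest.approx(0)

    def test_two_point_kurtosis_is_one(self):
        # m4 = 1, sigma^4 = 1 by hand
        assert standardized_moment(PixelSample([-1, -1, 1, 1]), 4) == pytest.approx(1.0)

    def test_normal_kurtosis_approaches_three(self):
        x = np.random.default_rng(7).standard_normal(1_000_000)
        k = standardized_moment(PixelSample(x), 4)
        assert k == pytest.approx(3.0, abs=0.05)

    def test_agrees_with_scipy_biased_estimators(self):
        x = np.random.default_rng(3).gamma(2.0, size=500)
        s = PixelSample(x)
        assert standardized_moment(s, 3) == pytest.approx(sps.skew(x, bias=True))
        assert standardized_moment(s, 4) == pytest.approx(
            sps.kurtosis(x, fisher=False, bias=True)
        )

    def test_degenerate_samples_error(self):
        with pytest.raises(DegenerateSampleError):
            standardized_moment(PixelSample([3.0, 3.0, 3.0]), 4)
        with pytest.raises(DegenerateSampleError):
            standardized_moment(PixelSample([1.0]), 3)

    @given(
        x=hnp.arrays(
            float,
            st.integers(5, 40),
            elements=st.floats(-1e3, 1e3, allow_nan=False),
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_kurtosis_skewness_bound(self, x):
        """kurtosis >= skewness^2 + 1 for any non-degenerate sample."""
        s = PixelSample(x)
        if np.var(x) < 1e-10 * (np.mean(x**2) + 1e-30):
            return  # numerically degenerate: cancellation dominates
        try:
            sk = standardized_moment(s, 3)
            ku = standardized_moment(s, 4)
        except DegenerateSampleError:
            return
        assert ku >= sk**2 + 1 - 1e-6 * max(1.0, sk**2)


class TestQuantize:
    def full(self, arr):
        a = np.asarray(arr, float)
        return ADCMap(a), ROIMask(np.ones(a.shape, bool))

    def test_constant_roi_maps_to_zero(self):
        adc, roi = self.full(np.full((3, 3), 7.0))
        assert np.all(quantize(adc, roi, 8).grid == 0)

    def test_bin_edges_two_levels(self):
        adc, roi = self.full([[0.0, 0.5, 1.0]])
        q = quantize(adc, roi, 2)
        assert list(q.grid[0]) == [0, 1, 1]

    def test_levels_within_range_and_absent_marker(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(6, 6))
        mask = rng.random((6, 6)) > 0.4
        mask[0, 0] = True
        q = quantize(ADCMap(vals), ROIMask(mask), 16)
        assert q.grid[mask].min() >= 0 and q.grid[mask].max() <= 15
        assert np.all(q.grid[~mask] == -1)

    def test_affine_rescale_invariance(self):
        rng = np.random.default_rng(9)
        vals = rng.normal(size=(8, 8))
        roi = ROIMask(np.ones((8, 8), bool))
        q1 = quantize(ADCMap(vals), roi, 16)
        q2 = quantize(ADCMap(3.5 * vals + 10.0), roi, 16)
        assert np.array_equal(q1.grid, q2.grid)


def brute_force_glcm_counts(grid, mask, offset, levels, symmetric):
    """Independent pair-enumeration oracle for the co-occurrence counts."""
    rows, cols = grid.shape
    dr, dc = offset
    counts = np.zeros((levels, levels))
    for r in range(rows):
        for c in range(cols):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < rows and 0 <= c2 < cols and mask[r, c] and mask[r2, c2]:
                counts[grid[r, c], grid[r2, c2]] += 1
    if symmetric:
        counts = counts + counts.T
    return counts


class TestGLCM:
    def quantized(self, grid, mask=None):
        from adctexture.texture import QuantizedROI

        grid = np.asarray(grid)
        if mask is None:
            mask = np.ones(grid.shape, bool)
        g = np.where(mask, grid, -1)
        return QuantizedROI(levels=int(grid.max()) + 1, grid=g, mask=ROIMask(mask))

    def test_horizontal_pairs_hand_count(self):
        q = self.quantized([[0, 0], [1, 1]])
        M = compute_glcm(q, (0, 1), symmetric=True)
        assert np.allclose(M.P, [[0.5, 0.0], [0.0, 0.5]])

    def test_vertical_pairs_hand_count(self):
        q = self.quantized([[0, 0], [1, 1]])
        M = compute_glcm(q, (1, 0), symmetric=True)
        assert np.allclose(M.P, [[0.0, 0.5], [0.5, 0.0]])

    def test_normalization_and_raw_counts(self):
        rng = np.random.default_rng(1)
        q = self.quantized(rng.integers(0, 4, size=(6, 6)))
        M = compute_glcm(q, (0, 1))
        assert M.P.sum() == pytest.approx(1.0)
        assert np.allclose(M.P, M.P.T)
        assert M.counts.sum() > 0 and np.allclose(M.counts / M.counts.sum(), M.P)

    @pytest.mark.parametrize("symmetric", [True, False])
    def test_matches_brute_force_oracle_on_random_masked_images(self, symmetric):
        rng = np.random.default_rng(2024)
        for trial in range(30):
            rows, cols = rng.integers(3, 9, size=2)
            levels = int(rng.integers(2, 6))
            grid = rng.integers(0, levels, size=(rows, cols))
            mask = rng.random((rows, cols)) > 0.3
            if mask.sum() < 2:
                continue
            from adctexture.texture import QuantizedROI

            q = QuantizedROI(
                levels=levels, grid=np.where(mask, grid, -1), mask=ROIMask(mask)
            )
            for off in orientation_offsets(1):
                expected = brute_force_glcm_counts(grid, mask, off, levels, symmetric)
                if expected.sum() == 0:
                    with pytest.raises(AdcTextureError):
                        compute_glcm(q, off, symmetric=symmetric)
                    continue
                M = compute_glcm(q, off, symmetric=symmetric)
                assert np.array_equal(M.counts, expected)

    def test_matches_skimage_on_full_mask(self):
        """Cross-check against the reference co-occurrence implementation
        (which has no mask support, hence the full mask)."""
        graycomatrix = pytest.importorskip("skimage.feature").graycomatrix
        rng = np.random.default_rng(8)
        grid = rng.integers(0, 8, size=(12, 12))
        q = self.quantized(grid)
        # skimage's angle k maps to displacement (sin k, cos k); under
        # symmetric accumulation that matches our up-oriented offsets as:
        angle_for_offset = {(0, 1): 0, (-1, 1): 3 * np.pi / 4, (-1, 0): np.pi / 2,
                            (-1, -1): np.pi / 4}
        for off, angle in angle_for_offset.items():
            ref = graycomatrix(
                grid.astype(np.uint8), [1], [angle], levels=8, symmetric=True
            )[:, :, 0, 0]
            M = compute_glcm(q, off, symmetric=True)
            assert np.array_equal(M.counts, ref)

    def test_zero_offset_rejected(self):
        with pytest.raises(AdcTextureError):
            compute_glcm(self.quantized([[0, 1]]), (0, 0))

    def test_roi_too_small_for_offset(self):
        mask = np.zeros((4, 4), bool)
        mask[0, 0] = mask[3, 3] = True
        q = self.quantized(np.zeros((4, 4), int), mask)
        with pytest.raises(AdcTextureError, match="too small"):
            compute_glcm(q, (0, 1))


class TestGLCMFeatures:
    def matrix(self, P, symmetric=True):
        from adctexture.texture import GLCMatrix

        P = np.asarray(P, float)
        return GLCMatrix(P=P, counts=P, offset=(0, 1), levels=P.shape[0],
                         symmetric=symmetric)

    def test_hand_oracle_diagonal_half_matrix(self):
        f = glcm_features(self.matrix([[0.5, 0.0], [0.0, 0.5]]))
        assert f.mean_i == pytest.approx(0.5)
        assert f.mean_j == pytest.approx(0.5)
        assert f.var_i == pytest.approx(0.25)
        assert f.var_j == pytest.approx(0.25)
        assert f.energy == pytest.approx(0.5)
        assert f.entropy == pytest.approx(np.log(2))
        assert f.contrast == pytest.approx(0.0)
        assert f.homogeneity == pytest.approx(1.0)
        assert f.correlation == pytest.approx(1.0)
        assert f.shade == pytest.approx(0.0)
        assert f.prominence == pytest.approx(1.0)

    def test_single_entry_matrix_uniform_texture(self):
        P = np.zeros((4, 4))
        P[2, 2] = 1.0
        f = glcm_features(self.matrix(P))
        assert f.energy == 1.0
        assert f.entropy == 0.0
        assert f.contrast == 0.0
        assert f.homogeneity == 1.0
        assert np.isnan(f.correlation)  # undefined, never silently 0

    def test_uniform_matrix_closed_forms(self):
        n = 8
        f = glcm_features(self.matrix(np.full((n, n), 1.0 / n**2)))
        assert f.energy == pytest.approx(1.0 / n**2)
        assert f.entropy == pytest.approx(2 * np.log(n))
        assert f.correlation == pytest.approx(0.0, abs=1e-12)

    def test_range_invariants_on_random_matrices(self):
        rng = np.random.default_rng(77)
        for _ in range(50):
            n = int(rng.integers(2, 10))
            raw = rng.random((n, n))
            raw = raw + raw.T
            f = glcm_features(self.matrix(raw / raw.sum()))
            assert 0 < f.energy <= 1
            assert 0 < f.homogeneity <= 1
            assert f.contrast >= 0 and f.prominence >= 0
            assert 0 <= f.entropy <= 2 * np.log(n) + 1e-12
            assert -1 - 1e-12 <= f.correlation <= 1 + 1e-12


class TestExtractImageFeatures:
    def textured(self, seed=0, shape=(32, 32)):
        rng = np.random.default_rng(seed)
        vals = rng.normal(1000e-6, 100e-6, size=shape)
        return ADCMap(vals), ROIMask(np.ones(shape, bool))

    def test_returns_all_fourteen_features(self):
        adc, roi = self.textured()
        feats = extract_image_features(adc, roi)
        assert list(feats) == IMAGE_FEATURE_NAMES
        assert all(np.isfinite(v) for v in feats.values())
        # symmetric accumulation makes both sides equal
        assert feats["glcm_mean_1"] == pytest.approx(feats["glcm_mean_2"])
        assert feats["glcm_var_1"] == pytest.approx(feats["glcm_var_2"])

    def test_isotropic_average_bounded_by_orientations(self):
        from adctexture.texture import compute_glcm, glcm_features, quantize

        adc, roi = self.textured(seed=4)
        q = quantize(adc, roi, 16)
        per = [
            glcm_features(compute_glcm(q, off)).contrast
            for off in orientation_offsets(1)
        ]
        feats = extract_image_features(adc, roi)
        assert min(per) <= feats["glcm_contrast"] <= max(per)
        assert feats["glcm_contrast"] == pytest.approx(np.mean(per))

    def test_constant_roi_flagged_invalid(self):
        adc = ADCMap(np.full((16, 16), 5e-4))
        roi = ROIMask(np.ones((16, 16), bool))
        with pytest.raises(FeatureExtractionError):
            extract_image_features(adc, roi)

    def test_rotation_by_90_degrees_preserves_averaged_features(self):
        adc, _ = self.textured(seed=12, shape=(20, 20))
        mask = np.zeros((20, 20), bool)
        mask[4:16, 6:15] = True
        base = extract_image_features(adc, ROIMask(mask))
        rot = extract_image_features(
            ADCMap(np.rot90(adc.values)), ROIMask(np.rot90(mask))
        )
        for k in IMAGE_FEATURE_NAMES:
            assert base[k] == pytest.approx(rot[k], rel=1e-9), k

    def test_smooth_texture_scores_higher_homogeneity_lower_contrast(self):
        from scipy.ndimage import gaussian_filter

        rng = np.random.default_rng(21)
        rough = rng.standard_normal((40, 40))
        smooth = gaussian_filter(rng.standard_normal((40, 40)), 3.0)
        roi = ROIMask(np.ones((40, 40), bool))
        f_rough = extract_image_features(ADCMap(rough), roi)
        f_smooth = extract_image_features(ADCMap(smooth), roi)
        assert f_smooth["glcm_homogeneity"] > f_rough["glcm_homogeneity"]
        assert f_smooth["glcm_contrast"] < f_rough["glcm_contrast"]
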