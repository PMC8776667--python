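"""Texture descriptors against hand computations and brute-force oracles."""

import numpy as np
import pytest
import pywt

from cystct.texture import (
    DEFAULT_GLCM_OFFSETS,
    FeatureVector,
    gabor_features,
    glcm_features,
    glcm_matrix,
    hog_features,
    lbp_features,
    quantize_gray,
    wavelet_features,
)


def brute_force_glcm(q, offset, levels):
    """Count every ordered pixel pair in both directions, then normalize."""
    dr, dc = offset
    h, w = q.shape
    M = np.zeros((levels, levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                M[q[r, c], q[r2, c2]] += 1
                M[q[r2, c2], q[r, c]] += 1
    total = M.sum()
    return M / total if total else M


class TestGLCM:
    def test_two_by_two_worked_example(self):
        """[[0,0],[1,1]] at offset (0,1): pairs (0,0) and (1,1) once each."""
        q = np.array([[0, 0], [1, 1]])
        M = glcm_matrix(q, (0, 1), 2)
        assert np.allclose(M, [[0.5, 0.0], [0.0, 0.5]])
        fv = glcm_features(q, levels=2, offsets=((0, 1),))
        contrast, correlation, energy, homogeneity, entropy = fv.values
        assert contrast == pytest.approx(0.0)
        assert energy == pytest.approx(0.5)
        assert homogeneity == pytest.approx(1.0)

    def test_constant_patch_degenerate_stats(self):
        fv = glcm_features(np.zeros((6, 6), dtype=int), levels=4)
        for off_block in fv.values.reshape(len(DEFAULT_GLCM_OFFSETS), 5):
            contrast, _, energy, homogeneity, entropy = off_block
            assert contrast == pytest.approx(0.0)
            assert energy == pytest.approx(1.0)
            assert homogeneity == pytest.approx(1.0)
            assert entropy == pytest.approx(0.0)

    @pytest.mark.parametrize("offset", DEFAULT_GLCM_OFFSETS)
    def test_matrix_equals_bruteforce_on_random_patches(self, offset):
        rng = np.random.default_rng(0)
        for _ in range(5):
            q = rng.integers(0, 8, size=(16, 16))
            assert np.allclose(glcm_matrix(q, offset, 8), brute_force_glcm(q, offset, 8))

    def test_exhaustive_3x3_binary_patches(self):
        """Every 3x3 binary patch, every default offset: exact oracle match."""
        for code in range(512):
            q = np.array([(code >> k) & 1 for k in range(9)]).reshape(3, 3)
            for offset in DEFAULT_GLCM_OFFSETS:
                assert np.allclose(
                    glcm_matrix(q, offset, 2), brute_force_glcm(q, offset, 2)
                )

    def test_oversized_offset_rejected(self):
        with pytest.raises(ValueError):
            glcm_matrix(np.zeros((3, 3), dtype=int), (0, 5), 2)

    def test_quantization_buckets(self):
        patch = np.array([[0.0, 0.49, 0.51, 0.999]])
        assert quantize_gray(patch, 2).tolist() == [[0, 0, 1, 1]]


class TestLBP:
    def test_constant_patch_single_code(self):
        """All-equal neighborhoods: every code is 2^8-1 under >= thresholding."""
        fv = lbp_features(np.full((8, 8), 0.3))
        assert fv.values[255] == pytest.approx(1.0)

    def test_histogram_sums_to_one(self, rng):
        fv = lbp_features(rng.random((12, 12)))
        assert fv.values.sum() == pytest.approx(1.0)
        assert fv.length == 256

    def test_codes_match_bruteforce_bilinear_oracle(self):
        """Interior codes equal explicit per-pixel recomputation (P=8, R=1)."""
        from skimage.feature import local_binary_pattern

        rng = np.random.default_rng(2)
        img = rng.random((8, 8))
        P, R = 8, 1

        def neighbor(r, c, p):
            rr = r - R * np.sin(2 * np.pi * p / P)
            cc = c + R * np.cos(2 * np.pi * p / P)
            fr, fc = int(np.floor(rr)), int(np.floor(cc))
            dr, dc = rr - fr, cc - fc
            def px(a, b):
                return img[a, b] if (0 <= a < 8 and 0 <= b < 8) else 0.0
            return (
                px(fr, fc) * (1 - dr) * (1 - dc)
                + px(fr, fc + 1) * (1 - dr) * dc
                + px(fr + 1, fc) * dr * (1 - dc)
                + px(fr + 1, fc + 1) * dr * dc
            )

        expected = np.zeros((8, 8))
        for r in range(8):
            for c in range(8):
                expected[r, c] = sum(
                    2**p
                    for p in range(P)
                    if neighbor(r, c, p) >= img[r, c] - 1e-12
                )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            codes = local_binary_pattern(img, P, R, method="default")
        assert np.array_equal(codes[1:-1, 1:-1], expected[1:-1, 1:-1])

    def test_too_small_patch_rejected(self):
        with pytest.raises(ValueError):
            lbp_features(np.ones((3, 3)))


class TestHOG:
    def test_constant_patch_zero_descriptor(self):
        assert not hog_features(np.full((32, 32), 0.5)).values.any()

    def test_deterministic_and_fixed_length(self, rng):
        a = rng.random((40, 55))
        fv1, fv2 = hog_features(a), hog_features(a)
        assert np.array_equal(fv1.values, fv2.values)
        # 64/8=8 cells/side, 7x7 block positions, 2x2 cells x 9 bins each
        assert fv1.length == 7 * 7 * 2 * 2 * 9
        assert hog_features(rng.random((21, 33))).length == fv1.length

    def test_vertical_stripes_concentrate_horizontal_gradient_bin(self):
        stripes = np.tile(np.repeat([0.0, 1.0], 8), (64, 4))[:, :64]
        fv = hog_features(stripes)
        per_bin = fv.values.reshape(-1, 9).sum(axis=0)
        # vertical stripe edges -> gradients along x -> orientation bin 0
        assert per_bin.argmax() == 0

    def test_cell_larger_than_patch_rejected(self):
        with pytest.raises(ValueError):
            hog_features(np.ones((16, 16)), cell_size=(128, 128))


class TestGabor:
    def test_constant_patch_zero_std(self):
        fv = gabor_features(np.full((16, 16), 0.7))
        stds = fv.values[1::2]
        assert np.allclose(stds, 0.0, atol=1e-10)

    def test_descriptor_length_contract(self, rng):
        fv = gabor_features(rng.random((16, 16)), frequencies=(0.1, 0.3),
                            orientations=(0.0, np.pi / 2))
        assert fv.length == 2 * 2 * 2

    def test_grating_maximizes_matched_filter(self):
        """A horizontal-frequency grating excites the matched (f, theta=0) filter."""
        x = np.arange(32)
        grating = np.tile(np.sin(2 * np.pi * 0.2 * x), (32, 1))
        freqs, thetas = (0.1, 0.2, 0.3), (0.0, np.pi / 2)
        fv = gabor_features(grating, frequencies=freqs, orientations=thetas)
        means = fv.values[0::2].reshape(len(freqs), len(thetas))
        best_f, best_t = np.unravel_index(means.argmax(), means.shape)
        assert (freqs[best_f], thetas[best_t]) == (0.2, 0.0)

    def test_empty_bank_rejected(self):
        with pytest.raises(ValueError):
            gabor_features(np.ones((8, 8)), frequencies=())


class TestWavelet:
    def test_constant_patch_zero_detail_energy(self):
        fv = wavelet_features(np.full((8, 8), 2.0), "haar", 1)
        energies = fv.values[0::2]
        # subband order: approximation first, then the three details
        assert energies[0] > 0
        assert np.allclose(energies[1:], 0.0)

    def test_haar_level1_hand_transform(self):
        """2x2 patch [[a,b],[c,d]]: approx (a+b+c+d)/2, details signed half-sums."""
        a, b, c, d = 1.0, 2.0, 3.0, 5.0
        coeffs = pywt.wavedec2(np.array([[a, b], [c, d]]), "haar", level=1)
        approx = coeffs[0][0, 0]
        (ch, cv, cd) = (coeffs[1][0][0, 0], coeffs[1][1][0, 0], coeffs[1][2][0, 0])
        assert approx == pytest.approx((a + b + c + d) / 2)
        assert ch == pytest.approx((a + b - c - d) / 2)
        assert cv == pytest.approx((a - b + c - d) / 2)
        assert cd == pytest.approx((a - b - c + d) / 2)

    def test_parseval_identity_haar(self, rng):
        """Orthonormal Haar: total coefficient energy equals input energy."""
        x = rng.random((16, 16))
        coeffs = pywt.wavedec2(x, "haar", level=2)
        total = np.sum(coeffs[0] ** 2) + sum(
            np.sum(band**2) for level in coeffs[1:] for band in level
        )
        assert total == pytest.approx(np.sum(x**2))

    def test_length_contract_and_small_patch(self, rng):
        assert wavelet_features(rng.random((16, 16)), "haar", 2).length == 14
        with pytest.raises(ValueError):
            wavelet_features(np.ones((3, 3)), "haar", 2)


def test_feature_vectors_reject_nonfinite():
    with pytest.raises(ValueError):
        FeatureVector(np.array([1.0, np.nan]), "bad")
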