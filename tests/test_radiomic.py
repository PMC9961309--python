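import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mgmtpmp.phantoms import toy_level_matrix
from mgmtpmp.radiomic import (
    GLCMConfig,
    GLCMProfile,
    HOGConfig,
    LBPConfig,
    cell_histograms,
    compute_glcm,
    glcm_feature_vector,
    haralick13,
    hog_feature_vector,
    lbp_bin_count,
    lbp_code,
    lbp_code_image,
    lbp_feature_vector,
    normalize_glcm,
    quantize_levels,
    radiomic_feature_vector,
)
from mgmtpmp.radiomic.lbp import _uniform_bin_map

from .oracles import brute_glcm, brute_haralick13


class TestQuantizeLevels:
    @pytest.mark.parametrize(
        "value, n_levels, expected",
        [(0, 8, 0), (255, 8, 7), (128, 4, 2), (0, 4, 0), (255, 4, 3)],
    )
    def test_endpoint_and_interior_examples(self, value, n_levels, expected):
        assert quantize_levels(np.array([[value]], np.uint8), n_levels)[0, 0] == expected

    def test_identity_at_256_levels(self, rng):
        img = rng.integers(0, 256, (16, 16)).astype(np.uint8)
        assert np.array_equal(quantize_levels(img, 256), img)


class TestComputeGLCM:
    def test_pair_counting_on_fig_like_matrix(self):
        m = compute_glcm(toy_level_matrix("fig6-like"), 1, 0, 4)
        assert m[3, 0] == 4

    def test_two_column_stripes(self):
        m = compute_glcm(toy_level_matrix("hstripes"), 1, 0, 2)
        assert m[0, 1] == 2 and m.sum() == 2

    def test_constant_image_single_diagonal_entry(self):
        m = compute_glcm(toy_level_matrix("constant4"), 1, 45, 4)
        assert m[2, 2] == m.sum() > 0

    @pytest.mark.parametrize("theta", [0, 45, 90, 135])
    @pytest.mark.parametrize("d", [1, 2, 3])
    def test_matches_brute_force_enumeration(self, rng, theta, d):
        lv = rng.integers(0, 4, (8, 8))
        assert np.array_equal(
            compute_glcm(lv, d, theta, 4), brute_glcm(lv, d, theta, 4)
        )

    @pytest.mark.parametrize(
        "theta, sk_angle, transpose",
        [(0, 0.0, False), (45, 3 * np.pi / 4, True),
         (90, np.pi / 2, True), (135, np.pi / 4, True)],
    )
    def test_agrees_with_skimage_up_to_direction_convention(
        self, rng, theta, sk_angle, transpose
    ):
        # unit distance only: skimage rounds diagonal offsets per component,
        # so d >= 2 diagonals are not directly comparable; its angles also
        # run clockwise in image coordinates (hence the 45/135 swap and the
        # transposed pair order)
        from skimage.feature import graycomatrix

        lv = rng.integers(0, 6, (12, 12))
        sk = graycomatrix(lv.astype(np.uint8), [1], [sk_angle], levels=6)[:, :, 0, 0]
        mine = compute_glcm(lv, 1, theta, 6)
        assert np.array_equal(mine, sk.T if transpose else sk)

    def test_oversized_distance_is_error(self):
        with pytest.raises(ValueError, match="no valid pixel pairs"):
            compute_glcm(np.zeros((4, 4), int), 4, 0, 2)

    def test_normalization_sums_to_one(self, rng):
        lv = rng.integers(0, 8, (16, 16))
        p = normalize_glcm(compute_glcm(lv, 3, 135, 8))
        assert p.sum() == pytest.approx(1.0, abs=1e-12)


class TestHaralick13:
    def test_single_atom_distribution(self):
        p = np.zeros((4, 4))
        p[2, 2] = 1.0
        f = haralick13(p)
        assert f[0] == 1.0 and f[1] == 0.0 and f[8] == 0.0

    def test_contrast_of_off_diagonal_atom(self):
        p = np.zeros((4, 4))
        p[0, 1] = 1.0
        assert haralick13(p)[1] == 1.0

    def test_uniform_two_level_matrix(self):
        f = haralick13(np.full((2, 2), 0.25))
        assert f[0] == pytest.approx(0.25)
        assert f[8] == pytest.approx(np.log(4))  # natural-log entropy

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(8):
            lv = rng.integers(0, 4, (8, 8))
            p = normalize_glcm(compute_glcm(lv, 1, 45, 4))
            assert np.allclose(haralick13(p), brute_haralick13(p), atol=1e-10)

    def test_feature_ranges_on_random_glcms(self, rng):
        for _ in range(5):
            lv = rng.integers(0, 8, (16, 16))
            f = haralick13(normalize_glcm(compute_glcm(lv, 1, 0, 8)))
            assert 0 < f[0] <= 1  # angular second moment
            assert f[8] >= 0  # entropy
            assert -1 <= f[2] <= 1  # correlation

    def test_unnormalized_input_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            GLCMProfile(np.full((2, 2), 1.0))


class TestGLCMFeatureVector:
    def test_length_is_13(self, random_images):
        assert glcm_feature_vector(random_images[0]).shape == (13,)

    def test_invariant_under_90_degree_rotation(self, random_images):
        for img in random_images[:3]:
            a = glcm_feature_vector(img)
            b = glcm_feature_vector(np.rot90(img))
            assert np.allclose(a, b, atol=1e-10)

    def test_constant_image_has_zero_contrast_and_variance(self):
        f = glcm_feature_vector(np.full((64, 64), 80, np.uint8))
        assert f[1] == 0.0 and f[3] == 0.0

    def test_direction_averaging_vs_pooled_matrices_differ_in_general(self, random_images):
        img = random_images[0]
        a = glcm_feature_vector(img)
        b = glcm_feature_vector(img, average_glcms=True)
        assert a.shape == b.shape == (13,)
        assert not np.allclose(a, b)  # two distinct, documented readings


class TestHOG:
    def test_descriptor_length_on_default_geometry(self, random_images):
        assert hog_feature_vector(random_images[0]).shape == (36,)
        assert HOGConfig().descriptor_length(64) == 36

    def test_constant_image_gives_zero_descriptor(self):
        assert np.allclose(hog_feature_vector(np.full((64, 64), 9, np.uint8)), 0)

    def test_vertical_step_edge_mass_in_horizontal_bin(self):
        img = np.zeros((64, 64), np.uint8)
        img[:, 32:] = 200
        hist = cell_histograms(img, HOGConfig())
        total = hist.sum(axis=(0, 1))
        assert total[0] == pytest.approx(total.sum())

    def test_intensity_shift_invariance(self, rng):
        a = rng.integers(30, 200, (64, 64)).astype(np.uint8)
        assert np.allclose(
            hog_feature_vector(a), hog_feature_vector((a + 20).astype(np.uint8))
        )

    def test_scale_invariance_up_to_block_normalization(self, rng):
        # with eps -> 0 the normalized blocks are scale-free
        base = rng.integers(0, 64, (64, 64)).astype(np.uint8)
        cfg = HOGConfig(eps=1e-12)
        a = hog_feature_vector(base, cfg)
        b = hog_feature_vector((base.astype(int) * 3).astype(np.uint8), cfg)
        assert np.allclose(a, b, atol=1e-6)

    def test_indivisible_cell_size_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            hog_feature_vector(np.zeros((60, 60), np.uint8))


class TestLBP:
    def test_bin_count_series(self):
        assert [lbp_bin_count(p) for p in range(7, 13)] == [45, 59, 75, 93, 113, 135]
        assert LBPConfig(8, 5).n_bins == 59

    def test_constant_window_gives_all_ones_code(self):
        assert lbp_code(np.full((11, 11), 5.0)) == 255  # H(0) = 1 inclusive

    def test_bright_center_gives_zero_code(self):
        w = np.zeros((11, 11))
        w[5, 5] = 255
        assert lbp_code(w) == 0

    def test_unit_radius_bit_ordering(self):
        # rightmost neighbor is bit 0, counter-clockwise afterwards
        w = np.zeros((3, 3))
        w[1, 1] = 15
        w[1, 2] = 20  # bit 0 (rightmost)
        assert lbp_code(w, LBPConfig(8, 1)) == 1
        w[0, 1] = 30  # bit 2 (top, two steps counter-clockwise)
        assert lbp_code(w, LBPConfig(8, 1)) == 0b101

    def test_histogram_normalized_with_59_bins(self, random_images):
        h = lbp_feature_vector(random_images[0])
        assert h.shape == (59,)
        assert h.sum() == pytest.approx(1.0)

    def test_constant_image_mass_in_all_ones_bin(self):
        h = lbp_feature_vector(np.full((64, 64), 7, np.uint8))
        assert h[_uniform_bin_map(8)[255]] == 1.0

    def test_monotone_invariance_exact_on_grid_aligned_sampling(self, rng):
        # p=4 samples land on integer pixels: invariance is exact for any
        # strictly increasing map
        img = rng.random((32, 32)) * 255
        cfg = LBPConfig(4, 3)
        for f in (lambda x: np.exp(x / 60), lambda x: x ** 3, lambda x: 5 * x - 40):
            assert np.allclose(
                lbp_feature_vector(img, cfg), lbp_feature_vector(f(img), cfg)
            )

    def test_affine_invariance_at_default_config(self, rng):
        # bilinear sampling commutes with affine maps, so invariance is exact
        img = rng.random((64, 64)) * 255
        assert np.allclose(
            lbp_feature_vector(img), lbp_feature_vector(2.5 * img + 7.0)
        )

    @given(st.integers(0, 2**31 - 1))
    def test_code_image_matches_per_pixel_codes(self, seed):
        img = np.random.default_rng(seed).integers(0, 256, (16, 16)).astype(np.uint8)
        cfg = LBPConfig(8, 2)
        codes = lbp_code_image(img, cfg)
        r = cfg.radius
        for rr, cc in [(0, 0), (3, 5), (11, 11)]:
            window = img[rr : rr + 2 * r + 1, cc : cc + 2 * r + 1].astype(float)
            assert codes[rr, cc] == lbp_code(window, cfg)

    def test_histogram_agrees_with_skimage_uniform_codes(self, rng):
        from skimage.feature import local_binary_pattern

        img = rng.integers(0, 256, (64, 64)).astype(np.uint8)
        cfg = LBPConfig(8, 1)
        mine = lbp_feature_vector(img, cfg)
        sk_codes = local_binary_pattern(img, 8, 1, method="nri_uniform")[1:-1, 1:-1]
        sk = np.bincount(sk_codes.astype(int).ravel(), minlength=59)
        sk = sk / sk.sum()
        # same non-uniform mass and same multiset of uniform-bin masses
        # (the two implementations order the 58 uniform codes differently)
        assert mine[58] == pytest.approx(sk[58])
        assert np.allclose(np.sort(mine[:58]), np.sort(sk[:58]))

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            lbp_feature_vector(np.zeros((8, 8), np.uint8), LBPConfig(8, 5))


def test_radiomic_vector_is_108_dimensional(random_images):
    v = radiomic_feature_vector(random_images[0])
    assert v.shape == (13 + 36 + 59,)
    assert np.all(np.isfinite(v))
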