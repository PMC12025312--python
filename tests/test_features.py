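import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.feature import graycomatrix, graycoprops

from choroidtex import (
    FEATURE_GROUPS,
    FEATURE_NAMES,
    GLCMSpec,
    compute_fos,
    compute_gabor_features,
    compute_glcm,
    compute_glcm_features,
    compute_lte_features,
    extract_all,
    feature_names,
)
from choroidtex.features import FeatureError

import oracles
from conftest import make_sample, random_roi_sample


class TestRegistry:
    def test_52_unique_names_partitioned_16_14_16_6(self):
        assert len(FEATURE_NAMES) == 52
        assert len(set(FEATURE_NAMES)) == 52
        sizes = {g: len(v) for g, v in FEATURE_GROUPS.items()}
        assert sizes == {"fos": 16, "glcm": 14, "gabor": 16, "lte": 6}

    def test_registry_contains_the_published_feature_names(self):
        for name in (
            "FOS_skewness",
            "FOS_mode",
            "GLCM_contrast_mean",
            "GLCM_difference_entropy_mean",
            "GABOR_a135_f0.1_std",
            "LTE_LE",
        ):
            assert name in FEATURE_NAMES

    def test_family_selection(self):
        assert feature_names(["gabor"]) == list(FEATURE_GROUPS["gabor"])
        with pytest.raises(KeyError):
            feature_names(["wavelet"])


class TestFOS:
    def test_constant_roi_degenerate_conventions(self):
        s = make_sample(np.full((8, 8), 7, dtype=np.uint8))
        f = compute_fos(s)
        assert f["FOS_mean"] == 7
        assert f["FOS_variance"] == 0
        assert f["FOS_entropy"] == 0
        assert f["FOS_energy"] == 1
        assert f["FOS_skewness"] == 0
        assert f["FOS_kurtosis"] == 0
        assert f["FOS_histogram_width"] == 0
        assert f["FOS_mode"] == 7

    def test_four_pixel_roi_forced_arithmetic(self):
        img = np.array([[1, 2], [3, 4]], dtype=np.uint8)
        f = compute_fos(make_sample(img))
        assert f["FOS_mean"] == 2.5
        assert f["FOS_median"] == 2.5
        assert f["FOS_min"] == 1
        assert f["FOS_max"] == 4

    def test_empty_mask_raises(self):
        with pytest.raises(FeatureError):
            compute_fos(make_sample(np.zeros((4, 4)), mask=np.zeros((4, 4), bool)))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_oracle_on_random_rois(self, seed):
        s = random_roi_sample(np.random.default_rng(seed), size=50)
        got = compute_fos(s)
        want = oracles.fos_oracle(s.roi_pixels)
        for name in want:
            assert got[name] == pytest.approx(want[name], rel=1e-10, abs=1e-12), name


class TestGLCM:
    def test_constant_image_single_cell(self):
        P = compute_glcm(make_sample(np.full((6, 6), 9, dtype=np.uint8)), angle=0)
        assert P.sum() == pytest.approx(1.0)
        assert P[0, 0] == pytest.approx(1.0)

    def test_checkerboard_two_levels_horizontal(self):
        img = np.indices((6, 6)).sum(axis=0) % 2 * 255
        P = compute_glcm(make_sample(img.astype(np.uint8)), GLCMSpec(levels=2), angle=0)
        assert P[0, 1] == pytest.approx(0.5)
        assert P[1, 0] == pytest.approx(0.5)
        assert P[0, 0] == P[1, 1] == 0

    @pytest.mark.parametrize("angle", [0, 45, 90, 135])
    def test_sums_to_one_and_symmetric(self, angle):
        s = random_roi_sample(np.random.default_rng(3), size=24)
        P = compute_glcm(s, angle=angle)
        assert P.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(P, P.T, atol=1e-15)

    @pytest.mark.parametrize("angle", [0, 45, 90, 135])
    def test_matrix_matches_pair_enumeration_oracle(self, angle):
        s = random_roi_sample(np.random.default_rng(11), size=16)
        P = compute_glcm(s, GLCMSpec(levels=8), angle=angle)
        want = oracles.glcm_oracle(s.image, s.mask, levels=8, angle=angle)
        np.testing.assert_allclose(P, want, atol=1e-12)

    def test_full_mask_matrix_matches_scikit_image(self):
        """Independent library cross-check on an unmasked image."""
        rng = np.random.default_rng(5)
        img = rng.integers(0, 8, size=(20, 20)).astype(np.uint8)
        s = make_sample(img)
        ours = compute_glcm(s, GLCMSpec(levels=8), angle=0)
        # quantization maps 0..7 to itself when levels=8 and ROI spans 0..7
        ski = graycomatrix(img, [1], [0], levels=8, symmetric=True, normed=True)[:, :, 0, 0]
        np.testing.assert_allclose(ours, ski, atol=1e-12)


class TestHaralick:
    def test_constant_image_degenerate_values(self):
        f = compute_glcm_features(make_sample(np.full((8, 8), 3, dtype=np.uint8)))
        assert f["GLCM_asm_mean"] == pytest.approx(1.0)
        assert f["GLCM_contrast_mean"] == pytest.approx(0.0)
        assert f["GLCM_entropy_mean"] == pytest.approx(0.0)
        assert f["GLCM_idm_mean"] == pytest.approx(1.0)
        assert f["GLCM_correlation_mean"] == 0.0  # zero-variance convention
        assert f["GLCM_imc1_mean"] == 0.0

    def test_checkerboard_hand_computed_2x2_matrix(self):
        # 0 deg matrix is [[0,.5],[.5,0]]: contrast 1, ASM 0.5, entropy 1 bit
        img = (np.indices((8, 8)).sum(axis=0) % 2 * 255).astype(np.uint8)
        spec = GLCMSpec(levels=2, angles=(0,))
        f = compute_glcm_features(make_sample(img), spec)
        assert f["GLCM_contrast_mean"] == pytest.approx(1.0)
        assert f["GLCM_asm_mean"] == pytest.approx(0.5)
        assert f["GLCM_entropy_mean"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_literal_formula_oracle(self, seed):
        s = random_roi_sample(np.random.default_rng(seed + 100), size=32)
        got = compute_glcm_features(s, GLCMSpec(levels=8))
        per_dir = [
            oracles.haralick_oracle(oracles.glcm_oracle(s.image, s.mask, 8, a))
            for a in (0, 45, 90, 135)
        ]
        for stat in per_dir[0]:
            want = np.mean([d[stat] for d in per_dir])
            assert got[f"GLCM_{stat}_mean"] == pytest.approx(want, abs=1e-8), stat

    def test_contrast_matches_scikit_image_on_full_mask(self):
        rng = np.random.default_rng(8)
        img = rng.integers(0, 32, size=(24, 24)).astype(np.uint8)
        img[0, 0], img[0, 1] = 0, 31  # pin the ROI range to 0..31
        f = compute_glcm_features(make_sample(img), GLCMSpec(levels=32, angles=(0,)))
        ski = graycomatrix(img, [1], [0], levels=32, symmetric=True, normed=True)
        assert f["GLCM_contrast_mean"] == pytest.approx(
            graycoprops(ski, "contrast")[0, 0], rel=1e-10
        )
        assert f["GLCM_asm_mean"] == pytest.approx(graycoprops(ski, "ASM")[0, 0], rel=1e-10)

    def test_bounds_invariants(self):
        s = random_roi_sample(np.random.default_rng(42), size=32)
        f = compute_glcm_features(s)
        assert 0.0 <= f["GLCM_mcc_mean"] <= 1.0
        assert 0.0 < f["GLCM_asm_mean"] <= 1.0
        assert f["GLCM_entropy_mean"] >= 0.0
        assert f["GLCM_sum_entropy_mean"] >= 0.0
        assert f["GLCM_difference_entropy_mean"] >= 0.0


class TestGabor:
    def test_constant_image_zero_response(self):
        f = compute_gabor_features(make_sample(np.full((32, 32), 128, dtype=np.uint8)))
        for name, v in f.items():
            assert abs(v) < 1e-6, name

    def test_rescaling_maps_255_to_half(self):
        # the working image is (x/255 - 0.5): extremes map to +-0.5
        assert 255 / 255.0 - 0.5 == 0.5
        assert 0 / 255.0 - 0.5 == -0.5

    def test_orientation_selectivity(self):
        """A 0.1 cycles/px vertical-stripe grating excites the matched filter."""
        cols = np.arange(64)
        img = (127.5 + 120 * np.sin(2 * np.pi * 0.1 * cols))[None, :].repeat(64, axis=0)
        s = make_sample(img.astype(np.uint8))
        f = compute_gabor_features(s)
        assert f["GABOR_a0_f0.1_mean"] > f["GABOR_a90_f0.1_mean"]
        assert f["GABOR_a0_f0.1_mean"] > f["GABOR_a0_f0.4_mean"]

    def test_frequency_selectivity(self):
        cols = np.arange(64)
        img = (127.5 + 120 * np.sin(2 * np.pi * 0.4 * cols))[None, :].repeat(64, axis=0)
        f = compute_gabor_features(make_sample(img.astype(np.uint8)))
        assert f["GABOR_a0_f0.4_mean"] > f["GABOR_a0_f0.1_mean"]

    def test_tiny_image_padding_does_not_crash(self):
        # image far smaller than the 0.1 cycles/px filter support
        s = make_sample(np.random.default_rng(0).integers(0, 255, (4, 6)).astype(np.uint8))
        f = compute_gabor_features(s)
        assert all(np.isfinite(v) for v in f.values())


class TestLTE:
    def test_constant_image_has_zero_fluctuation_energy(self):
        f = compute_lte_features(make_sample(np.full((9, 9), 50, dtype=np.uint8)))
        for name in ("LTE_LL", "LTE_LE", "LTE_LS", "LTE_EE", "LTE_ES", "LTE_SS"):
            assert f[name] == pytest.approx(0.0, abs=1e-12)

    def test_transpose_symmetry_of_averaged_pairs(self):
        rng = np.random.default_rng(2)
        img = rng.integers(0, 255, size=(16, 16)).astype(np.uint8)
        f1 = compute_lte_features(make_sample(img))
        f2 = compute_lte_features(make_sample(img.T.copy()))
        for name in ("LTE_LL", "LTE_LE", "LTE_LS", "LTE_EE", "LTE_ES", "LTE_SS"):
            assert f1[name] == pytest.approx(f2[name], rel=1e-10), name

    def test_vertical_edge_excites_only_l_row_kernels(self):
        """A column-only-varying image: zero-sum vertical vectors (E3, S3) kill
        every pair except LE/LS/LL, which must fire on the edge."""
        img = np.zeros((12, 12), dtype=np.uint8)
        img[:, 6:] = 200  # vertical step edge
        s = make_sample(img)
        f = compute_lte_features(s)
        assert f["LTE_LE"] > 0 and f["LTE_LS"] > 0
        assert f["LTE_EE"] == pytest.approx(0.0, abs=1e-12)
        assert f["LTE_ES"] == pytest.approx(0.0, abs=1e-12)
        centred = img.astype(float) - img.astype(float).mean()
        ll = oracles.laws_energy_oracle(centred, s.mask, "L", "L")
        le = (
            oracles.laws_energy_oracle(centred, s.mask, "L", "E")
            + oracles.laws_energy_oracle(centred, s.mask, "E", "L")
        ) / 2.0
        assert f["LTE_LE"] == pytest.approx(le / ll, abs=1e-8)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_direct_correlation_oracle(self, seed):
        s = random_roi_sample(np.random.default_rng(seed + 50), size=14)
        f = compute_lte_features(s)
        centred = s.image.astype(float) - s.roi_pixels.mean()
        ll = oracles.laws_energy_oracle(centred, s.mask, "L", "L")
        assert f["LTE_LL"] == pytest.approx(ll, abs=1e-8)
        for name, (u, v) in [("LTE_LE", "LE"), ("LTE_LS", "LS"), ("LTE_ES", "ES")]:
            want = (
                oracles.laws_energy_oracle(centred, s.mask, u, v)
                + oracles.laws_energy_oracle(centred, s.mask, v, u)
            ) / 2.0
            assert f[name] == pytest.approx(want / ll, abs=1e-8), name


class TestPropertyInvariants:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_glcm_is_a_distribution_and_fos_is_order_consistent(self, seed):
        """For arbitrary masked ROIs: the GLCM is symmetric and sums to 1,
        and FOS order statistics respect min <= p10 <= median <= p90 <= max."""
        s = random_roi_sample(np.random.default_rng(seed), size=16)
        P = compute_glcm(s, angle=0)
        assert P.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(P, P.T, atol=1e-15)
        f = compute_fos(s)
        assert (
            f["FOS_min"]
            <= f["FOS_p10"]
            <= f["FOS_median"]
            <= f["FOS_p90"]
            <= f["FOS_max"]
        )
        assert 0.0 < f["FOS_energy"] <= 1.0
        assert f["FOS_entropy"] >= 0.0


class TestExtractAll:
    def test_vector_has_52_finite_values_in_registry_order(self, tiny_cohort):
        fv = extract_all(tiny_cohort.eyes[0].horizontal_samples[0])
        assert list(fv.values) == list(FEATURE_NAMES)
        assert all(np.isfinite(v) for v in fv.values.values())

    def test_identical_inputs_give_identical_vectors(self):
        s1 = random_roi_sample(np.random.default_rng(77))
        s2 = make_sample(s1.image.copy(), s1.mask.copy())
        assert extract_all(s1).values == extract_all(s2).values

    def test_mask_sensitivity_far_pixels_do_not_matter(self):
        """Pixels outside the mask and beyond filter support change nothing."""
        rng = np.random.default_rng(4)
        img = rng.integers(60, 200, size=(80, 80)).astype(np.uint8)
        mask = np.zeros((80, 80), bool)
        mask[30:50, 30:50] = True
        a = extract_all(make_sample(img, mask))
        img2 = img.copy()
        img2[:2, :] = 255  # corner strip far from the ROI (support margin ~17 px)
        img2[-2:, :] = 0
        b = extract_all(make_sample(img2, mask))
        for name in FEATURE_NAMES:
            assert a.values[name] == pytest.approx(b.values[name], rel=1e-9, abs=1e-12), name

    def test_intensity_shift_behavior(self):
        """+c shifts location features by c and leaves spread/texture invariant."""
        rng = np.random.default_rng(9)
        img = rng.integers(40, 120, size=(40, 40)).astype(np.uint8)
        mask = np.ones((40, 40), bool)
        a = extract_all(make_sample(img))
        b = extract_all(make_sample((img + 30).astype(np.uint8)))
        for name in ("FOS_mean", "FOS_median", "FOS_p10", "FOS_p90", "FOS_min", "FOS_max", "FOS_mode"):
            assert b.values[name] == pytest.approx(a.values[name] + 30, abs=1e-9), name
        assert b.values["FOS_variance"] == pytest.approx(a.values["FOS_variance"], rel=1e-9)
        # GLCM quantizes over the ROI min-max, so a pure shift is invisible
        assert b.values["GLCM_contrast_mean"] == pytest.approx(
            a.values["GLCM_contrast_mean"], rel=1e-9
        )
        assert b.values["GLCM_difference_entropy_mean"] == pytest.approx(
            a.values["GLCM_difference_entropy_mean"], rel=1e-9
        )
        # LTE-normalized features are ratios of zero-sum kernel responses
        for name in ("LTE_EE", "LTE_ES", "LTE_SS"):
            assert b.values[name] == pytest.approx(a.values[name], rel=1e-6), name

    def test_family_restriction(self, tiny_cohort):
        fv = extract_all(tiny_cohort.eyes[0].horizontal_samples[0], groups=["gabor"])
        assert list(fv.values) == list(FEATURE_GROUPS["gabor"])
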