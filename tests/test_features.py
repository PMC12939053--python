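import numpy as np
import pytest
from skimage.draw import disk
from skimage.feature import graycomatrix, graycoprops

from mammocad import (
    FEATURE_NAMES,
    GrayImage,
    compute_glcm,
    extract_feature_vector,
    generate_mass_image,
    glcm_block,
    glcm_feature_set,
    histogram_feature_set,
    quantize,
    segment_mass_mask,
    shape_feature_set,
)
from mammocad.features import GLCM, SegmentationError
from mammocad.synthetic import benign_spec, malignant_spec


def gray(array, bit_depth=8):
    return GrayImage(np.asarray(array), bit_depth)


class TestQuantize:
    def test_endpoints(self):
        image = gray([[0, 255]])
        np.testing.assert_array_equal(quantize(image, 8), [[0, 7]])

    def test_midpoint_binning(self):
        assert quantize(gray([[128, 128]]), 8)[0, 0] == 4  # floor(128*8/256)

    def test_full_levels_is_identity(self):
        pixels = np.arange(256, dtype=np.uint8).reshape(16, 16)
        np.testing.assert_array_equal(quantize(gray(pixels), 256), pixels)

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            quantize(gray([[0]]), 1)


class TestComputeGLCM:
    def test_horizontal_pairs(self):
        g = compute_glcm(np.array([[0, 0], [1, 1]]), angle=0, levels=2)
        np.testing.assert_allclose(g.matrix, [[0.5, 0.0], [0.0, 0.5]])

    def test_vertical_pairs(self):
        g = compute_glcm(np.array([[0, 0], [1, 1]]), angle=90, levels=2)
        np.testing.assert_allclose(g.matrix, [[0.0, 0.5], [0.5, 0.0]])

    def test_entries_sum_to_one_and_symmetric(self, rng):
        quantized = rng.integers(0, 8, (20, 20))
        for angle in (0, 45, 90, 135):
            g = compute_glcm(quantized, angle, levels=8)
            assert g.matrix.sum() == pytest.approx(1.0, abs=1e-12)
            np.testing.assert_allclose(g.matrix, g.matrix.T)

    @pytest.mark.parametrize("angle,sk_angle_idx", [(0, 0), (45, 3), (90, 1), (135, 2)])
    def test_matches_skimage_symmetric(self, rng, angle, sk_angle_idx):
        """Independent oracle: skimage's GLCM at the corresponding offset.

        skimage labels angles by the (sin, cos) offset so its 45-degree
        matrix corresponds to the 135-degree up-left/down-right pair here
        and vice versa; symmetric accumulation makes opposite offsets equal.
        """
        quantized = rng.integers(0, 8, (15, 17)).astype(np.uint8)
        sk = graycomatrix(
            quantized, [1], [0, np.pi / 2, np.pi / 4, 3 * np.pi / 4],
            levels=8, symmetric=True, normed=True,
        )
        mine = compute_glcm(quantized, angle, levels=8).matrix
        np.testing.assert_allclose(mine, sk[:, :, 0, sk_angle_idx], atol=1e-12)


class TestGLCMFeatureSet:
    diag = GLCM(np.array([[0.5, 0.0], [0.0, 0.5]]), 2, 0, 1)
    flat = GLCM(np.full((2, 2), 0.25), 2, 0, 1)

    def test_diagonal_matrix_hand_values(self):
        f = glcm_feature_set(self.diag)
        assert f["energy"] == pytest.approx(0.5)
        assert f["entropy"] == pytest.approx(np.log(2))
        assert f["contrast"] == 0
        assert f["dissimilarity"] == 0
        assert f["maximum_probability"] == pytest.approx(0.5)
        assert f["homogeneity"] == pytest.approx(1.0)
        assert f["inverse_difference"] == pytest.approx(1.0)
        assert f["correlation"] == pytest.approx(1.0)  # perfectly coupled levels

    def test_uniform_matrix_hand_values(self):
        f = glcm_feature_set(self.flat)
        assert f["energy"] == pytest.approx(0.25)
        assert f["entropy"] == pytest.approx(np.log(4))
        assert f["contrast"] == pytest.approx(0.5)  # sum p (i-j)^2
        assert f["correlation"] == pytest.approx(0.0)  # independent levels

    def test_autocorrelation_uses_one_based_levels(self):
        # uniform 2x2: sum i*j/4 over i,j in {1,2} = (1+2+2+4)/4 = 2.25
        assert glcm_feature_set(self.flat)["autocorrelation"] == pytest.approx(2.25)

    def test_sum_statistics_hand_values(self):
        f = glcm_feature_set(self.flat)
        # p_{x+y}: k=2 -> .25, k=3 -> .5, k=4 -> .25 ; mean 3, variance 0.5
        assert f["sum_average"] == pytest.approx(3.0)
        assert f["sum_variance"] == pytest.approx(0.5)
        assert f["sum_entropy"] == pytest.approx(
            -(0.25 * np.log(0.25) * 2 + 0.5 * np.log(0.5))
        )

    def test_definitional_bounds_on_random_glcms(self, rng):
        for _ in range(10):
            m = rng.random((6, 6))
            m = (m + m.T) / (2 * m.sum())
            f = glcm_feature_set(GLCM(m, 6, 0, 1))
            assert f["maximum_probability"] == pytest.approx(m.max())
            assert 0 < f["energy"] <= 1
            assert f["entropy"] >= 0
            assert -1 <= f["correlation"] <= 1 + 1e-12
            assert 0 <= f["info_correlation_2"] <= 1

    def test_matches_skimage_graycoprops(self, rng):
        """Cross-check the stats skimage also implements, on random images."""
        quantized = rng.integers(0, 8, (12, 14)).astype(np.uint8)
        sk = graycomatrix(quantized, [1], [0], levels=8, symmetric=True, normed=True)
        f = glcm_feature_set(compute_glcm(quantized, 0, levels=8))
        for mine, theirs in [
            ("contrast", "contrast"),
            ("dissimilarity", "dissimilarity"),
            ("homogeneity", "homogeneity"),
            ("correlation", "correlation"),
        ]:
            assert f[mine] == pytest.approx(graycoprops(sk, theirs)[0, 0], abs=1e-10)
        assert f["energy"] == pytest.approx(graycoprops(sk, "ASM")[0, 0], abs=1e-10)

    def test_rejects_unnormalized_matrix(self):
        with pytest.raises(ValueError):
            glcm_feature_set(GLCM(np.ones((2, 2)), 2, 0, 1))


class TestGLCMBlock:
    def test_block_has_88_angle_suffixed_names(self, random_image):
        block = glcm_block(random_image)
        assert len(block) == 88
        assert list(block)[:4] == [
            "autocorrelation_a0", "autocorrelation_a45",
            "autocorrelation_a90", "autocorrelation_a135",
        ]

    def test_rotation_symmetric_image_matches_across_angles(self):
        # a symmetric cross pattern is invariant under 90-degree rotation
        pixels = np.zeros((9, 9), dtype=np.uint8)
        pixels[4, :] = 200
        pixels[:, 4] = 200
        block = glcm_block(gray(pixels))
        for stat in ("contrast", "energy", "entropy", "homogeneity"):
            assert block[f"{stat}_a0"] == pytest.approx(block[f"{stat}_a90"], abs=1e-9)
            assert block[f"{stat}_a45"] == pytest.approx(block[f"{stat}_a135"], abs=1e-9)

    def test_constant_image_degenerate_values(self):
        block = glcm_block(gray(np.full((8, 8), 42)))
        for angle in (0, 45, 90, 135):
            assert block[f"contrast_a{angle}"] == 0
            assert block[f"dissimilarity_a{angle}"] == 0
            assert block[f"energy_a{angle}"] == 1
            assert block[f"entropy_a{angle}"] == 0


class TestHistogramFeatures:
    def test_constant_image(self):
        f = histogram_feature_set(gray(np.full((5, 5), 9)))
        assert f["hist_variance"] == 0
        assert f["hist_energy"] == 1
        assert f["hist_entropy"] == 0
        assert f["hist_skewness"] == 0 and f["hist_kurtosis"] == 0

    def test_two_bin_moments(self):
        pixels = np.zeros((4, 4), dtype=np.uint8)
        pixels[:2] = 255
        f = histogram_feature_set(gray(pixels))
        assert f["hist_mean"] == pytest.approx(127.5)
        assert f["hist_skewness"] == pytest.approx(0, abs=1e-12)
        assert f["hist_energy"] == pytest.approx(0.5)
        assert f["hist_entropy"] == pytest.approx(np.log(2))

    def test_mirrored_histogram_symmetry(self, random_image):
        f = histogram_feature_set(random_image)
        mirrored = gray(255 - random_image.pixels)
        g = histogram_feature_set(mirrored)
        for name in ("hist_variance", "hist_energy", "hist_entropy"):
            assert f[name] == pytest.approx(g[name], rel=1e-12)
        assert f["hist_skewness"] == pytest.approx(-g["hist_skewness"], rel=1e-9)


class TestSegmentation:
    def test_bright_disk_recovered(self):
        pixels = np.full((60, 60), 30, dtype=np.uint8)
        rr, cc = disk((30, 30), 15)
        pixels[rr, cc] = 200
        mask = segment_mass_mask(gray(pixels))
        truth = np.pi * 15**2
        assert abs(mask.sum() - truth) / truth < 0.05

    def test_largest_component_wins(self):
        pixels = np.zeros((40, 80), dtype=np.uint8)
        rr, cc = disk((20, 20), 6)
        pixels[rr, cc] = 255
        rr, cc = disk((20, 60), 12)
        pixels[rr, cc] = 255
        mask = segment_mass_mask(gray(pixels))
        assert mask[20, 60] and not mask[20, 20]

    def test_interior_hole_filled(self):
        pixels = np.zeros((40, 40), dtype=np.uint8)
        rr, cc = disk((20, 20), 12)
        pixels[rr, cc] = 255
        rr, cc = disk((20, 20), 4)
        pixels[rr, cc] = 0
        mask = segment_mass_mask(gray(pixels))
        assert mask[20, 20]

    def test_constant_roi_flagged(self):
        with pytest.raises(SegmentationError):
            segment_mass_mask(gray(np.full((10, 10), 7)))


class TestShapeFeatures:
    def test_full_rectangle(self):
        mask = np.ones((8, 12), dtype=bool)
        f = shape_feature_set(mask)
        assert f["shape_extent"] == 1
        assert f["shape_solidity"] == 1
        assert f["shape_area"] == 96

    def test_disk_equiv_diameter_and_eccentricity(self):
        mask = np.zeros((60, 60), dtype=bool)
        rr, cc = disk((30, 30), 20)
        mask[rr, cc] = True
        f = shape_feature_set(mask)
        assert abs(f["shape_equiv_diameter"] - 40) / 40 < 0.02
        assert f["shape_eccentricity"] < 0.1

    def test_horizontal_line_orientation_zero(self):
        mask = np.zeros((5, 21), dtype=bool)
        mask[2, :] = True
        f = shape_feature_set(mask)
        assert f["shape_orientation"] == pytest.approx(0.0, abs=1e-9)
        assert f["shape_eccentricity"] > 0.99
        assert f["shape_minor_axis_length"] < 1.5

    def test_vertical_line_orientation_ninety(self):
        mask = np.zeros((21, 5), dtype=bool)
        mask[:, 2] = True
        assert shape_feature_set(mask)["shape_orientation"] == pytest.approx(90.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            shape_feature_set(np.zeros((4, 4), dtype=bool))


class TestExtractFeatureVector:
    def test_104_finite_named_values(self, phantom_features):
        assert phantom_features.feature_names == list(FEATURE_NAMES)
        assert np.isfinite(phantom_features.values).all()

    def test_deterministic(self):
        image, _ = generate_mass_image(benign_spec(seed=3))
        a = extract_feature_vector(image)
        b = extract_feature_vector(image)
        assert a == b

    def test_benign_more_solid_than_malignant(self):
        """Smooth elliptical phantoms out-solidify spiculated ones on average."""
        sol = {0: [], 1: []}
        for seed in range(25):
            for spec in (benign_spec(seed=seed), malignant_spec(seed=seed + 1000)):
                _, mask = generate_mass_image(spec)
                sol[spec.label].append(shape_feature_set(mask)["shape_solidity"])
        assert np.mean(sol[0]) > np.mean(sol[1])
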