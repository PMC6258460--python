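import numpy as np
import pytest

from hive.glcm import (GLCMExtractor, compute_glcm, haralick_properties,
                       quantize_levels)
from hive.records import ImageRecord

ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def brute_force_glcm(pixels, levels, distances, angles, symmetric, normed):
    """Independent oracle: exhaustive double loop over all ordered pairs."""
    q = quantize_levels(pixels, levels)
    n, m = q.shape
    out = np.zeros((levels, levels, len(distances), len(angles)))
    for di, d in enumerate(distances):
        for ai, angle in enumerate(angles):
            dr, dc = (v * d for v in ANGLE_OFFSETS[angle])
            for r in range(n):
                for c in range(m):
                    r2, c2 = r + dr, c + dc
                    if 0 <= r2 < n and 0 <= c2 < m:
                        out[q[r, c], q[r2, c2], di, ai] += 1
            if symmetric:
                out[:, :, di, ai] += out[:, :, di, ai].T.copy()
            total = out[:, :, di, ai].sum()
            if normed and total > 0:
                out[:, :, di, ai] /= total
    return out


class TestMatrix:
    def test_constant_image_is_point_mass(self):
        img = ImageRecord("c", np.full((6, 6), 0.5))
        glcm = compute_glcm(img, levels=8)
        level = quantize_levels(np.array([[0.5]]), 8)[0, 0]
        for ai in range(4):
            slice_ = glcm[:, :, 0, ai]
            assert slice_[level, level] == pytest.approx(1.0)
            assert slice_.sum() == pytest.approx(1.0)

    def test_two_by_two_example(self):
        img = ImageRecord("t", np.array([[0.0, 0.6], [0.0, 0.6]]))
        glcm = compute_glcm(img, levels=2, angles=(0,))
        slice_ = glcm[:, :, 0, 0]
        assert slice_[0, 1] == pytest.approx(0.5)
        assert slice_[1, 0] == pytest.approx(0.5)
        assert slice_[0, 0] == 0 and slice_[1, 1] == 0

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_pair_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        h, w = rng.integers(4, 17, size=2)
        pixels = rng.random((h, w))
        kwargs = dict(levels=8, distances=(1, 2), angles=(0, 45, 90, 135),
                      symmetric=bool(seed % 2), normed=True)
        ours = compute_glcm(ImageRecord("r", pixels), **kwargs)
        expected = brute_force_glcm(pixels, **kwargs)
        assert np.allclose(ours, expected, atol=1e-12)

    def test_matches_skimage_reference(self, rng):
        skimage_feature = pytest.importorskip("skimage.feature")
        pixels = rng.integers(0, 8, size=(12, 12))
        ours = compute_glcm(ImageRecord("r", pixels / 8.0 + 1e-9), levels=8,
                            symmetric=True, normed=True)
        # skimage's angle convention points +row along sin(theta) (downward);
        # negated angles reproduce this package's 90-deg-up convention
        ref = skimage_feature.graycomatrix(
            pixels.astype(np.uint8), distances=[1],
            angles=[0, -np.pi / 4, -np.pi / 2, -3 * np.pi / 4], levels=8,
            symmetric=True, normed=True)
        assert np.allclose(ours, ref, atol=1e-12)

    def test_normed_slices_sum_to_one(self, noise_image):
        glcm = compute_glcm(noise_image, levels=16)
        sums = glcm.sum(axis=(0, 1))
        assert np.allclose(sums, 1.0)

    def test_symmetric_slices_equal_transpose(self, noise_image):
        glcm = compute_glcm(noise_image, levels=16, symmetric=True)
        for di in range(glcm.shape[2]):
            for ai in range(glcm.shape[3]):
                s = glcm[:, :, di, ai]
                assert np.array_equal(s, s.T)

    def test_oversized_offset_gives_zero_slice(self):
        img = ImageRecord("tiny", np.array([[0.1, 0.9]]))
        glcm = compute_glcm(img, levels=4, distances=(5,), angles=(0,))
        assert glcm.sum() == 0


class TestHaralick:
    def test_constant_slice_degenerate_values(self):
        img = ImageRecord("c", np.full((6, 6), 0.5))
        glcm = compute_glcm(img, levels=8, angles=(0,))
        props = haralick_properties(glcm).reshape(6, 1, 1)[:, 0, 0]
        contrast, dissim, homog, energy, corr, asm = props
        assert contrast == 0 and dissim == 0
        assert homog == 1 and asm == 1 and energy == 1
        assert corr == 1  # degenerate zero-variance convention

    def test_two_by_two_arithmetic(self):
        img = ImageRecord("t", np.array([[0.0, 0.6], [0.0, 0.6]]))
        glcm = compute_glcm(img, levels=2, angles=(0,))
        ext = GLCMExtractor(levels=2, angles=(0,))
        labels = ext.feature_labels((2, 2))
        values = dict(zip(labels, haralick_properties(glcm)))
        assert values["GLCM_contrast_d1_a0"] == pytest.approx(1.0)
        assert values["GLCM_dissimilarity_d1_a0"] == pytest.approx(1.0)
        assert values["GLCM_ASM_d1_a0"] == pytest.approx(0.5)
        assert values["GLCM_energy_d1_a0"] == pytest.approx(np.sqrt(0.5))

    def test_bounds_on_random_input(self, rng):
        pixels = rng.random((15, 15))
        glcm = compute_glcm(ImageRecord("r", pixels), levels=16)
        props = haralick_properties(glcm).reshape(6, 1, 4)
        homogeneity, asm = props[2], props[5]
        correlation = props[4]
        assert np.all((0 <= homogeneity) & (homogeneity <= 1))
        assert np.all((0 <= asm) & (asm <= 1))
        assert np.all((-1 - 1e-12 <= correlation) & (correlation <= 1 + 1e-12))

    def test_matches_skimage_properties(self, rng):
        skimage_feature = pytest.importorskip("skimage.feature")
        pixels = rng.integers(0, 8, size=(10, 10))
        glcm = compute_glcm(ImageRecord("r", pixels / 8.0 + 1e-9), levels=8)
        ours = haralick_properties(glcm).reshape(6, 1, 4)
        ref_glcm = skimage_feature.graycomatrix(
            pixels.astype(np.uint8), [1],
            [0, -np.pi / 4, -np.pi / 2, -3 * np.pi / 4], levels=8,
            symmetric=True, normed=True)
        for pk, prop in enumerate(("contrast", "dissimilarity", "homogeneity",
                                   "energy", "correlation", "ASM")):
            ref = skimage_feature.graycoprops(ref_glcm, prop)
            assert np.allclose(ours[pk], ref, atol=1e-10), prop

    def test_unknown_property_rejected(self, noise_image):
        glcm = compute_glcm(noise_image, levels=8)
        with pytest.raises(ValueError, match="unknown"):
            haralick_properties(glcm, ["entropy"])
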