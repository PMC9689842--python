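"""Patch decomposition, gradient maps and texture intensity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from patchnoise import (
    GradientKernels,
    decompose,
    gradient_maps,
    sigma_flat_direct,
    texture_intensity,
    texture_map,
    validate_image,
)
from patchnoise.patch_engine import texture_intensities

from conftest import eps_bruteforce


def ramp_patch(d=6):
    """p(i, j) = j: unit horizontal gradient everywhere."""
    return np.tile(np.arange(d, dtype=float), (d, 1))


class TestValidateImage:
    def test_rejects_non_finite(self):
        img = np.ones((8, 8))
        img[3, 3] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            validate_image(img)

    def test_rejects_wrong_ndim(self):
        with pytest.raises(ValueError):
            validate_image(np.ones((4, 4, 7)))

    def test_color_reduced_to_luma_with_warning(self):
        rgb = np.zeros((4, 4, 3))
        rgb[..., 1] = 100.0
        with pytest.warns(UserWarning, match="luminance"):
            gray = validate_image(rgb)
        assert gray.shape == (4, 4)
        assert np.allclose(gray, 58.7)


class TestDecompose:
    @pytest.mark.parametrize(
        "shape, d, expected_S",
        [((6, 6), 6, 1), ((8, 7), 6, 6), ((15, 11), 4, 12 * 8)],
    )
    def test_patch_count(self, shape, d, expected_S):
        ps = decompose(np.zeros(shape), d)
        # brute-force enumeration of window positions
        brute = sum(
            1
            for r in range(shape[0] - d + 1)
            for c in range(shape[1] - d + 1)
        )
        assert ps.S == expected_S == brute

    def test_exact_fit_patch_equals_image(self, rng):
        img = rng.uniform(0, 255, (6, 6))
        ps = decompose(img, 6)
        assert ps.S == 1
        np.testing.assert_array_equal(ps[0].values, img)

    def test_patches_are_image_windows_row_major(self, rng):
        img = rng.uniform(0, 255, (9, 8))
        ps = decompose(img, 4)
        for k, p in enumerate(ps):
            assert ps.coords(k) == (p.row, p.col)
            np.testing.assert_array_equal(
                p.values, img[p.row : p.row + 4, p.col : p.col + 4]
            )
        # row-major order of top-left corners
        coords = [ps.coords(k) for k in range(ps.S)]
        assert coords == sorted(coords)

    def test_large_flat_image_count_and_constancy(self):
        img = np.full((1024, 1024), 128.0)
        ps = decompose(img, 6)
        assert ps.S == 1_038_361
        assert np.all(ps.variances() == 0.0)
        assert np.all(ps.means() == 128.0)

    def test_too_small_image_raises(self):
        with pytest.raises(ValueError, match="smaller than the patch size"):
            decompose(np.zeros((4, 4)), 6)

    def test_non_finite_pixels_raise(self):
        img = np.ones((8, 8))
        img[0, 0] = np.inf
        with pytest.raises(ValueError):
            decompose(img, 4)

    def test_variances_are_unbiased_convention(self, rng):
        img = rng.normal(100, 10, (10, 10))
        ps = decompose(img, 6)
        expected = np.array([p.values.var(ddof=1) for p in ps])
        np.testing.assert_allclose(ps.variances(), expected, rtol=1e-10)


class TestGradientKernels:
    def test_non_zero_sum_rejected(self):
        with pytest.raises(ValueError, match="sum to zero"):
            GradientKernels(hh=np.array([[1.0, 1.0]]), hv=np.array([[1.0], [1.0]]))

    def test_hv_must_be_transpose(self):
        with pytest.raises(ValueError, match="transpose"):
            GradientKernels(hh=np.array([[-1.0, 1.0]]), hv=np.array([[-1.0, 1.0]]))

    def test_from_name(self):
        assert GradientKernels.from_name("diff").name == "diff"
        assert GradientKernels.from_name("sobel").hh.shape == (3, 3)
        with pytest.raises(ValueError):
            GradientKernels.from_name("scharr")


class TestGradientMaps:
    def test_constant_patch_zero_maps(self, diff_kernels):
        gh, gv = gradient_maps(np.full((6, 6), 128.0), diff_kernels)
        assert np.all(gh == 0) and np.all(gv == 0)

    def test_horizontal_ramp(self, diff_kernels):
        gh, gv = gradient_maps(ramp_patch(), diff_kernels)
        assert gh.shape == (6, 5) and gv.shape == (5, 6)
        np.testing.assert_array_equal(gh, np.ones((6, 5)))
        np.testing.assert_array_equal(gv, np.zeros((5, 6)))

    def test_linearity_in_patch(self, rng, diff_kernels):
        p = rng.uniform(0, 255, (6, 6))
        gh1, gv1 = gradient_maps(p, diff_kernels)
        gh2, gv2 = gradient_maps(2.0 * p, diff_kernels)
        np.testing.assert_array_equal(gh2, 2.0 * gh1)
        np.testing.assert_array_equal(gv2, 2.0 * gv1)

    def test_kernel_larger_than_patch(self):
        k = GradientKernels.sobel()
        with pytest.raises(ValueError, match="larger"):
            gradient_maps(np.zeros((2, 2)), k)


class TestTextureIntensity:
    def test_constant_patch_zero(self, diff_kernels):
        assert texture_intensity(np.full((6, 6), 77.0), diff_kernels) == 0.0

    def test_horizontal_ramp_is_thirty(self, diff_kernels):
        # 6x5 valid horizontal map of unit gradients, zero vertical
        assert texture_intensity(ramp_patch(), diff_kernels) == 30.0

    @given(
        patch=hnp.arrays(
            np.float64, (6, 6), elements=st.floats(-255, 255, width=32)
        ),
        alpha=st.floats(0.25, 8.0, width=16),
    )
    @settings(max_examples=30, deadline=None)
    def test_positive_homogeneity(self, patch, alpha):
        k = GradientKernels.first_difference()
        eps = texture_intensity(patch, k)
        assert texture_intensity(alpha * patch, k) == pytest.approx(
            alpha * eps, rel=1e-12, abs=1e-9
        )

    @pytest.mark.parametrize("kernels_name", ["diff", "sobel"])
    def test_bruteforce_oracle_on_random_patches(self, rng, kernels_name):
        kernels = GradientKernels.from_name(kernels_name)
        for _ in range(10):
            p = rng.uniform(0, 255, (6, 6))
            expected = eps_bruteforce(p, kernels)
            assert texture_intensity(p, kernels) == pytest.approx(expected, rel=1e-12)
            batch = texture_intensities(p[None], kernels)
            assert batch[0] == pytest.approx(expected, rel=1e-12)


class TestTextureMap:
    def test_matches_per_patch_intensity(self, rng, diff_kernels):
        img = rng.uniform(0, 255, (14, 12))
        tm = texture_map(img, 6, diff_kernels)
        ps = decompose(img, 6)
        expected = np.array([texture_intensity(p.values, diff_kernels) for p in ps])
        np.testing.assert_allclose(tm.eps, expected, rtol=1e-12)
        assert tm.S == ps.S
        assert np.all(tm.eps >= 0)

    def test_flat_noiseless_image_all_zero(self, diff_kernels):
        tm = texture_map(np.full((32, 32), 64.0), 6, diff_kernels)
        assert np.all(tm.eps == 0.0)

    def test_shift_invariance_exact(self, rng, diff_kernels):
        img = rng.integers(0, 200, (20, 20)).astype(float)
        tm1 = texture_map(img, 6, diff_kernels)
        tm2 = texture_map(img + 100.0, 6, diff_kernels)
        np.testing.assert_array_equal(tm1.eps_grid, tm2.eps_grid)

    def test_noise_doubling_doubles_map_exactly(self, rng, diff_kernels):
        n = rng.standard_normal((20, 20))
        tm1 = texture_map(10.0 * n, 6, diff_kernels)
        tm2 = texture_map(20.0 * n, 6, diff_kernels)
        np.testing.assert_array_equal(tm2.eps_grid, 2.0 * tm1.eps_grid)

    def test_sobel_path_matches_bruteforce(self, rng):
        kernels = GradientKernels.sobel()
        img = rng.uniform(0, 255, (10, 9))
        tm = texture_map(img, 6, kernels)
        ps = decompose(img, 6)
        expected = np.array([eps_bruteforce(p.values, kernels) for p in ps])
        np.testing.assert_allclose(tm.eps, expected, rtol=1e-12)


class TestSigmaFlatDirect:
    def test_constant_image_zero(self):
        assert sigma_flat_direct(np.full((8, 8), 42.0)) == 0.0

    def test_two_by_two_example(self):
        assert sigma_flat_direct(np.array([[0.0, 0.0], [10.0, 10.0]])) == 5.0

    def test_flat_plus_noise_recovers_sigma(self):
        rng = np.random.default_rng(7)
        img = 128.0 + 10.0 * rng.standard_normal((1024, 1024))
        assert abs(sigma_flat_direct(img) - 10.0) < 0.1
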