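import numpy as np
import pytest
from scipy import ndimage

from mribovw import (
    GrayImage,
    aos_step,
    build_nonlinear_scale_space,
    conductivity,
    dense_extract_nonlinear,
    estimate_contrast_k,
    nonlinear_descriptor_at,
)
from mribovw.errors import ParameterError, ScaleError


def dense_diffusion_matrix(cvec, tau):
    """Explicit (I - 2*tau*A) for one 1-D line with Neumann boundaries."""
    n = len(cvec)
    A = np.zeros((n, n))
    c_half = 0.5 * (cvec[:-1] + cvec[1:])
    for j in range(n - 1):
        A[j, j] -= c_half[j]
        A[j, j + 1] += c_half[j]
        A[j + 1, j + 1] -= c_half[j]
        A[j + 1, j] += c_half[j]
    return np.eye(n) - 2 * tau * A


class TestContrastK:
    def test_constant_image_floors_with_warning(self):
        img = GrayImage(np.full((64, 64), 0.5))
        with pytest.warns(UserWarning, match="constant"):
            assert estimate_contrast_k(img) == pytest.approx(1e-3)

    def test_matches_sort_based_percentile_oracle(self, textured_image):
        smoothed = ndimage.gaussian_filter(textured_image.pixels, 1.0, mode="nearest")
        gy, gx = np.gradient(smoothed)
        mag = np.sort(np.sqrt(gx**2 + gy**2).ravel())
        mag = mag[mag > 0]
        expected = np.percentile(mag, 70.0)
        assert estimate_contrast_k(img=textured_image) == pytest.approx(expected)


class TestConductivity:
    def test_unity_at_zero_gradient(self):
        assert conductivity(np.zeros((4, 4)), k=2.0) == pytest.approx(1.0)

    def test_half_at_contrast_point(self):
        k = 1.7
        assert conductivity(np.array([k**2]), k=k)[0] == pytest.approx(0.5)

    def test_strictly_decreasing_in_gradient(self):
        grads = np.linspace(0.0, 10.0, 100)
        c = conductivity(grads**2, k=2.0)
        assert np.all(np.diff(c) < 0)

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ParameterError):
            conductivity(np.zeros(3), k=0.0)


class TestAosStep:
    def test_constant_field_is_steady_state(self, rng):
        L = np.full((16, 16), 0.37)
        c = rng.random((16, 16))
        assert np.allclose(aos_step(L, c, tau=3.0), L, atol=1e-12)

    def test_mean_intensity_conserved(self, rng):
        L = rng.random((20, 20))
        c = rng.random((20, 20)) * 0.9 + 0.1
        out = aos_step(L, c, tau=5.0)
        assert out.mean() == pytest.approx(L.mean(), abs=1e-10)

    def test_matches_dense_linear_solve_on_8x8(self, rng):
        L = rng.random((8, 8))
        c = rng.random((8, 8)) * 0.9 + 0.1
        tau = 2.0
        rows = np.vstack(
            [np.linalg.solve(dense_diffusion_matrix(c[i], tau), L[i]) for i in range(8)]
        )
        cols = np.vstack(
            [np.linalg.solve(dense_diffusion_matrix(c[:, j], tau), L[:, j]) for j in range(8)]
        ).T
        expected = 0.5 * (rows + cols)
        assert np.allclose(aos_step(L, c, tau), expected, atol=1e-12)

    @pytest.mark.parametrize("tau", [0.5, 5.0, 50.0])
    def test_maximum_principle(self, tau, rng):
        L = rng.random((24, 24))
        c = rng.random((24, 24)) * 0.9 + 0.1
        out = aos_step(L, c, tau)
        assert np.abs(out).max() <= np.abs(L).max() + 1e-9

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(ParameterError):
            aos_step(np.zeros((4, 4)), np.ones((4, 4)), tau=0.0)


class TestScaleSpace:
    def test_four_levels_with_increasing_times(self, textured_image):
        ss = build_nonlinear_scale_space(textured_image, (16, 32, 48, 64))
        assert len(ss.levels) == 4
        assert all(t2 > t1 for t1, t2 in zip(ss.times, ss.times[1:]))

    def test_mean_preserved_across_levels(self, textured_image):
        ss = build_nonlinear_scale_space(textured_image, (16, 32, 48, 64))
        for level in ss.levels:
            assert level.mean() == pytest.approx(textured_image.pixels.mean(), abs=1e-8)

    def test_linear_limit_matches_gaussian_blur(self, textured_image):
        ss = build_nonlinear_scale_space(
            textured_image, (16, 32, 48, 64),
            conductivity_kind="constant", aos_substeps=25,
        )
        for level, t in zip(ss.levels, ss.times):
            # half-sample-symmetric reflection matches zero-flux Neumann
            ref = ndimage.gaussian_filter(
                textured_image.pixels, np.sqrt(2 * t), mode="reflect"
            )
            assert np.abs(level - ref).max() < 0.02

    def test_edge_preservation_beats_linear_blur(self, rng):
        px = np.full((96, 96), 0.2)
        px[:, 48:] = 0.8
        px += ndimage.gaussian_filter(rng.normal(0, 0.05, (96, 96)), 1.0)
        img = GrayImage(np.clip(px, 0, 1))
        ss = build_nonlinear_scale_space(img, (48,), aos_substeps=5)
        t = ss.times[0]
        linear = ndimage.gaussian_filter(img.pixels, np.sqrt(2 * t), mode="reflect")
        jump_nl = np.abs(ss.levels[0][:, 50].mean() - ss.levels[0][:, 45].mean())
        jump_lin = np.abs(linear[:, 50].mean() - linear[:, 45].mean())
        assert jump_nl >= 1.5 * jump_lin


class TestNonlinearDescriptor:
    def test_constant_region_zero_vector(self):
        img = GrayImage(np.full((96, 96), 0.5))
        ss = build_nonlinear_scale_space(img, (16,), contrast_k=1.0)
        d = nonlinear_descriptor_at(ss, (48, 48), 16)
        assert np.allclose(d.vector, 0.0)
        assert d.strength == 0.0

    def test_textured_patch_unit_norm(self, textured_image):
        ss = build_nonlinear_scale_space(textured_image, (16,))
        d = nonlinear_descriptor_at(ss, (48, 48), 16)
        assert np.linalg.norm(d.vector) == pytest.approx(1.0, abs=1e-9)

    def test_unknown_scale_rejected(self, textured_image):
        ss = build_nonlinear_scale_space(textured_image, (16,))
        with pytest.raises(ScaleError):
            nonlinear_descriptor_at(ss, (48, 48), 32)

    def test_assigned_mode_is_rotation_tolerant(self, rng):
        # oriented texture: stripes plus a blob, rotated by exactly 90 deg
        px = 0.5 + 0.2 * np.sin(np.arange(96)[None, :] / 3.0) * np.ones((96, 1))
        yy, xx = np.mgrid[0:96, 0:96]
        px += 0.25 * np.exp(-((yy - 40) ** 2 + (xx - 52) ** 2) / 40.0)
        px = np.clip(px + ndimage.gaussian_filter(rng.normal(0, 0.02, (96, 96)), 1), 0, 1)
        img = GrayImage(px)
        rot = GrayImage(np.rot90(px).copy())
        ss = build_nonlinear_scale_space(img, (32,))
        ss_rot = build_nonlinear_scale_space(rot, (32,))
        d = nonlinear_descriptor_at(ss, (48, 48), 32, orientation="assigned")
        d_rot = nonlinear_descriptor_at(ss_rot, (47, 48), 32, orientation="assigned")
        cos = float(d.vector @ d_rot.vector)
        assert cos > 0.9

    def test_noise_robustness(self, textured_image, rng):
        ss = build_nonlinear_scale_space(textured_image, (32,))
        clean = nonlinear_descriptor_at(ss, (48, 48), 32).vector
        noisy_px = np.clip(
            textured_image.pixels + rng.normal(0, 0.01, (96, 96)), 0, 1
        )
        ss_n = build_nonlinear_scale_space(GrayImage(noisy_px), (32,))
        noisy = nonlinear_descriptor_at(ss_n, (48, 48), 32).vector
        assert float(clean @ noisy) > 0.95


class TestDenseNonlinear:
    def test_count_single_scale(self, rng):
        img = GrayImage(rng.random((64, 64)))
        d = dense_extract_nonlinear(img, grid_step=8, scales=(16,))
        assert len(d) == 64

    def test_family_tag(self, rng):
        img = GrayImage(rng.random((64, 64)))
        d = dense_extract_nonlinear(img, grid_step=8, scales=(16,))
        assert d.family == "nonlinear"

    def test_matches_per_point_descriptor(self, textured_image):
        ss = build_nonlinear_scale_space(textured_image, (16, 32))
        d = dense_extract_nonlinear(
            textured_image, grid_step=8, scales=(16, 32), ss=ss
        )
        for i in [0, 50, 200]:
            single = nonlinear_descriptor_at(
                ss, tuple(d.positions[i]), int(d.scales[i])
            )
            assert np.allclose(d.matrix[i], single.vector, atol=1e-12)
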