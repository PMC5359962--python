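import numpy as np
import pytest

from fibsemquant import synthetic_data as sd
from fibsemquant.preprocess import (
    DriftTrace,
    apply_drift_correction,
    correct_view_angle,
    denoise_wiener,
    estimate_drift,
    lowpass,
)
from fibsemquant.stack_io import ImageStack, VoxelGeometry


def _stack(data, view_angle=0.0):
    g = VoxelGeometry(6.3, 6.3, 40.0, view_angle)
    return ImageStack(data=np.asarray(data, dtype=float), geometry=g)


class TestEstimateDrift:
    def test_identical_slices_zero_shift(self):
        rng = np.random.default_rng(0)
        img = rng.normal(0.5, 0.1, (48, 64))
        stack = _stack([img, img, img])
        trace = estimate_drift(stack)
        assert not trace.shifts.any()

    def test_known_translation_recovered(self):
        rng = np.random.default_rng(1)
        img = rng.normal(0.5, 0.1, (48, 64))
        shifted = np.roll(img, (3, -2), axis=(0, 1))
        trace = estimate_drift(_stack([img, shifted]))
        assert tuple(trace.shifts[1]) == (3, -2)

    def test_flat_slice_flagged_zero(self):
        rng = np.random.default_rng(2)
        img = rng.normal(0.5, 0.1, (32, 32))
        with pytest.warns(UserWarning):
            trace = estimate_drift(_stack([img, np.zeros_like(img)]))
        assert tuple(trace.shifts[1]) == (0, 0)
        assert trace.flat_flags[1]

    def test_single_slice_rejected(self):
        with pytest.raises(ValueError):
            estimate_drift(_stack([np.zeros((8, 8))]))

    def test_scripted_phantom_steps_within_one_pixel(self):
        """Per-slice pairwise steps match the drift script on content slices."""
        drift = sd.make_drift_script(36, max_step=2, seed=51)
        phantom = sd.generate_phantom(
            [(1, "in_plane")] * 10 + [(3, "random")] * 2,
            shape=(36, 200, 256),
            noise_sd=0.05,
            drift=drift,
            seed=1,
        )
        stack, _ = sd.render_stack(phantom)
        trace = estimate_drift(stack)
        steps_est = np.diff(trace.shifts, axis=0)
        steps_true = np.diff(drift, axis=0)
        # evaluate where the cell provides registerable content
        nz = stack.n_slices
        err = np.abs(steps_est - steps_true)[nz // 4 : 3 * nz // 4]
        assert err.max() <= 1


class TestApplyDriftCorrection:
    def test_zero_trace_is_identity(self):
        rng = np.random.default_rng(3)
        data = rng.normal(0.5, 0.1, (3, 24, 24))
        stack = _stack(data)
        trace = DriftTrace(np.zeros((3, 2), int), np.zeros(3, bool))
        out = apply_drift_correction(stack, trace)
        np.testing.assert_allclose(out.data, data)

    def test_correction_is_idempotent(self):
        rng = np.random.default_rng(4)
        img = rng.normal(0.5, 0.1, (48, 64))
        stack = _stack([img, np.roll(img, (4, 1), axis=(0, 1)), np.roll(img, (6, 3), axis=(0, 1))])
        corrected = apply_drift_correction(stack, estimate_drift(stack))
        residual = estimate_drift(corrected)
        assert not residual.shifts.any()

    def test_length_mismatch_raises(self):
        stack = _stack(np.zeros((3, 8, 8)))
        trace = DriftTrace(np.zeros((2, 2), int), np.zeros(2, bool))
        with pytest.raises(ValueError):
            apply_drift_correction(stack, trace)

    def test_scripted_phantom_corrected_matches_drift_free(self):
        drift = sd.make_drift_script(24, max_step=2, seed=9)
        kwargs = dict(shape=(24, 160, 192), noise_sd=0.0, texture_sd=0.04, seed=5)
        ph_drift = sd.generate_phantom([(1, "in_plane")] * 6, drift=drift, **kwargs)
        ph_still = sd.generate_phantom([(1, "in_plane")] * 6, **kwargs)
        stack_d, _ = sd.render_stack(ph_drift)
        stack_s, _ = sd.render_stack(ph_still)
        corrected = apply_drift_correction(
            stack_d, DriftTrace(drift, np.zeros(len(drift), bool))
        )
        # compare away from borders, where fill values differ
        a = corrected.data[:, 14:-14, 14:-14].ravel()
        b = stack_s.data[:, 14:-14, 14:-14].ravel()
        assert np.corrcoef(a, b)[0, 1] > 0.99


class TestCorrectViewAngle:
    def test_zero_angle_identity(self):
        data = np.random.default_rng(5).random((2, 20, 20))
        out = correct_view_angle(_stack(data, view_angle=0.0))
        np.testing.assert_allclose(out.data, data)

    def test_sixty_degrees_doubles_height(self):
        data = np.zeros((1, 50, 10))
        out = correct_view_angle(_stack(data, view_angle=60.0))
        assert out.data.shape[1] == 100
        assert out.geometry.view_angle == 0.0

    def test_52_degrees_stretch_factor(self):
        data = np.zeros((1, 100, 10))
        out = correct_view_angle(_stack(data, view_angle=52.0))
        assert out.data.shape[1] == round(100 / np.cos(np.deg2rad(52.0)))  # ~162

    def test_physical_height_preserved(self):
        # an object of h pixels at angle theta spans the same nm afterwards
        stack = _stack(np.zeros((1, 80, 10)), view_angle=52.0)
        before = 80 * stack.geometry.pixel_size_y
        out = correct_view_angle(stack)
        after = out.data.shape[1] * out.geometry.pixel_size_y
        assert after == pytest.approx(before, rel=1e-9)


class TestDenoiseWiener:
    def test_constant_image_unchanged(self):
        img = np.full((32, 32), 0.7)
        np.testing.assert_allclose(denoise_wiener(img, 5), img)

    def test_noise_variance_reduced_mean_preserved(self):
        rng = np.random.default_rng(6)
        img = 0.5 + rng.normal(0, 0.1, (64, 64))
        out = denoise_wiener(img, 5)
        assert (out - 0.5).std() < 0.1
        assert abs(out.mean() - img.mean()) / img.mean() < 0.01

    @pytest.mark.parametrize("window", [2, 1, 4])
    def test_invalid_window(self, window):
        with pytest.raises(ValueError):
            denoise_wiener(np.zeros((8, 8)), window)

    def test_window_larger_than_image(self):
        with pytest.raises(ValueError):
            denoise_wiener(np.zeros((4, 4)), 5)

    def test_phantom_contrast_ratio_preserved(self, singles_phantom):
        phantom, stack, truth = singles_phantom
        p = truth.particles.iloc[0]
        k = int(p.first_exposure_slice) + 1
        r = int(p.cy_nm / 6.3)
        c = int(p.cx_nm / 6.3)
        img = stack.data[k]
        out = denoise_wiener(img, 5)

        def contrast(im):
            particle = im[r - 1 : r + 2, c - 1 : c + 2].mean()
            matrix = im[r - 1 : r + 2, c + 25 : c + 28].mean()  # nearby matrix patch
            return particle / matrix

        assert abs(contrast(out) - contrast(img)) / contrast(img) < 0.10


class TestLowpass:
    def test_impulse_becomes_gaussian_kernel(self):
        img = np.zeros((41, 41))
        img[20, 20] = 1.0
        out = lowpass(img, 2.0)
        yy, xx = np.meshgrid(np.arange(41), np.arange(41), indexing="ij")
        kernel = np.exp(-((yy - 20) ** 2 + (xx - 20) ** 2) / (2 * 2.0**2))
        kernel /= kernel.sum()
        np.testing.assert_allclose(out, kernel, atol=2e-5)

    def test_zero_sigma_identity(self):
        img = np.random.default_rng(7).random((16, 16))
        np.testing.assert_array_equal(lowpass(img, 0), img)

    def test_energy_preserved(self):
        img = np.random.default_rng(8).random((64, 64))
        out = lowpass(img, 3.0)
        assert abs(out.sum() - img.sum()) / img.sum() < 0.01

    def test_bimodal_histogram_stays_otsu_separable(self, singles_phantom):
        from skimage.filters import threshold_otsu

        phantom, stack, _ = singles_phantom
        img = stack.data[phantom.shape[0] // 2]
        out = lowpass(img, 1.5)
        thr = threshold_otsu(out)
        lo, hi = out[out < thr], out[out >= thr]
        # resin and matrix classes remain well separated after filtering
        assert hi.mean() - lo.mean() > 4 * max(lo.std(), hi.std())
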