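"""MSE / PSNR / SSIM / CNR / profile-FWHM measurement suite."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tomodose.metrics import (
    ProfileMeasurement,
    RoiSpec,
    background_rois,
    cnr,
    extract_profile,
    fwhm,
    mse,
    mssim,
    psnr,
    ssim_map,
)


class TestMse:
    def test_identical_images(self, rng):
        a = rng.random((8, 8))
        assert mse(a, a) == 0.0

    def test_constant_offset(self, rng):
        a = rng.random((8, 8))
        assert mse(a, a + 0.1) == pytest.approx(0.01, abs=1e-12)

    def test_matches_double_loop(self, rng):
        a, b = rng.random((8, 8)), rng.random((8, 8))
        expected = sum(
            (a[i, j] - b[i, j]) ** 2 for i in range(8) for j in range(8)
        ) / 64.0
        assert mse(a, b) == pytest.approx(expected, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mse(np.zeros((2, 2)), np.zeros((3, 3)))


class TestPsnr:
    def test_twenty_db(self):
        a = np.zeros((4, 4))
        assert psnr(a, a + 0.1) == pytest.approx(20.0, abs=1e-9)

    def test_zero_db(self):
        a = np.zeros((4, 4))
        assert psnr(a, a + 1.0) == pytest.approx(0.0, abs=1e-9)

    def test_identical_is_infinite(self, rng):
        a = rng.random((4, 4))
        assert psnr(a, a) == float("inf")

    def test_decreases_with_noise(self, rng):
        a = rng.random((64, 64))
        values = [psnr(a, a + rng.normal(0, s, a.shape)) for s in (0.01, 0.03, 0.1)]
        assert values[0] > values[1] > values[2]


def _direct_ssim(a, b):
    """Windowed direct computation of the SSIM map (the textbook formula)."""
    from scipy.ndimage import correlate

    g = np.exp(-((np.arange(11) - 5) ** 2) / (2 * 1.5**2))
    w = np.outer(g, g)
    w /= w.sum()

    def win(x):
        return correlate(x, w, mode="nearest")

    c1, c2 = 0.01**2, 0.03**2
    mu_a, mu_b = win(a), win(b)
    va = win(a * a) - mu_a**2
    vb = win(b * b) - mu_b**2
    cov = win(a * b) - mu_a * mu_b
    return ((2 * mu_a * mu_b + c1) * (2 * cov + c2)) / (
        (mu_a**2 + mu_b**2 + c1) * (va + vb + c2)
    )


class TestSsim:
    def test_identical_images_unity(self, rng):
        a = rng.random((32, 32))
        assert mssim(a, a) == pytest.approx(1.0, abs=1e-9)

    def test_anticorrelated_matches_direct_formula(self, rng):
        a = rng.random((48, 48))
        b = 1.0 - a
        smap = ssim_map(a, b)
        direct = _direct_ssim(a, b)
        interior = (slice(8, -8), slice(8, -8))  # identical away from borders
        assert np.abs(smap[interior] - direct[interior]).max() < 1e-6
        assert smap.min() < 0  # negative structure possible

    def test_luminance_sensitivity(self, rng):
        a = rng.random((32, 32)) * 0.8
        assert mssim(a, a + 0.1) < 1.0

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            ssim_map(np.zeros((8, 8)), np.zeros((8, 8)))


class TestCnr:
    def _image_with_known_stats(self):
        img = np.full((64, 64), 0.5)
        img[::2, ::2] = 0.45
        img[1::2, 1::2] = 0.55  # background mean 0.5, nonzero std
        feature = RoiSpec((32.0, 32.0), 8, role="feature")
        img[feature.mask(img.shape)] = 0.6
        return img, feature

    def test_arithmetic(self):
        img, feature = self._image_with_known_stats()
        bgs = background_rois(feature, 16.0)
        bg_pix = np.concatenate([img[b.mask(img.shape)] for b in bgs])
        expected = (0.6 - bg_pix.mean()) / bg_pix.std()
        assert cnr(img, feature, bgs) == pytest.approx(expected, abs=1e-12)

    def test_feature_equals_background_is_near_zero(self, rng):
        img = rng.normal(0.5, 0.02, (64, 64))
        feature = RoiSpec((32.0, 32.0), 8)
        value = cnr(img, feature, background_rois(feature, 16.0))
        assert abs(value) < 0.5

    def test_offset_invariance_and_noise_scaling(self, rng):
        base = rng.normal(0.0, 0.02, (64, 64))
        img = 0.5 + base
        feature = RoiSpec((32.0, 32.0), 8)
        img[feature.mask(img.shape)] += 0.1
        bgs = background_rois(feature, 16.0)
        v1 = cnr(img, feature, bgs)
        assert cnr(img + 0.3, feature, bgs) == pytest.approx(v1, abs=1e-9)
        img2 = 0.5 + 2.0 * base
        img2[feature.mask(img2.shape)] += 0.1
        v2 = cnr(img2, feature, bgs)
        assert v2 == pytest.approx(v1 / 2.0, rel=0.15)

    def test_degenerate_background_rejected(self):
        img = np.full((64, 64), 0.5)
        feature = RoiSpec((32.0, 32.0), 8)
        with pytest.raises(ValueError, match="degenerate"):
            cnr(img, feature, background_rois(feature, 16.0))

    def test_requires_four_backgrounds(self, rng):
        img = rng.random((64, 64))
        feature = RoiSpec((32.0, 32.0), 8)
        with pytest.raises(ValueError, match="4 background"):
            cnr(img, feature, background_rois(feature, 16.0)[:3])

    def test_roi_outside_image_rejected(self):
        with pytest.raises(ValueError, match="inside"):
            RoiSpec((2.0, 2.0), 10).mask((64, 64))


class TestProfile:
    def test_single_line_profile(self, rng):
        img = rng.random((32, 32))
        p = extract_profile(img, (16, 16), "horizontal", sum_width=1, half_len_px=5)
        assert np.allclose(p.profile, img[16, 11:22])

    def test_four_line_sum_matches_loop(self, rng):
        img = rng.random((32, 32))
        p = extract_profile(img, (16, 16), "horizontal", sum_width=4, half_len_px=5)
        expected = sum(img[15 + k, 11:22] for k in range(4))  # rows 15..18
        assert np.allclose(p.profile, expected)

    def test_vertical_direction(self, rng):
        img = rng.random((32, 32))
        p = extract_profile(img, (16, 16), "vertical", sum_width=1, half_len_px=5)
        assert np.allclose(p.profile, img[11:22, 16])

    def test_symmetric_speck_gives_symmetric_profile(self):
        img = np.zeros((33, 33))
        y, x = np.ogrid[:33, :33]
        img += np.exp(-((y - 16) ** 2 + (x - 16) ** 2) / 8.0)
        p = extract_profile(img, (16, 16), "horizontal", sum_width=1, half_len_px=8)
        assert np.allclose(p.profile, p.profile[::-1], atol=1e-12)

    def test_window_exit_rejected(self, rng):
        with pytest.raises(ValueError, match="window"):
            extract_profile(rng.random((32, 32)), (2, 2), "horizontal", half_len_px=5)


class TestFwhm:
    def _measure(self, profile, pitch=1.0):
        return fwhm(ProfileMeasurement("horizontal", 1, np.asarray(profile), pitch, 0))

    def test_gaussian_closed_form(self):
        x = np.arange(-60, 61) * 0.02  # 0.02 mm sampling
        prof = np.exp(-(x**2) / (2 * 0.2**2))
        expected = 2.0 * np.sqrt(2.0 * np.log(2.0)) * 0.2
        assert self._measure(prof, 0.02) == pytest.approx(expected, rel=1e-3)

    def test_triangle_peak(self):
        w = 10
        prof = np.concatenate([np.zeros(20), np.linspace(0, 1, w + 1),
                               np.linspace(1, 0, w + 1)[1:], np.zeros(20)])
        assert self._measure(prof) == pytest.approx(w, rel=1e-9)

    def test_noisy_gaussian_mean_within_five_percent(self):
        x = np.arange(-40, 41) * 0.02
        clean = np.exp(-(x**2) / (2 * 0.2**2))
        expected = 2.0 * np.sqrt(2.0 * np.log(2.0)) * 0.2
        rng = np.random.default_rng(12345)
        values = []
        for _ in range(100):
            v = self._measure(clean + rng.normal(0, 0.02, clean.shape), 0.02)
            if v is not None:
                values.append(v)
        assert abs(np.mean(values) - expected) / expected < 0.05

    def test_mean_reduce_gives_identical_fwhm(self, rng):
        img = np.zeros((33, 41))
        y, x = np.ogrid[:33, :41]
        img += np.exp(-((y - 16) ** 2 + (x - 20) ** 2) / 4.0)
        a = extract_profile(img, (16, 20), "horizontal", sum_width=4, half_len_px=10)
        b = extract_profile(img, (16, 20), "horizontal", sum_width=4,
                            half_len_px=10, reduce="mean")
        assert fwhm(a) == pytest.approx(fwhm(b), abs=1e-12)

    def test_linear_baseline_handles_sloped_background(self):
        x = np.arange(-60, 61) * 0.02
        prof = np.exp(-(x**2) / (2 * 0.2**2)) + 0.3 * np.linspace(0, 1, len(x))
        expected = 2.0 * np.sqrt(2.0 * np.log(2.0)) * 0.2
        v = fwhm(ProfileMeasurement("horizontal", 1, prof, 0.02, 60),
                 baseline="linear")
        assert v == pytest.approx(expected, rel=0.05)

    def test_no_peak_reports_missing(self):
        assert self._measure(np.linspace(1, 0, 30)) is None
        assert self._measure(np.zeros(30)) is None

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(sigma=st.floats(0.1, 0.5), amp=st.floats(0.1, 5.0))
    def test_gaussian_family_closed_form(self, sigma, amp):
        x = np.arange(-80, 81) * 0.02
        prof = amp * np.exp(-(x**2) / (2 * sigma**2))
        expected = 2.0 * np.sqrt(2.0 * np.log(2.0)) * sigma
        assert self._measure(prof, 0.02) == pytest.approx(expected, rel=2e-2)
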