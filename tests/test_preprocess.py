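"""Binning, smoothing, normalization and augmentation contracts."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msicodec import preprocess as pp
from msicodec.types import BinnedImage


def make_raw(points, x=0, y=0):
    mz, inten = zip(*points)
    return pp.RawSpectrum(mz=np.array(mz), intensity=np.array(inten), x=x, y=y)


class TestBinToGrid:
    def test_rounding_to_first_decimal(self):
        raw = [make_raw([(500.04, 3.0), (500.06, 2.0)])]
        img = pp.bin_to_grid(raw, mz_range=(500.0, 500.1))
        assert np.allclose(img.mz_axis, [500.0, 500.1])
        assert np.allclose(img.intensities, [[3.0, 2.0]])

    def test_half_rounds_away_from_zero(self):
        raw = [make_raw([(500.05, 1.0)])]
        img = pp.bin_to_grid(raw, mz_range=(500.0, 500.1))
        assert np.allclose(img.intensities, [[0.0, 1.0]])

    def test_empty_spectrum_gives_zero_row(self):
        raw = [
            make_raw([(100.0, 1.0)], x=0),
            pp.RawSpectrum(mz=np.array([]), intensity=np.array([]), x=1, y=0),
        ]
        img = pp.bin_to_grid(raw, mz_range=(100.0, 100.2))
        assert img.intensities[1].sum() == 0.0

    def test_out_of_range_rejected(self):
        raw = [make_raw([(600.0, 1.0)])]
        with pytest.raises(ValueError, match="outside"):
            pp.bin_to_grid(raw, mz_range=(100.0, 200.0))

    @given(st.lists(
        st.tuples(st.floats(100.0, 110.0), st.floats(0.0, 1e4)),
        min_size=1, max_size=30,
    ))
    @settings(max_examples=50, deadline=None)
    def test_total_intensity_conserved(self, points):
        raw = [make_raw(points)]
        img = pp.bin_to_grid(raw, mz_range=(100.0, 110.0))
        assert img.intensities.sum() == pytest.approx(
            sum(v for _, v in points), rel=1e-12, abs=1e-12)


class TestGaussianSmooth:
    @pytest.fixture()
    def impulse_image(self):
        intensities = np.zeros((1, 41))
        intensities[0, 20] = 1.0
        return BinnedImage(
            width=1, height=1, pixel_coords=[[0, 0]],
            mz_axis=100.0 + np.arange(41) * 0.1, intensities=intensities,
        )

    def test_impulse_becomes_normalized_symmetric_hump(self, impulse_image):
        out = pp.gaussian_smooth(impulse_image, sigma=0.1)
        row = out.intensities[0]
        assert row.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(row, row[::-1], atol=1e-12)
        assert row.argmax() == 20

    def test_impulse_peak_height_matches_kernel_center(self, impulse_image):
        impulse_image.intensities[0, 20] = 10.0
        kernel = pp.gaussian_kernel(0.1, impulse_image.grid_step)
        out = pp.gaussian_smooth(impulse_image, sigma=0.1)
        assert out.intensities.max() == pytest.approx(10.0 * kernel.max(), rel=1e-9)

    def test_zero_spectrum_stays_zero(self, impulse_image):
        zero = impulse_image.with_intensities(np.zeros_like(impulse_image.intensities))
        out = pp.gaussian_smooth(zero)
        assert not out.intensities.any()

    def test_commutes_with_scalar_multiplication(self, impulse_image):
        rng = np.random.default_rng(0)
        img = impulse_image.with_intensities(rng.uniform(0, 5, size=(1, 41)))
        a = pp.gaussian_smooth(img.with_intensities(img.intensities * 3.0))
        b = pp.gaussian_smooth(img)
        assert np.allclose(a.intensities, 3.0 * b.intensities, rtol=1e-12)
        assert (pp.gaussian_smooth(img).intensities >= 0).all()

    def test_invalid_sigma(self, impulse_image):
        with pytest.raises(ValueError):
            pp.gaussian_smooth(impulse_image, sigma=0.0)


class TestNormalize:
    def test_global_max_scales_to_unit(self):
        intensities = np.array([[1.0, 50.0], [25.0, 0.0]])
        img = BinnedImage(width=2, height=1, pixel_coords=[[0, 0], [1, 0]],
                          mz_axis=[100.0, 100.1], intensities=intensities)
        out, scale = pp.normalize_intensities(img)
        assert out.intensities.max() == pytest.approx(1.0)
        assert scale.scale == pytest.approx(50.0)
        restored = out.intensities * scale.scale
        assert np.allclose(restored, intensities, rtol=1e-7)

    def test_none_is_identity(self):
        img = BinnedImage(width=1, height=1, pixel_coords=[[0, 0]],
                          mz_axis=[100.0], intensities=[[4.0]])
        out, scale = pp.normalize_intensities(img, method="none")
        assert scale.scale == 1.0
        assert np.array_equal(out.intensities, img.intensities)

    def test_all_zero_rejected(self):
        img = BinnedImage(width=1, height=1, pixel_coords=[[0, 0]],
                          mz_axis=[100.0], intensities=[[0.0]])
        with pytest.raises(ValueError):
            pp.normalize_intensities(img)


class TestAugment:
    def test_delta_zero_is_identity(self):
        spec = np.array([0.0, 1.0, 5.0])
        assert np.array_equal(pp.augment(spec, delta=0.0, rng=1), spec)

    def test_bounds_and_zeros(self):
        rng = np.random.default_rng(0)
        spec = rng.uniform(0, 10, size=200)
        spec[::5] = 0.0
        out = pp.augment(spec, delta=0.1, rng=2)
        nz = spec > 0
        ratio = out[nz] / spec[nz]
        assert (ratio >= 0.9).all() and (ratio <= 1.1).all()
        assert (out[~nz] == 0.0).all()

    def test_seed_determinism(self):
        spec = np.arange(1.0, 11.0)
        a = pp.augment(spec, rng=42)
        b = pp.augment(spec, rng=42)
        c = pp.augment(spec, rng=43)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_mean_is_unbiased(self):
        # E[augmented] = original under uniform multiplicative noise
        spec = np.array([2.0, 8.0])
        acc = np.zeros_like(spec)
        n = 4000
        for s in range(n):
            acc += pp.augment(spec, delta=0.1, rng=s)
        assert np.allclose(acc / n, spec, rtol=5e-3)

    def test_negative_delta_rejected(self):
        with pytest.raises(ValueError):
            pp.augment(np.ones(3), delta=-0.1)


class TestMakeBatch:
    def test_minimal_batch(self, small_image):
        batch = pp.make_batch(small_image, [0], rng=0)
        assert batch.spectra.shape == (2, small_image.n_bins)
        assert list(batch.pair_index) == [1, 0]
        assert np.array_equal(batch.spectra[0], small_image.intensities[0])

    def test_published_batch_size(self, small_image):
        batch = pp.make_batch(small_image, range(64), rng=0)
        assert batch.n == 64
        assert batch.spectra.shape[0] == 128

    def test_involution_and_noise_bound(self, small_image):
        rng = np.random.default_rng(0)
        idx = rng.choice(small_image.n_pixels, size=9, replace=False)
        batch = pp.make_batch(small_image, idx, delta=0.1, rng=1)
        p = batch.pair_index
        assert np.array_equal(p[p], np.arange(len(p)))
        assert (p != np.arange(len(p))).all()
        originals = batch.spectra[0::2]
        copies = batch.spectra[1::2]
        nz = originals > 0
        ratio = copies[nz] / originals[nz]
        assert (ratio >= 0.9).all() and (ratio <= 1.1).all()

    def test_duplicate_indices_rejected(self, small_image):
        with pytest.raises(ValueError):
            pp.make_batch(small_image, [0, 0], rng=0)
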