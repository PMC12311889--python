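"""From raw profile spectra to the fixed-length vectors the codec consumes.

The pipeline is: aggregate each pixel's raw (m/z, intensity) points onto a
uniform 0.1-Da grid by rounding m/z to the first decimal, smooth each binned
spectrum with a Gaussian convolution (sigma = 0.1 Da by default), scale
intensities into [0, 1] by the dataset-wide maximum, and — during training —
produce noisy "augmentation" copies whose intensities are independently
perturbed by up to 10% while peak locations stay fixed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.ndimage import convolve1d

from .types import AugmentedBatch, BinnedImage

__all__ = [
    "RawSpectrum",
    "NormalizationScale",
    "bin_to_grid",
    "gaussian_smooth",
    "normalize_intensities",
    "augment",
    "make_batch",
]


@dataclass
class RawSpectrum:
    """One pixel's unbinned profile spectrum with its 0-based grid position."""

    mz: np.ndarray
    intensity: np.ndarray
    x: int
    y: int


@dataclass(frozen=True)
class NormalizationScale:
    """Record of the intensity scaling applied before encoding.

    ``scale`` is the divisor: original units are restored by multiplying
    decoded intensities by it.
    """

    method: str = "global_max"
    scale: float = 1.0


def _round_half_away(x: np.ndarray) -> np.ndarray:
    # numpy's round() rounds half to even; binning uses half away from zero
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def bin_to_grid(
    spectra: Sequence[RawSpectrum],
    mz_range: Optional[tuple[float, float]] = None,
    grid_step: float = 0.1,
    width: Optional[int] = None,
    height: Optional[int] = None,
) -> BinnedImage:
    """Aggregate raw points onto a uniform m/z grid by rounding to bin centers.

    Each raw point's intensity is added to the bin whose center is its m/z
    rounded to the grid (ties rounded away from zero), so total intensity is
    conserved exactly per pixel.  ``mz_range`` declares the global axis range
    shared by all pixels; by default it is taken from the data.
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    spectra = list(spectra)
    if not spectra:
        raise ValueError("no spectra to bin")
    if mz_range is None:
        lo = min(float(s.mz.min()) for s in spectra if len(s.mz))
        hi = max(float(s.mz.max()) for s in spectra if len(s.mz))
        mz_range = (lo, hi)
    lo_idx = int(_round_half_away(np.array(mz_range[0] / grid_step)))
    hi_idx = int(_round_half_away(np.array(mz_range[1] / grid_step)))
    n_bins = hi_idx - lo_idx + 1
    mz_axis = (np.arange(lo_idx, hi_idx + 1)) * grid_step

    coords = np.array([(s.x, s.y) for s in spectra], dtype=np.int64)
    if width is None:
        width = int(coords[:, 0].max()) + 1
    if height is None:
        height = int(coords[:, 1].max()) + 1

    intensities = np.zeros((len(spectra), n_bins))
    for row, s in enumerate(spectra):
        if len(s.mz) == 0:
            continue  # empty spectrum -> all-zero row
        idx = _round_half_away(np.asarray(s.mz, dtype=np.float64) / grid_step).astype(np.int64)
        if idx.min() < lo_idx or idx.max() > hi_idx:
            raise ValueError(
                f"pixel ({s.x}, {s.y}) has m/z outside the declared range {mz_range}"
            )
        np.add.at(intensities[row], idx - lo_idx, np.asarray(s.intensity, dtype=np.float64))
    return BinnedImage(width=width, height=height, pixel_coords=coords,
                       mz_axis=mz_axis, intensities=intensities)


def gaussian_kernel(sigma: float, grid_step: float) -> np.ndarray:
    """Discrete Gaussian sampled on the bin grid, truncated at 4 sigma and
    renormalized to sum one (so convolution conserves interior intensity)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    half = max(1, int(np.ceil(4.0 * sigma / grid_step)))
    offsets = np.arange(-half, half + 1) * grid_step
    kernel = np.exp(-0.5 * (offsets / sigma) ** 2)
    return kernel / kernel.sum()


def gaussian_smooth(image: BinnedImage, sigma: float = 0.1) -> BinnedImage:
    """Convolve every pixel spectrum with a normalized Gaussian kernel."""
    kernel = gaussian_kernel(sigma, image.grid_step)
    smoothed = convolve1d(image.intensities, kernel, axis=1, mode="constant", cval=0.0)
    # convolution of nonnegative data with a nonnegative kernel; clip the
    # odd -1e-17 produced by floating point cancellation
    np.clip(smoothed, 0.0, None, out=smoothed)
    return image.with_intensities(smoothed)


def normalize_intensities(
    image: BinnedImage, method: str = "global_max"
) -> tuple[BinnedImage, NormalizationScale]:
    """Scale intensities into [0, 1] by the dataset-wide maximum.

    Returns the scaled image and the scale record needed to restore original
    units after decoding.  ``method="none"`` is the identity.
    """
    if image.n_pixels == 0:
        raise ValueError("cannot normalize an empty image")
    if method == "none":
        return image.with_intensities(image.intensities), NormalizationScale("none", 1.0)
    if method != "global_max":
        raise ValueError(f"unknown normalization method {method!r}")
    peak = float(image.intensities.max())
    if peak == 0.0:
        raise ValueError("cannot global-max normalize an all-zero image")
    return (
        image.with_intensities(image.intensities / peak),
        NormalizationScale("global_max", peak),
    )


def augment(
    spectrum: np.ndarray,
    delta: float = 0.1,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Noisy copy: each bin scaled by an independent uniform factor in
    [1 - delta, 1 + delta].  Peak positions (and zeros) are untouched, so the
    overall spectral structure is preserved."""
    if delta < 0 or delta >= 1:
        raise ValueError("delta must lie in [0, 1)")
    rng = np.random.default_rng(rng)
    spectrum = np.asarray(spectrum, dtype=np.float64)
    factors = rng.uniform(1.0 - delta, 1.0 + delta, size=spectrum.shape)
    return spectrum * factors


def make_batch(
    image: BinnedImage,
    pixel_indices: Iterable[int],
    delta: float = 0.1,
    rng: np.random.Generator | int | None = None,
) -> AugmentedBatch:
    """Build a contrastive batch of 2N rows interleaving each selected pixel's
    spectrum with one augmentation of it."""
    indices = np.asarray(list(pixel_indices), dtype=np.int64)
    if len(indices) == 0:
        raise ValueError("batch needs at least one pixel")
    if len(np.unique(indices)) != len(indices):
        raise ValueError("duplicate pixel indices in batch")
    if indices.min() < 0 or indices.max() >= image.n_pixels:
        raise ValueError("pixel index out of range")
    rng = np.random.default_rng(rng)
    n = len(indices)
    f_s = image.n_bins
    spectra = np.empty((2 * n, f_s))
    originals = image.intensities[indices]
    spectra[0::2] = originals
    spectra[1::2] = originals * rng.uniform(1.0 - delta, 1.0 + delta, size=originals.shape)
    pair_index = np.arange(2 * n)
    pair_index[0::2] += 1
    pair_index[1::2] -= 1
    return AugmentedBatch(spectra=spectra, pair_index=pair_index, n=n)
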