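"""Core in-memory containers for mass spectrometry images and their embeddings.

A mass spectrometry image (MSI) is a pixel grid where every occupied pixel
carries a full mass spectrum.  After binning to a uniform m/z grid the image
becomes a dense matrix of shape ``(n_pixels, n_bins)`` plus the pixel
coordinates, which is what :class:`BinnedImage` stores.  Not every grid cell
has to be occupied: biopsy sections are irregularly shaped, so pixels are kept
as an explicit coordinate list rather than a full rectangle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Sentinel for pixels without a class assignment in a :class:`LabelMap`.
UNLABELED = -1


def _check_coords(pixel_coords: np.ndarray, width: int, height: int) -> np.ndarray:
    coords = np.asarray(pixel_coords, dtype=np.int64)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError(f"pixel_coords must be (n, 2), got {coords.shape}")
    if coords.size:
        if coords[:, 0].min() < 0 or coords[:, 0].max() >= width:
            raise ValueError("pixel x coordinate out of [0, width)")
        if coords[:, 1].min() < 0 or coords[:, 1].max() >= height:
            raise ValueError("pixel y coordinate out of [0, height)")
        if len(np.unique(coords, axis=0)) != len(coords):
            raise ValueError("pixel coordinates must be unique")
    return coords


@dataclass
class BinnedImage:
    """Pixel grid with a shared m/z bin axis and one intensity row per pixel.

    Parameters
    ----------
    width, height
        Grid extent in pixels.  ``0 <= x < width`` and ``0 <= y < height``.
    pixel_coords
        Integer array of shape ``(n_pixels, 2)`` holding ``(x, y)`` positions;
        x indexes the column, y the row.  Cells absent from this list are
        unmeasured, not zero.
    mz_axis
        Strictly increasing, uniformly spaced bin centers in daltons.
    intensities
        Nonnegative float matrix ``(n_pixels, len(mz_axis))``.
    """

    width: int
    height: int
    pixel_coords: np.ndarray
    mz_axis: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.pixel_coords = _check_coords(self.pixel_coords, self.width, self.height)
        self.mz_axis = np.asarray(self.mz_axis, dtype=np.float64)
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.mz_axis.ndim != 1:
            raise ValueError("mz_axis must be one-dimensional")
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be a 2-D matrix")
        if self.intensities.shape != (len(self.pixel_coords), len(self.mz_axis)):
            raise ValueError(
                f"intensities shape {self.intensities.shape} does not match "
                f"{len(self.pixel_coords)} pixels x {len(self.mz_axis)} bins"
            )
        if len(self.mz_axis) > 1:
            steps = np.diff(self.mz_axis)
            if steps.min() <= 0:
                raise ValueError("mz_axis must be strictly increasing")
            if not np.allclose(steps, steps[0], rtol=1e-9, atol=0.0):
                raise ValueError("mz_axis must be uniformly spaced")
        if not np.isfinite(self.intensities).all():
            raise ValueError("intensities contain non-finite values")
        if self.intensities.size and self.intensities.min() < 0:
            raise ValueError("intensities must be nonnegative")

    @property
    def n_pixels(self) -> int:
        return len(self.pixel_coords)

    @property
    def n_bins(self) -> int:
        """Length of the spectral axis (the sample vector length F_s)."""
        return len(self.mz_axis)

    @property
    def grid_step(self) -> float:
        if len(self.mz_axis) < 2:
            raise ValueError("grid step undefined for fewer than two bins")
        return float(self.mz_axis[1] - self.mz_axis[0])

    def raster_order(self) -> np.ndarray:
        """Permutation putting pixels in raster order (y-major, then x)."""
        return np.lexsort((self.pixel_coords[:, 0], self.pixel_coords[:, 1]))

    def with_intensities(self, intensities: np.ndarray) -> "BinnedImage":
        """Copy of this image with a replaced intensity matrix."""
        return BinnedImage(
            width=self.width,
            height=self.height,
            pixel_coords=self.pixel_coords.copy(),
            mz_axis=self.mz_axis.copy(),
            intensities=np.asarray(intensities),
        )


@dataclass
class EmbeddingStore:
    """Per-pixel embedding vectors produced by a trained codec.

    Embeddings are held single precision; four bytes per value is the storage
    arithmetic the on-disk size accounting assumes.  ``codec_id`` ties the
    store to the exact codec that produced it so that decoding with a
    different model is refused rather than silently wrong.
    """

    pixel_coords: np.ndarray
    embeddings: np.ndarray
    codec_id: str
    width: int = 0
    height: int = 0

    def __post_init__(self) -> None:
        self.pixel_coords = np.asarray(self.pixel_coords, dtype=np.int64)
        self.embeddings = np.asarray(self.embeddings, dtype=np.float32)
        if self.pixel_coords.ndim != 2 or self.pixel_coords.shape[1] != 2:
            raise ValueError("pixel_coords must be (n, 2)")
        if self.embeddings.ndim != 2:
            raise ValueError("embeddings must be a 2-D matrix")
        if len(self.embeddings) != len(self.pixel_coords):
            raise ValueError("embedding row count must match pixel count")
        if self.embeddings.shape[1] < 1:
            raise ValueError("embedding length F_e must be positive")
        if not self.codec_id:
            raise ValueError("codec_id is required")

    @property
    def n_pixels(self) -> int:
        return len(self.pixel_coords)

    @property
    def f_e(self) -> int:
        """Embedding length."""
        return self.embeddings.shape[1]


@dataclass
class LabelMap:
    """Per-pixel integer class image; ``-1`` marks unlabeled pixels.

    ``labels`` is a dense ``(height, width)`` array indexed ``[y, x]``;
    unoccupied and unannotated cells both carry the ``UNLABELED`` sentinel.
    ``provenance`` distinguishes algorithm predictions from baseline
    (reference) segmentations.
    """

    labels: np.ndarray
    provenance: str = "prediction"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D (height, width) array")
        if self.labels.size and self.labels.min() < UNLABELED:
            raise ValueError("labels must be >= -1")
        if self.provenance not in ("prediction", "baseline"):
            raise ValueError("provenance must be 'prediction' or 'baseline'")

    @property
    def width(self) -> int:
        return self.labels.shape[1]

    @property
    def height(self) -> int:
        return self.labels.shape[0]

    def occupied_coords(self) -> np.ndarray:
        """Coordinates (x, y) of labeled pixels in raster order."""
        ys, xs = np.nonzero(self.labels != UNLABELED)
        return np.column_stack([xs, ys])

    def values_at(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=np.int64)
        return self.labels[coords[:, 1], coords[:, 0]]

    def copy(self) -> "LabelMap":
        return LabelMap(labels=self.labels.copy(), provenance=self.provenance)


@dataclass
class AugmentedBatch:
    """Contrastive training batch of 2N spectra in (original, noisy copy) pairs.

    Rows ``2j`` and ``2j + 1`` form the j-th positive pair.  ``pair_index``
    maps each row to its positive partner and is a fixed-point-free
    involution.
    """

    spectra: np.ndarray
    pair_index: np.ndarray
    n: int = field(default=0)

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=np.float64)
        self.pair_index = np.asarray(self.pair_index, dtype=np.int64)
        rows = len(self.spectra)
        if rows % 2 != 0:
            raise ValueError("batch must contain an even number of rows")
        if self.n == 0:
            self.n = rows // 2
        if rows != 2 * self.n:
            raise ValueError("row count must equal 2N")
        if len(self.pair_index) != rows:
            raise ValueError("pair_index length must equal row count")
        idx = np.arange(rows)
        if np.any(self.pair_index == idx):
            raise ValueError("pair_index must have no fixed points")
        if not np.array_equal(self.pair_index[self.pair_index], idx):
            raise ValueError("pair_index must be an involution")
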