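"""Reading and writing MS images and embeddings; storage-size accounting.

Three on-disk forms are supported:

* **imzML 1.1** (read only, continuous or processed binary mode) — the
  community standard for MSI raw data, read through ``pyimzml``.
* **Columnar pixel table** (Apache Parquet) — one row per pixel with columns
  ``x``, ``y`` and one column per m/z bin, named by the bin center.  The
  binned working format for whole images.
* **Embedding store** (HDF5) — coordinates, the float32 embedding matrix and
  the id of the codec that produced it; the compressed representation that
  actually gets archived.

``estimate_encoded_size`` does the compression arithmetic: ``n_pixels x F_e``
float32 values, reported in bytes and binary megabytes.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple

import numpy as np
import pandas as pd
import pyarrow as pa
import pyarrow.parquet as pq

from .preprocess import RawSpectrum
from .types import BinnedImage, EmbeddingStore

__all__ = [
    "read_imzml",
    "read_pixel_table",
    "write_pixel_table",
    "write_embeddings",
    "read_embeddings",
    "estimate_encoded_size",
    "reduction_percent",
    "EncodedSize",
]


def read_imzml(path) -> list[RawSpectrum]:
    """Read all pixel spectra from an imzML 1.1 file.

    Coordinates are converted from imzML's 1-based convention to the internal
    0-based one.  Centroid-mode files are passed through with a warning (a
    Gaussian smoothing step will turn the sticks into profile-like curves).
    """
    from pyimzml.ImzMLParser import ImzMLParser

    try:
        parser = ImzMLParser(str(path))
    except Exception as exc:  # malformed XML, missing .ibd, ...
        raise ValueError(f"could not parse imzML file {path}: {exc}") from exc
    try:
        params = parser.metadata.file_description.param_by_name
        if params.get("centroid spectrum"):
            warnings.warn(
                f"{path} contains centroid-mode spectra; Gaussian smoothing is "
                "recommended before encoding",
                stacklevel=2,
            )
    except AttributeError:  # metadata section absent; mode unknown
        pass
    spectra = []
    for i, coord in enumerate(parser.coordinates):
        mz, intensity = parser.getspectrum(i)
        x, y = int(coord[0]) - 1, int(coord[1]) - 1
        spectra.append(
            RawSpectrum(
                mz=np.asarray(mz, dtype=np.float64),
                intensity=np.asarray(intensity, dtype=np.float64),
                x=x,
                y=y,
            )
        )
    return spectra


def _format_mz(value: float) -> str:
    return np.format_float_positional(round(float(value), 6), trim="-")


def write_pixel_table(image: BinnedImage, path) -> None:
    """Write a binned image as a Parquet pixel table (raster row order).

    Intensities are stored single precision; bin columns are named by their
    m/z center (one decimal on the default 0.1-Da grid, e.g. ``"422.9"``).
    """
    order = image.raster_order()
    coords = image.pixel_coords[order]
    arrays = [
        pa.array(coords[:, 0], type=pa.int32()),
        pa.array(coords[:, 1], type=pa.int32()),
    ]
    names = ["x", "y"]
    intensities = image.intensities[order].astype(np.float32)
    for j, mz in enumerate(image.mz_axis):
        names.append(_format_mz(mz))
        arrays.append(pa.array(intensities[:, j], type=pa.float32()))
    table = pa.table(dict(zip(names, arrays)))
    meta = {b"msicodec:width": str(image.width).encode(),
            b"msicodec:height": str(image.height).encode()}
    if image.n_bins > 1:
        meta[b"msicodec:grid_step"] = repr(image.grid_step).encode()
    table = table.replace_schema_metadata(meta)
    pq.write_table(table, str(path))


def read_pixel_table(path) -> BinnedImage:
    """Read a Parquet pixel table back into a :class:`BinnedImage`.

    Row order is normalized to raster order (y-major, then x) regardless of
    the order in the file; non-uniform bin spacing and negative intensities
    are rejected.
    """
    table = pq.read_table(str(path))
    frame = table.to_pandas()
    if "x" not in frame.columns or "y" not in frame.columns:
        raise ValueError(f"{path} is not a pixel table (missing x/y columns)")
    bin_names = [c for c in frame.columns if c not in ("x", "y")]
    try:
        mz_axis = np.array([float(name) for name in bin_names])
    except ValueError as exc:
        raise ValueError(f"{path} has a non-numeric bin column name") from exc
    meta = table.schema.metadata or {}
    if len(mz_axis) > 1:
        steps = np.diff(mz_axis)
        if b"msicodec:grid_step" in meta:
            expected = float(meta[b"msicodec:grid_step"])
        else:
            # foreign table: the column names imply the grid resolution
            # ("100.1" means a 0.1-Da grid); consecutive bins must be adjacent
            decimals = max(len(n.split(".")[1]) if "." in n else 0 for n in bin_names)
            expected = 10.0 ** -decimals
        if steps.min() <= 0 or not np.allclose(steps, expected, rtol=1e-6, atol=0.0):
            raise ValueError(
                f"{path} has non-uniform bin spacing: expected a uniform "
                f"{expected:g}-Da grid, got steps from {steps.min():g} "
                f"to {steps.max():g}"
            )
    intensities = frame[bin_names].to_numpy(dtype=np.float64)
    if intensities.size and intensities.min() < 0:
        row, col = np.unravel_index(np.argmin(intensities), intensities.shape)
        raise ValueError(
            f"negative intensity at pixel (x={frame['x'].iat[row]}, "
            f"y={frame['y'].iat[row]}), bin {bin_names[col]}"
        )
    coords = frame[["x", "y"]].to_numpy(dtype=np.int64)
    width = int(meta.get(b"msicodec:width", b"0") or 0) or (
        int(coords[:, 0].max()) + 1 if len(coords) else 1
    )
    height = int(meta.get(b"msicodec:height", b"0") or 0) or (
        int(coords[:, 1].max()) + 1 if len(coords) else 1
    )
    image = BinnedImage(
        width=width, height=height, pixel_coords=coords,
        mz_axis=mz_axis, intensities=intensities,
    )
    order = image.raster_order()
    return BinnedImage(
        width=width, height=height, pixel_coords=coords[order],
        mz_axis=mz_axis, intensities=intensities[order],
    )


def write_embeddings(store: EmbeddingStore, path) -> None:
    """Persist an embedding store as a single HDF5 file (bit-exact)."""
    import h5py

    with h5py.File(str(path), "w") as fh:
        fh.create_dataset("coords", data=store.pixel_coords.astype(np.int32))
        fh.create_dataset("embeddings", data=store.embeddings.astype(np.float32))
        fh.attrs["codec_id"] = store.codec_id
        fh.attrs["f_e"] = store.f_e
        fh.attrs["width"] = store.width
        fh.attrs["height"] = store.height


def read_embeddings(path) -> EmbeddingStore:
    import h5py

    with h5py.File(str(path), "r") as fh:
        if "codec_id" not in fh.attrs:
            raise ValueError(f"{path} lacks a codec_id; cannot tie embeddings to a codec")
        return EmbeddingStore(
            pixel_coords=fh["coords"][...].astype(np.int64),
            embeddings=fh["embeddings"][...],
            codec_id=str(fh.attrs["codec_id"]),
            width=int(fh.attrs.get("width", 0)),
            height=int(fh.attrs.get("height", 0)),
        )


class EncodedSize(NamedTuple):
    """On-disk size of an encoded image: exact bytes and binary megabytes."""

    bytes: int
    megabytes: float


def estimate_encoded_size(
    n_pixels: int, f_e: int, bytes_per_value: int = 4
) -> EncodedSize:
    """Storage needed for the embedding payload of an encoded image.

    ``n_pixels * f_e`` values at ``bytes_per_value`` (4 for float32); the
    megabyte figure uses the binary convention (1 MB = 1024**2 bytes) and is
    rounded to one decimal.
    """
    for name, value in (("n_pixels", n_pixels), ("f_e", f_e),
                        ("bytes_per_value", bytes_per_value)):
        if int(value) != value or value <= 0:
            raise ValueError(f"{name} must be a positive integer, got {value}")
    total = int(n_pixels) * int(f_e) * int(bytes_per_value)
    return EncodedSize(bytes=total, megabytes=round(total / 1024**2, 1))


def reduction_percent(raw_bytes: float, encoded_bytes: float) -> float:
    """Percentage reduction in storage achieved by encoding."""
    if raw_bytes <= 0 or encoded_bytes < 0:
        raise ValueError("sizes must be positive")
    return 100.0 * (1.0 - encoded_bytes / raw_bytes)
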