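"""The encoder-decoder network that compresses spectra into embeddings.

The encoder turns a binned spectrum of length ``F_s`` into an embedding of
length ``F_e`` (64 by default) through a stack of strided 1-D convolution
blocks — convolution, per-channel batch normalization, ReLU — followed by a
linear layer onto the embedding.  The decoder mirrors it: a linear layer back
to the flattened convolutional shape and a stack of transposed convolutions
reconstructing all ``F_s`` intensity values.  The spectrum length is
zero-padded to the nearest length compatible with the stride stack; the
padding is recorded and stripped again on decode.

A trained :class:`Codec` also carries the intensity normalization scale used
during training, so decoded spectra come back in original units, and a
``codec_id`` content hash so embeddings can always be traced to the exact
model that produced them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .nn import BatchNorm1d, Conv1d, ConvTranspose1d, Linear, ReLU, Reshape, Sequential
from .preprocess import NormalizationScale
from .types import BinnedImage, EmbeddingStore

__all__ = ["CodecArchitecture", "Codec", "build_codec", "encode", "decode",
           "save_codec", "load_codec", "encode_image", "decode_store"]

_FORMAT_VERSION = 1


@dataclass(frozen=True)
class CodecArchitecture:
    """Hyperparameters defining the network's shape.

    ``conv_channels`` lists the output channels of the encoder convolution
    blocks (the decoder mirrors them in reverse); every block uses the same
    odd ``kernel_size`` and ``stride``.  With four stride-4 blocks a spectrum
    is temporally downsampled 256x before the linear projection to ``f_e``.
    """

    f_s: int
    f_e: int = 64
    conv_channels: tuple[int, ...] = (8, 16, 32, 64)
    kernel_size: int = 7
    stride: int = 4
    use_normalization: bool = True

    def __post_init__(self) -> None:
        if self.f_s < 1 or self.f_e < 1:
            raise ValueError("f_s and f_e must be positive")
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if not self.conv_channels:
            raise ValueError("at least one convolution block is required")

    @property
    def total_stride(self) -> int:
        return self.stride ** len(self.conv_channels)

    @property
    def padded_f_s(self) -> int:
        """Input length zero-padded up to a multiple of the total stride."""
        return -(-self.f_s // self.total_stride) * self.total_stride

    @property
    def bottleneck_length(self) -> int:
        return self.padded_f_s // self.total_stride

    @property
    def flattened_size(self) -> int:
        return self.conv_channels[-1] * self.bottleneck_length

    def to_dict(self) -> dict:
        return {
            "f_s": self.f_s,
            "f_e": self.f_e,
            "conv_channels": list(self.conv_channels),
            "kernel_size": self.kernel_size,
            "stride": self.stride,
            "use_normalization": self.use_normalization,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CodecArchitecture":
        d = dict(d)
        d["conv_channels"] = tuple(d["conv_channels"])
        return cls(**d)


def _build_networks(arch: CodecArchitecture, rng: np.random.Generator, dtype):
    k, s = arch.kernel_size, arch.stride
    pad = k // 2
    enc: list = [Reshape((1, arch.padded_f_s))]
    c_prev = 1
    for c in arch.conv_channels:
        enc.append(Conv1d(c_prev, c, k, s, pad, rng, dtype))
        if arch.use_normalization:
            enc.append(BatchNorm1d(c, dtype=dtype))
        enc.append(ReLU())
        c_prev = c
    enc.append(Reshape((arch.flattened_size,)))
    enc.append(Linear(arch.flattened_size, arch.f_e, rng, dtype))

    dec: list = [Linear(arch.f_e, arch.flattened_size, rng, dtype)]
    if arch.use_normalization:
        dec.append(BatchNorm1d(arch.flattened_size, dtype=dtype))
    dec.append(ReLU())
    dec.append(Reshape((arch.conv_channels[-1], arch.bottleneck_length)))
    channels = (1,) + arch.conv_channels
    out_pad = s - 1 if s > 1 else 0
    for i in range(len(arch.conv_channels) - 1, -1, -1):
        c_in, c_out = channels[i + 1], channels[i]
        dec.append(ConvTranspose1d(c_in, c_out, k, s, pad, out_pad, rng, dtype))
        if i > 0:  # last block outputs raw intensities
            if arch.use_normalization:
                dec.append(BatchNorm1d(c_out, dtype=dtype))
            dec.append(ReLU())
    dec.append(Reshape((arch.padded_f_s,)))
    return Sequential(enc), Sequential(dec)


@dataclass
class Codec:
    """A (possibly trained) encoder-decoder pair with its metadata."""

    architecture: CodecArchitecture
    encoder: Sequential
    decoder: Sequential
    scale: NormalizationScale = field(default_factory=NormalizationScale)
    mz_axis: np.ndarray | None = None
    dtype: np.dtype = np.dtype(np.float32)

    def set_training(self, training: bool) -> None:
        self.encoder.set_training(training)
        self.decoder.set_training(training)

    def _pad(self, spectra: np.ndarray) -> np.ndarray:
        extra = self.architecture.padded_f_s - self.architecture.f_s
        if extra == 0:
            return spectra
        return np.pad(spectra, ((0, 0), (0, extra)))

    def forward(self, spectra_padded: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Training-mode forward pass on already padded, normalized spectra."""
        w = self.encoder.forward(spectra_padded)
        return w, self.decoder.forward(w)

    def encode(self, spectra: np.ndarray) -> np.ndarray:
        """Map normalized spectra ``(n, F_s)`` to embeddings ``(n, F_e)``.

        Runs in inference mode (running batch-norm statistics), so results
        are deterministic and row-independent.
        """
        spectra = np.asarray(spectra, dtype=self.dtype)
        if spectra.ndim != 2 or spectra.shape[1] != self.architecture.f_s:
            raise ValueError(
                f"expected (n, {self.architecture.f_s}) spectra, got {spectra.shape}"
            )
        if len(spectra) == 0:
            return np.empty((0, self.architecture.f_e))
        self.set_training(False)
        return self.encoder.forward(self._pad(spectra)).astype(np.float64)

    def decode(self, embeddings: np.ndarray) -> np.ndarray:
        """Map embeddings back to spectra in original intensity units."""
        embeddings = np.asarray(embeddings, dtype=self.dtype)
        if embeddings.ndim != 2 or embeddings.shape[1] != self.architecture.f_e:
            raise ValueError(
                f"expected (n, {self.architecture.f_e}) embeddings, got {embeddings.shape}"
            )
        if len(embeddings) == 0:
            return np.empty((0, self.architecture.f_s))
        self.set_training(False)
        out = self.decoder.forward(embeddings)[:, : self.architecture.f_s]
        return out.astype(np.float64) * self.scale.scale

    @property
    def codec_id(self) -> str:
        """SHA-256 of the canonical serialization; changes with any weight."""
        h = hashlib.sha256()
        h.update(json.dumps(self.architecture.to_dict(), sort_keys=True).encode())
        for name, state in (("enc", self.encoder.state()), ("dec", self.decoder.state())):
            for key in sorted(state):
                h.update(f"{name}.{key}".encode())
                h.update(np.ascontiguousarray(state[key], dtype=np.float64).tobytes())
        return h.hexdigest()


def build_codec(arch: CodecArchitecture, seed: int | None = 0,
                dtype=np.float32) -> Codec:
    """Deterministically initialize an untrained codec.

    Raises at build time (not at first use) if the architecture cannot carry
    ``f_e`` features or the decoder cannot reconstruct ``f_s`` values.
    ``dtype`` is the working precision of the network (single by default).
    """
    if arch.f_e > arch.flattened_size:
        raise ValueError(
            f"embedding length {arch.f_e} exceeds flattened convolutional size "
            f"{arch.flattened_size}; use fewer/looser blocks or a smaller f_e"
        )
    rng = np.random.default_rng(seed)
    encoder, decoder = _build_networks(arch, rng, np.dtype(dtype))
    codec = Codec(architecture=arch, encoder=encoder, decoder=decoder,
                  dtype=np.dtype(dtype))
    # shape self-check: one zero spectrum must survive the round trip
    probe = codec.decode(codec.encode(np.zeros((1, arch.f_s))))
    if probe.shape != (1, arch.f_s):  # pragma: no cover - defensive
        raise RuntimeError("decoder failed to reconstruct the input length")
    return codec


def encode(codec: Codec, spectra: np.ndarray) -> np.ndarray:
    return codec.encode(spectra)


def decode(codec: Codec, embeddings: np.ndarray) -> np.ndarray:
    return codec.decode(embeddings)


def encode_image(codec: Codec, image: BinnedImage) -> EmbeddingStore:
    """Encode a whole binned image into an embedding store.

    Applies the codec's recorded intensity normalization before encoding, so
    the image may be given in original units.
    """
    spectra = image.intensities / codec.scale.scale
    embeddings = codec.encode(spectra)
    return EmbeddingStore(
        pixel_coords=image.pixel_coords,
        embeddings=embeddings.astype(np.float32),
        codec_id=codec.codec_id,
        width=image.width,
        height=image.height,
    )


def decode_store(codec: Codec, store: EmbeddingStore) -> BinnedImage:
    """Decode an embedding store back into a binned image (original units).

    Refuses to decode embeddings produced by a different codec.
    """
    if store.codec_id != codec.codec_id:
        raise ValueError(
            f"embedding store was produced by codec {store.codec_id[:12]}..., "
            f"not by this codec ({codec.codec_id[:12]}...)"
        )
    if codec.mz_axis is None:
        raise ValueError("codec carries no m/z axis; cannot rebuild an image")
    spectra = codec.decode(store.embeddings.astype(np.float64))
    np.clip(spectra, 0.0, None, out=spectra)
    return BinnedImage(
        width=store.width or int(store.pixel_coords[:, 0].max()) + 1,
        height=store.height or int(store.pixel_coords[:, 1].max()) + 1,
        pixel_coords=store.pixel_coords,
        mz_axis=np.asarray(codec.mz_axis),
        intensities=spectra,
    )


def save_codec(codec: Codec, path) -> None:
    """Persist a codec to a single ``.npz`` file (architecture + weights)."""
    meta = {
        "format_version": _FORMAT_VERSION,
        "architecture": codec.architecture.to_dict(),
        "scale_method": codec.scale.method,
        "scale_value": codec.scale.scale,
        "codec_id": codec.codec_id,
        "dtype": codec.dtype.name,
    }
    arrays = {f"enc.{k}": v for k, v in codec.encoder.state().items()}
    arrays.update({f"dec.{k}": v for k, v in codec.decoder.state().items()})
    if codec.mz_axis is not None:
        arrays["mz_axis"] = np.asarray(codec.mz_axis, dtype=np.float64)
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_codec(path) -> Codec:
    """Load a codec saved by :func:`save_codec`; verifies the content hash."""
    try:
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            arrays = {k: data[k] for k in data.files if k != "__meta__"}
    except (OSError, ValueError, KeyError) as exc:
        raise ValueError(f"not a readable codec file: {path}") from exc
    if meta.get("format_version") != _FORMAT_VERSION:
        raise ValueError(f"unsupported codec format version in {path}")
    arch = CodecArchitecture.from_dict(meta["architecture"])
    dtype = np.dtype(meta.get("dtype", "float32"))
    rng = np.random.default_rng(0)
    encoder, decoder = _build_networks(arch, rng, dtype)
    encoder.load_state({k[len("enc."):]: v for k, v in arrays.items() if k.startswith("enc.")})
    decoder.load_state({k[len("dec."):]: v for k, v in arrays.items() if k.startswith("dec.")})
    codec = Codec(
        architecture=arch,
        encoder=encoder,
        decoder=decoder,
        scale=NormalizationScale(meta["scale_method"], meta["scale_value"]),
        mz_axis=arrays.get("mz_axis"),
        dtype=dtype,
    )
    if codec.codec_id != meta["codec_id"]:
        raise ValueError(f"codec file {path} is corrupted (content hash mismatch)")
    return codec
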