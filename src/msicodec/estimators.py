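"""scikit-learn style front end to the spectrum codec.

:class:`SpectrumCodec` wraps the whole train/encode/decode cycle as a
transformer: ``fit`` trains the contrastive encoder-decoder on a matrix of
pixel spectra (or a :class:`~msicodec.types.BinnedImage`), ``transform``
compresses spectra to embeddings and ``inverse_transform`` reconstructs
spectra in original intensity units.  It composes with sklearn pipelines and
clusterers, e.g. ``KMeans(8).fit_predict(SpectrumCodec().fit_transform(X))``.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .codec_model import CodecArchitecture
from .objective import BIOPSY_WEIGHTS, BLADDER_WEIGHTS, ContrastiveParams, LossWeights
from .trainer import TrainingConfig, train
from .types import BinnedImage

__all__ = ["SpectrumCodec"]

_WEIGHT_PRESETS = {"bladder": BLADDER_WEIGHTS, "biopsy": BIOPSY_WEIGHTS}


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, BinnedImage):
        return X.intensities
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D (n_pixels, F_s) matrix or a BinnedImage")
    return X


def _as_image(X) -> BinnedImage:
    if isinstance(X, BinnedImage):
        return X
    X = _as_matrix(X)
    n, f_s = X.shape
    coords = np.column_stack([np.zeros(n, dtype=np.int64), np.arange(n)])
    return BinnedImage(
        width=1, height=n, pixel_coords=coords,
        mz_axis=np.arange(f_s) * 0.1, intensities=X,
    )


class SpectrumCodec(TransformerMixin, BaseEstimator):
    """Contrastive encoder-decoder compressor for pixel spectra.

    Fitting trains a 1-D convolutional encoder-decoder with the combined
    contrastive / mean / standard-deviation / reconstruction objective; the
    fitted transformer maps spectra of length ``F_s`` to embeddings of length
    ``f_e`` and back.

    Parameters
    ----------
    f_e : int
        Embedding length (64 suits bladder-scale images, 128 biopsies).
    conv_channels, kernel_size, stride, use_normalization
        Architecture of the convolution stack (mirrored in the decoder).
    learning_rate, weight_decay, batch_size, patience_epochs, max_epochs
        Adam optimization and early-stopping settings.
    loss_weights : {"bladder", "biopsy"} or LossWeights
        Weighting of the four loss terms.
    contrastive_alpha : float or None
        Contrastive weight constant; None averages per anchor (1/2N).
    contrastive_gamma : float
        Softmax temperature of the contrastive term.
    augment_delta : float
        Maximum relative intensity perturbation of the noisy copies.
    normalization : {"global_max", "none"}
        Intensity scaling applied before training and encoding.
    random_state : int
        Seed controlling initialization, shuffling and augmentation noise.

    Attributes
    ----------
    codec_ : the trained low-level :class:`~msicodec.codec_model.Codec`.
    history_ : list of per-epoch loss reports.
    codec_id_ : content hash of the trained model.
    n_features_in_ : spectrum length F_s seen during fit.
    """

    def __init__(
        self,
        f_e: int = 64,
        conv_channels: tuple[int, ...] = (8, 16, 32, 64),
        kernel_size: int = 7,
        stride: int = 4,
        use_normalization: bool = True,
        learning_rate: float = 1e-3,
        weight_decay: float = 1e-5,
        batch_size: int = 64,
        patience_epochs: int = 30,
        max_epochs: int = 300,
        loss_weights: str | LossWeights = "bladder",
        contrastive_alpha: Optional[float] = None,
        contrastive_gamma: float = 0.5,
        augment_delta: float = 0.1,
        normalization: str = "global_max",
        random_state: int = 0,
    ):
        self.f_e = f_e
        self.conv_channels = conv_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.use_normalization = use_normalization
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.patience_epochs = patience_epochs
        self.max_epochs = max_epochs
        self.loss_weights = loss_weights
        self.contrastive_alpha = contrastive_alpha
        self.contrastive_gamma = contrastive_gamma
        self.augment_delta = augment_delta
        self.normalization = normalization
        self.random_state = random_state

    def _training_config(self) -> TrainingConfig:
        weights = self.loss_weights
        if isinstance(weights, str):
            try:
                weights = _WEIGHT_PRESETS[weights]
            except KeyError:
                raise ValueError(
                    f"unknown loss weight preset {self.loss_weights!r}; "
                    f"choose from {sorted(_WEIGHT_PRESETS)}"
                ) from None
        return TrainingConfig(
            learning_rate=self.learning_rate,
            weight_decay=self.weight_decay,
            batch_size=self.batch_size,
            patience_epochs=self.patience_epochs,
            max_epochs=self.max_epochs,
            loss_weights=weights,
            contrastive_params=ContrastiveParams(
                alpha=self.contrastive_alpha, gamma=self.contrastive_gamma
            ),
            augment_delta=self.augment_delta,
            normalization=self.normalization,
            seed=self.random_state,
        )

    def fit(self, X, y=None):
        image = _as_image(X)
        arch = CodecArchitecture(
            f_s=image.n_bins,
            f_e=self.f_e,
            conv_channels=tuple(self.conv_channels),
            kernel_size=self.kernel_size,
            stride=self.stride,
            use_normalization=self.use_normalization,
        )
        self.codec_, self.history_ = train(image, arch, self._training_config())
        self.codec_id_ = self.codec_.codec_id
        self.n_features_in_ = image.n_bins
        return self

    def transform(self, X) -> np.ndarray:
        """Compress spectra (original units) into embeddings."""
        check_is_fitted(self, "codec_")
        spectra = _as_matrix(X)
        if spectra.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {spectra.shape[1]} bins; codec expects {self.n_features_in_}"
            )
        return self.codec_.encode(spectra / self.codec_.scale.scale)

    def inverse_transform(self, W) -> np.ndarray:
        """Decode embeddings back into spectra in original intensity units."""
        check_is_fitted(self, "codec_")
        return self.codec_.decode(np.asarray(W, dtype=np.float64))
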