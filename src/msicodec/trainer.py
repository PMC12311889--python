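"""Training loop: Adam-optimized contrastive encoder-decoder learning.

Each epoch makes one full pass over all pixels in a seeded shuffled order.
Every batch of N pixels becomes 2N rows (each spectrum interleaved with one
noisy augmentation), is pushed through encoder and decoder, and the weighted
sum of the contrastive, mean, standard and reconstruction losses is
backpropagated.  Training stops when the weighted epoch loss has not improved
for ``patience_epochs`` epochs (or at ``max_epochs``), and the weights from
the best epoch are restored.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import objective, preprocess
from .codec_model import Codec, CodecArchitecture, build_codec
from .nn import Adam
from .objective import BLADDER_WEIGHTS, ContrastiveParams, LossReport, LossWeights
from .types import BinnedImage

__all__ = ["TrainingConfig", "train", "train_per_group", "history_to_csv"]

#: Relative improvement in the weighted loss below which an epoch does not
#: reset the early-stopping counter.
_IMPROVEMENT_RTOL = 1e-6


@dataclass(frozen=True)
class TrainingConfig:
    """All knobs of one training run.

    Defaults: Adam with learning rate 1e-3 and weight decay 1e-5, batch size
    64, early-stopping patience 30 epochs, 10% multiplicative augmentation
    noise, and the bladder-like loss weights (contrastive 1e-1, mean and
    standard 1e-2, decoder 1e-2).
    """

    learning_rate: float = 1e-3
    weight_decay: float = 1e-5
    batch_size: int = 64
    patience_epochs: int = 30
    max_epochs: int = 300
    loss_weights: LossWeights = field(default_factory=lambda: BLADDER_WEIGHTS)
    contrastive_params: ContrastiveParams = field(default_factory=ContrastiveParams)
    augment_delta: float = 0.1
    normalization: str = "global_max"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be nonnegative")
        if self.batch_size < 2:
            raise ValueError("batch_size must be at least 2")
        if self.patience_epochs < 1:
            raise ValueError("patience_epochs must be at least 1")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be at least 1")

    def to_dict(self) -> dict:
        return {
            "learning_rate": self.learning_rate,
            "weight_decay": self.weight_decay,
            "batch_size": self.batch_size,
            "patience_epochs": self.patience_epochs,
            "max_epochs": self.max_epochs,
            "loss_weights": {
                "contrastive": self.loss_weights.contrastive,
                "mean": self.loss_weights.mean,
                "standard": self.loss_weights.standard,
                "decoder": self.loss_weights.decoder,
            },
            "contrastive_params": {
                "alpha": self.contrastive_params.alpha,
                "gamma": self.contrastive_params.gamma,
            },
            "augment_delta": self.augment_delta,
            "normalization": self.normalization,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TrainingConfig":
        d = dict(d)
        if "loss_weights" in d and isinstance(d["loss_weights"], Mapping):
            d["loss_weights"] = LossWeights(**d["loss_weights"])
        if "contrastive_params" in d and isinstance(d["contrastive_params"], Mapping):
            d["contrastive_params"] = ContrastiveParams(**d["contrastive_params"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "TrainingConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _snapshot(codec: Codec) -> tuple[dict, dict]:
    return (copy.deepcopy(codec.encoder.state()), copy.deepcopy(codec.decoder.state()))


def _restore(codec: Codec, snap: tuple[dict, dict]) -> None:
    codec.encoder.load_state(snap[0])
    codec.decoder.load_state(snap[1])


def train(
    image: BinnedImage,
    arch: CodecArchitecture,
    config: TrainingConfig = TrainingConfig(),
) -> tuple[Codec, list[LossReport]]:
    """Fit a codec to one MS image; returns (best codec, per-epoch history)."""
    if image.n_pixels == 0:
        raise ValueError("cannot train on an empty image")
    if image.n_bins != arch.f_s:
        raise ValueError(
            f"image has {image.n_bins} bins but architecture expects {arch.f_s}"
        )
    normalized, scale = preprocess.normalize_intensities(image, config.normalization)
    rng = np.random.default_rng(config.seed)
    codec = build_codec(arch, seed=int(rng.integers(2**31)))
    codec.scale = scale
    codec.mz_axis = image.mz_axis.copy()
    optimizer = Adam(
        codec.encoder, learning_rate=config.learning_rate, weight_decay=config.weight_decay
    )
    optimizer_dec = Adam(
        codec.decoder, learning_rate=config.learning_rate, weight_decay=config.weight_decay
    )

    n = normalized.n_pixels
    if n < config.batch_size:
        warnings.warn(
            f"image has only {n} pixels (< batch size {config.batch_size}); "
            "training with a single smaller batch",
            stacklevel=2,
        )

    weights = config.loss_weights
    cparams = config.contrastive_params
    f_s = arch.f_s
    pad_extra = arch.padded_f_s - f_s

    history: list[LossReport] = []
    best = np.inf
    best_snap = _snapshot(codec)
    since_improve = 0

    for _epoch in range(config.max_epochs):
        order = rng.permutation(n)
        sums = np.zeros(4)
        n_batches = 0
        codec.set_training(True)
        for start in range(0, n, config.batch_size):
            idx = order[start: start + config.batch_size]
            batch = preprocess.make_batch(normalized, idx, config.augment_delta, rng)
            x = batch.spectra.astype(codec.dtype)
            xp = np.pad(x, ((0, 0), (0, pad_extra))) if pad_extra else x
            w, decoded = codec.forward(xp)

            # loss math in double precision on the small embedding matrices
            w64 = w.astype(np.float64)
            l_con, g_con = objective.contrastive_loss_grad(w64, batch.pair_index, cparams)
            l_mean, g_mean = objective.mean_loss_grad(w64)
            l_std, g_std = objective.standard_loss_grad(w64)
            l_mse, g_mse = objective.mse_loss_grad(x, decoded[:, :f_s])
            objective.total_loss(l_con, l_mean, l_std, l_mse, weights)  # NaN guard

            g_decoded = np.zeros_like(decoded)
            g_decoded[:, :f_s] = weights.decoder * g_mse
            g_w = (
                weights.contrastive * g_con
                + weights.mean * g_mean
                + weights.standard * g_std
            ).astype(codec.dtype) + codec.decoder.backward(g_decoded)
            codec.encoder.backward(g_w)
            optimizer.step()
            optimizer_dec.step()
            sums += (l_con, l_mean, l_std, l_mse)
            n_batches += 1

        means = sums / n_batches
        weighted, report = objective.total_loss(*means, weights)
        history.append(report)

        improved = (
            weighted < best - _IMPROVEMENT_RTOL * abs(best) if np.isfinite(best) else True
        )
        if improved:
            best = weighted
            best_snap = _snapshot(codec)
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= config.patience_epochs:
                break

    _restore(codec, best_snap)
    codec.set_training(False)
    return codec, history


def train_per_group(
    images: Mapping[str, BinnedImage] | Iterable[tuple[str, BinnedImage]],
    arch: CodecArchitecture,
    config: TrainingConfig = TrainingConfig(),
) -> dict[str, tuple[Codec, list[LossReport]]]:
    """Train one codec per subject/group, with per-group seeds derived from
    the master seed (so the whole ensemble is reproducible end to end)."""
    items = list(images.items()) if isinstance(images, Mapping) else list(images)
    if not items:
        raise ValueError("train_per_group needs at least one group")
    results: dict[str, tuple[Codec, list[LossReport]]] = {}
    for i, (group_id, image) in enumerate(items):
        seed = int(np.random.SeedSequence([config.seed, i]).generate_state(1)[0] % 2**31)
        group_config = replace(config, seed=seed)
        try:
            results[group_id] = train(image, arch, group_config)
        except Exception as exc:
            raise RuntimeError(f"training failed for group {group_id!r}") from exc
    return results


def history_to_csv(history: list[LossReport], path) -> None:
    """Export per-epoch loss components (the loss-trajectory record)."""
    frame = pd.DataFrame(
        {
            "epoch": np.arange(1, len(history) + 1),
            "contrastive": [h.contrastive for h in history],
            "mean": [h.mean for h in history],
            "standard": [h.standard for h in history],
            "mse": [h.mse for h in history],
            "weighted_total": [h.weighted_total for h in history],
        }
    )
    frame.to_csv(path, index=False)
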