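"""Shared fixtures: small synthetic images and a trained codec (session scope).

Everything is generated programmatically; no stored data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from msicodec import codec_model, synthetic_data, trainer


@pytest.fixture(scope="session")
def small_fixture():
    """12x12 image, 4 ring classes, 400 bins — fast enough for unit tests."""
    return synthetic_data.default_fixture(seed=7, width=12, height=12, n_bins=400)


@pytest.fixture(scope="session")
def small_image(small_fixture):
    return small_fixture[0]


@pytest.fixture(scope="session")
def small_label_map(small_fixture):
    return small_fixture[1]


@pytest.fixture(scope="session")
def trained_small_codec(small_image):
    """Codec briefly trained on the small image (shared across tests)."""
    arch = codec_model.CodecArchitecture(f_s=small_image.n_bins, f_e=16)
    config = trainer.TrainingConfig(
        batch_size=32, max_epochs=12, patience_epochs=30, seed=3
    )
    codec, history = trainer.train(small_image, arch, config)
    return codec, history


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
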