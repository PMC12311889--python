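"""Loss functions for contrastive encoder-decoder training.

Four terms drive the codec:

* ``contrastive_loss`` -- an NT-Xent-style normalized temperature-scaled
  cross-entropy over cosine similarities.  Each spectrum and its noisy copy
  form a positive pair; every other in-batch pair is negative.  For anchor i
  with positive partner j,

      l(i, j) = -log[ exp(sim(w_i, w_j) / gamma)
                      / sum_{k != i} exp(sim(w_i, w_k) / gamma) ]

  and the loss is ``alpha`` times the sum of l over all *ordered* positive
  pairs (both (i, j) and (j, i)).
* ``mean_loss`` -- (1/2N) sum_i mu(w_i)^2, the squared per-embedding mean;
  keeps embeddings centered near zero.
* ``standard_loss`` -- (1/F_e) sum_f (sigma_f(w) - 1)^2 with sigma_f the
  population standard deviation of feature f across the batch; keeps every
  embedding feature at unit spread.
* ``mse_loss`` -- mean squared reconstruction error between input and decoded
  spectra, averaged over every entry of the batch.

All loss functions come with closed-form gradients (``*_grad``) with respect
to their inputs; the training loop backpropagates those through the network.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "ContrastiveParams",
    "LossWeights",
    "LossReport",
    "cosine_similarity",
    "contrastive_loss",
    "contrastive_loss_grad",
    "mean_loss",
    "mean_loss_grad",
    "standard_loss",
    "standard_loss_grad",
    "mse_loss",
    "mse_loss_grad",
    "total_loss",
    "BLADDER_WEIGHTS",
    "BIOPSY_WEIGHTS",
]


@dataclass(frozen=True)
class ContrastiveParams:
    """Weight constant ``alpha`` and temperature ``gamma`` of the contrastive term.

    ``alpha=None`` means 1/(2N): the sum over ordered positive pairs becomes a
    per-anchor average, making the term batch-size independent.  ``gamma``
    divides the cosine similarity inside the softmax; smaller values sharpen
    the contrast between the positive pair and the negatives.
    """

    alpha: Optional[float] = None
    gamma: float = 0.5

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("temperature gamma must be positive")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("alpha must be positive")

    def effective_alpha(self, two_n: int) -> float:
        return 1.0 / two_n if self.alpha is None else self.alpha


@dataclass(frozen=True)
class LossWeights:
    """Nonnegative weights of the four loss terms in the training objective."""

    contrastive: float = 0.1
    mean: float = 0.01
    standard: float = 0.01
    decoder: float = 0.01

    def __post_init__(self) -> None:
        vals = (self.contrastive, self.mean, self.standard, self.decoder)
        if any(v < 0 for v in vals):
            raise ValueError("loss weights must be nonnegative")
        if all(v == 0 for v in vals):
            raise ValueError("at least one loss weight must be positive")


#: Preset used for the mouse-bladder-like setting (decoder term at 1e-2).
BLADDER_WEIGHTS = LossWeights(contrastive=0.1, mean=0.01, standard=0.01, decoder=0.01)
#: Preset for biopsy-like data where reconstruction is emphasised (decoder at 1).
BIOPSY_WEIGHTS = LossWeights(contrastive=0.1, mean=0.01, standard=0.01, decoder=1.0)


@dataclass
class LossReport:
    """Per-step or per-epoch record of the individual and combined losses."""

    contrastive: float
    mean: float
    standard: float
    mse: float
    weighted_total: float


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between two nonzero vectors, in [-1, 1]."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


def _validate_pairs(embeddings: np.ndarray, pair_index: np.ndarray) -> np.ndarray:
    w = np.asarray(embeddings, dtype=np.float64)
    if w.ndim != 2 or len(w) < 2 or len(w) % 2 != 0:
        raise ValueError("embeddings must be a (2N, F_e) matrix with N >= 1")
    p = np.asarray(pair_index, dtype=np.int64)
    idx = np.arange(len(w))
    if len(p) != len(w) or np.any(p == idx) or not np.array_equal(p[p], idx):
        raise ValueError("pair_index must be a fixed-point-free involution over the batch")
    return w


def _contrastive_core(w: np.ndarray, pair_index: np.ndarray, gamma: float):
    """Shared forward pass: returns (unit rows, norms, softmax matrix, loss sum)."""
    norms = np.linalg.norm(w, axis=1, keepdims=True)
    if np.any(norms == 0.0):
        raise ValueError("contrastive loss undefined for zero embeddings")
    u = w / norms
    sim = u @ u.T
    logits = sim / gamma
    np.fill_diagonal(logits, -np.inf)  # k != i in the denominator
    # max-subtraction keeps exp() finite even for extreme sim/gamma
    logits = logits - logits.max(axis=1, keepdims=True)
    ex = np.exp(logits)
    denom = ex.sum(axis=1, keepdims=True)
    softmax = ex / denom
    rows = np.arange(len(w))
    log_prob_pos = logits[rows, pair_index] - np.log(denom[:, 0])
    return u, norms, softmax, -log_prob_pos.sum()


def contrastive_loss(
    embeddings: np.ndarray,
    pair_index: np.ndarray,
    params: ContrastiveParams = ContrastiveParams(),
) -> float:
    """NT-Xent contrastive loss over all ordered positive pairs, times alpha."""
    w = _validate_pairs(embeddings, pair_index)
    pair_index = np.asarray(pair_index, dtype=np.int64)
    _, _, _, loss_sum = _contrastive_core(w, pair_index, params.gamma)
    return params.effective_alpha(len(w)) * float(loss_sum)


def contrastive_loss_grad(
    embeddings: np.ndarray,
    pair_index: np.ndarray,
    params: ContrastiveParams = ContrastiveParams(),
) -> tuple[float, np.ndarray]:
    """Loss value and its gradient with respect to the raw embeddings."""
    w = _validate_pairs(embeddings, pair_index)
    pair_index = np.asarray(pair_index, dtype=np.int64)
    gamma = params.gamma
    u, norms, softmax, loss_sum = _contrastive_core(w, pair_index, gamma)
    alpha = params.effective_alpha(len(w))

    # dL/d sim[i, k] = alpha * (softmax[i, k] - 1{k = pair(i)}) / gamma, k != i
    g_sim = softmax.copy()
    rows = np.arange(len(w))
    g_sim[rows, pair_index] -= 1.0
    g_sim *= alpha / gamma
    np.fill_diagonal(g_sim, 0.0)

    # sim = u u^T  =>  dL/du = (G + G^T) u ; then through row normalization
    g_u = (g_sim + g_sim.T) @ u
    g_w = (g_u - (g_u * u).sum(axis=1, keepdims=True) * u) / norms
    return alpha * float(loss_sum), g_w


def mean_loss(embeddings: np.ndarray) -> float:
    """Average squared row mean: (1/2N) sum_i mu(w_i)^2."""
    w = np.asarray(embeddings, dtype=np.float64)
    if w.ndim != 2 or len(w) == 0:
        raise ValueError("embeddings must be a nonempty 2-D matrix")
    mu = w.mean(axis=1)
    return float(np.mean(mu**2))


def mean_loss_grad(embeddings: np.ndarray) -> tuple[float, np.ndarray]:
    w = np.asarray(embeddings, dtype=np.float64)
    if w.ndim != 2 or len(w) == 0:
        raise ValueError("embeddings must be a nonempty 2-D matrix")
    b, f = w.shape
    mu = w.mean(axis=1, keepdims=True)
    grad = 2.0 * mu / (b * f) * np.ones_like(w)
    return float(np.mean(mu[:, 0] ** 2)), grad


def standard_loss(embeddings: np.ndarray) -> float:
    """Average squared deviation of per-feature population std from one."""
    w = np.asarray(embeddings, dtype=np.float64)
    if w.ndim != 2 or len(w) < 2:
        raise ValueError("standard loss needs at least two embeddings")
    sigma = w.std(axis=0)  # population (ddof=0)
    return float(np.mean((sigma - 1.0) ** 2))


def standard_loss_grad(embeddings: np.ndarray) -> tuple[float, np.ndarray]:
    w = np.asarray(embeddings, dtype=np.float64)
    if w.ndim != 2 or len(w) < 2:
        raise ValueError("standard loss needs at least two embeddings")
    b, f = w.shape
    mu = w.mean(axis=0, keepdims=True)
    centered = w - mu
    sigma = np.sqrt((centered**2).mean(axis=0) + 1e-24)
    loss = float(np.mean((sigma - 1.0) ** 2))
    # d sigma_f / d w_if = centered_if / (b * sigma_f)
    grad = (2.0 / f) * (sigma - 1.0) / (b * sigma) * centered
    return loss, grad


def mse_loss(original: np.ndarray, decoded: np.ndarray) -> float:
    """Mean squared error over every entry of the spectra matrices."""
    z = np.asarray(original, dtype=np.float64)
    zt = np.asarray(decoded, dtype=np.float64)
    if z.shape != zt.shape:
        raise ValueError(f"shape mismatch: {z.shape} vs {zt.shape}")
    return float(np.mean((z - zt) ** 2))


def mse_loss_grad(original: np.ndarray, decoded: np.ndarray) -> tuple[float, np.ndarray]:
    """MSE and its gradient with respect to the decoded spectra."""
    z = np.asarray(original, dtype=np.float64)
    zt = np.asarray(decoded, dtype=np.float64)
    if z.shape != zt.shape:
        raise ValueError(f"shape mismatch: {z.shape} vs {zt.shape}")
    diff = zt - z
    return float(np.mean(diff**2)), 2.0 * diff / diff.size


def total_loss(
    contrastive: float,
    mean: float,
    standard: float,
    mse: float,
    weights: LossWeights,
) -> tuple[float, LossReport]:
    """Weighted sum of the four components, plus a per-component report."""
    components = {"contrastive": contrastive, "mean": mean, "standard": standard, "mse": mse}
    for name, value in components.items():
        if not np.isfinite(value):
            raise FloatingPointError(f"{name} loss diverged (value {value})")
    weighted = (
        weights.contrastive * contrastive
        + weights.mean * mean
        + weights.standard * standard
        + weights.decoder * mse
    )
    return weighted, LossReport(
        contrastive=contrastive,
        mean=mean,
        standard=standard,
        mse=mse,
        weighted_total=weighted,
    )
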