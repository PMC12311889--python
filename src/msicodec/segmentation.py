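"""Pixel clustering into tissue classes.

Three feature sources feed the same clustering machinery: raw binned spectra,
the top-mean-intensity peak subset, or codec embeddings.  Plain k-means needs
the cluster count up front; the iterative variant estimates it by walking the
principal components of the data one at a time, choosing for each a cluster
count by silhouette score and multiplying the counts until a target ``K`` is
met or a component shows no structure.  A final majority-vote convolutional
smoothing pass removes isolated mislabeled pixels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.ndimage import convolve
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .types import UNLABELED, BinnedImage, LabelMap

__all__ = [
    "IterativeKMeans",
    "IterativeKMeansResult",
    "top_peak_features",
    "kmeans_segment",
    "best_count_for_component",
    "iterative_kmeans",
    "convolutional_smooth",
    "labels_to_map",
    "write_label_map_csv",
    "read_label_map_csv",
]


def labels_to_map(
    labels: np.ndarray, pixel_coords: np.ndarray, width: int, height: int,
    provenance: str = "prediction",
) -> LabelMap:
    """Place per-pixel labels onto a dense grid; unoccupied cells stay -1."""
    grid = np.full((height, width), UNLABELED, dtype=np.int64)
    coords = np.asarray(pixel_coords, dtype=np.int64)
    grid[coords[:, 1], coords[:, 0]] = np.asarray(labels, dtype=np.int64)
    return LabelMap(labels=grid, provenance=provenance)


def top_peak_features(image: BinnedImage, n_peaks: int = 128) -> np.ndarray:
    """Select the ``n_peaks`` bins with the highest across-image mean intensity.

    Columns are ordered by descending mean; equal means break toward the lower
    m/z.  This is the cheap "top peaks" representation used as a clustering
    baseline when the full spectra are too large.
    """
    if n_peaks <= 0:
        raise ValueError("n_peaks must be positive")
    if n_peaks > image.n_bins:
        raise ValueError(f"n_peaks={n_peaks} exceeds the {image.n_bins} available bins")
    means = image.intensities.mean(axis=0)
    order = np.lexsort((np.arange(image.n_bins), -means))
    return image.intensities[:, order[:n_peaks]]


def kmeans_segment(
    features: np.ndarray,
    k: int,
    pixel_coords: np.ndarray,
    width: int,
    height: int,
    seed: Optional[int] = None,
    n_init: int = 10,
) -> LabelMap:
    """k-means (k-means++ init, ``n_init`` restarts) mapped back to the grid."""
    features = np.asarray(features, dtype=np.float64)
    if k < 1:
        raise ValueError("k must be at least 1")
    if len(features) < k:
        raise ValueError(f"cannot form {k} clusters from {len(features)} pixels")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(features)
    return labels_to_map(labels, pixel_coords, width, height)


def _best_count(
    values: np.ndarray, c_max: int, threshold: float, seed: Optional[int], n_init: int
) -> tuple[int, np.ndarray]:
    """Silhouette-selected cluster count for a 1-D projection, with labels."""
    values = np.asarray(values, dtype=np.float64).reshape(-1, 1)
    n = len(values)
    if np.ptp(values) == 0.0:  # constant projection: no structure
        return 1, np.zeros(n, dtype=np.int64)
    best_c, best_score, best_labels = 1, -np.inf, np.zeros(n, dtype=np.int64)
    for c in range(2, min(c_max, n - 1) + 1):
        km = KMeans(n_clusters=c, n_init=n_init, random_state=seed)
        labels = km.fit_predict(values)
        if len(np.unique(labels)) < 2:
            continue
        score = silhouette_score(values, labels)
        if score > best_score:
            best_c, best_score, best_labels = c, score, labels
    if best_score < threshold:
        return 1, np.zeros(n, dtype=np.int64)
    return best_c, best_labels


def best_count_for_component(
    values: np.ndarray,
    c_max: int = 10,
    silhouette_threshold: float = 0.7,
    seed: Optional[int] = None,
    n_init: int = 10,
) -> int:
    """Optimal k-means cluster count for one principal-component projection.

    Runs k-means for every candidate count in ``{2..c_max}`` and returns the
    count with the highest mean silhouette score — or 1 if even the best score
    stays below ``silhouette_threshold``, declaring the component
    structureless.
    """
    if c_max < 2:
        raise ValueError("c_max must be at least 2")
    values = np.asarray(values, dtype=np.float64).reshape(-1)
    if len(values) <= c_max:
        raise ValueError("need more points than c_max")
    c, _ = _best_count(values, c_max, silhouette_threshold, seed, n_init)
    return c


class IterativeKMeans(ClusterMixin, BaseEstimator):
    """Cluster-count-free k-means driven by per-principal-component silhouettes.

    The algorithm: project the (centered) data onto its principal components;
    for component i = 1, 2, ... run k-means on the 1-D projection with every
    candidate count, keep the silhouette-optimal count c; stop when c = 1
    (no further structure) or when the product of the counts reaches the
    target ``n_clusters_max`` (K).  The final clusters are the nonempty cells
    of the Cartesian product of the per-component assignments.

    Parameters
    ----------
    n_clusters_max : int
        Target K; component processing stops once the composite count
        reaches it.
    silhouette_threshold : float
        Minimum acceptable silhouette score; below it a component is declared
        structureless (c = 1).  On 1-D projections even unclustered data
        scores about 0.55-0.60, while genuinely multimodal projections score
        above 0.9, so the default 0.7 sits between the two regimes.
    c_max_per_component : int
        Largest candidate count tried on any single component.
    n_init : int
        k-means restarts per candidate count.
    random_state : int or None
        Seed for every k-means run.

    Attributes
    ----------
    labels_ : composite cluster id per sample, renumbered ``0..k_found - 1``.
    n_clusters_found_ : number of distinct nonempty composite clusters.
    per_component_counts_ : the chosen c for each component that was used.
    components_used_ : how many principal components contributed.
    """

    def __init__(
        self,
        n_clusters_max: int = 8,
        silhouette_threshold: float = 0.7,
        c_max_per_component: int = 10,
        n_init: int = 10,
        random_state: Optional[int] = None,
    ):
        self.n_clusters_max = n_clusters_max
        self.silhouette_threshold = silhouette_threshold
        self.c_max_per_component = c_max_per_component
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D feature matrix")
        n = len(X)
        if self.n_clusters_max < 1:
            raise ValueError("n_clusters_max must be at least 1")
        if self.n_clusters_max > n:
            raise ValueError(f"K={self.n_clusters_max} exceeds the {n} samples")

        counts: list[int] = []
        assignments: list[np.ndarray] = []
        k = 1
        if self.n_clusters_max > 1 and X.shape[1] > 0:
            n_comp = min(n, X.shape[1])
            projections = PCA(n_components=n_comp).fit_transform(X)  # centers X
            for i in range(n_comp):
                if k >= self.n_clusters_max:
                    break
                c_max = min(self.c_max_per_component, n - 1)
                c, labels = _best_count(
                    projections[:, i], c_max, self.silhouette_threshold,
                    self.random_state, self.n_init,
                )
                if c == 1:
                    break
                counts.append(c)
                assignments.append(labels)
                k *= c

        if assignments:
            composite = np.stack(assignments, axis=1)
            _, labels = np.unique(composite, axis=0, return_inverse=True)
        else:
            labels = np.zeros(n, dtype=np.int64)
        self.labels_ = labels.astype(np.int64)
        self.n_clusters_found_ = int(labels.max()) + 1
        self.per_component_counts_ = counts
        self.components_used_ = len(counts)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


@dataclass
class IterativeKMeansResult:
    """Outcome of iterative k-means mapped back to a pixel grid."""

    label_map: LabelMap
    n_clusters_found: int
    per_component_counts: list[int]
    components_used: int
    labels: np.ndarray


def iterative_kmeans(
    features: np.ndarray,
    K: int,
    pixel_coords: np.ndarray,
    width: int,
    height: int,
    silhouette_threshold: float = 0.7,
    c_max_per_component: int = 10,
    seed: Optional[int] = None,
) -> IterativeKMeansResult:
    """Functional wrapper over :class:`IterativeKMeans` returning a LabelMap."""
    est = IterativeKMeans(
        n_clusters_max=K,
        silhouette_threshold=silhouette_threshold,
        c_max_per_component=c_max_per_component,
        random_state=seed,
    ).fit(np.asarray(features, dtype=np.float64))
    return IterativeKMeansResult(
        label_map=labels_to_map(est.labels_, pixel_coords, width, height),
        n_clusters_found=est.n_clusters_found_,
        per_component_counts=est.per_component_counts_,
        components_used=est.components_used_,
        labels=est.labels_,
    )


def convolutional_smooth(
    label_map: LabelMap, radius: int = 1, iterations: int = 1
) -> LabelMap:
    """Majority-vote label smoothing over a square spatial window.

    Every pixel is reassigned to the most frequent label among itself and its
    occupied neighbors within a ``(2r+1) x (2r+1)`` window; unlabeled pixels
    neither vote nor change.  All updates in one iteration are computed from
    the input map (synchronous update); ties go to the smallest label id.
    """
    if radius < 1:
        raise ValueError("radius must be at least 1")
    labels = label_map.labels.copy()
    present = np.unique(labels[labels != UNLABELED])
    if present.size == 0:
        return label_map.copy()
    kernel = np.ones((2 * radius + 1, 2 * radius + 1))
    for _ in range(iterations):
        counts = np.stack(
            [
                convolve((labels == lab).astype(np.float64), kernel,
                         mode="constant", cval=0.0)
                for lab in present
            ]
        )
        winner = present[np.argmax(counts, axis=0)]  # argmax takes the first
        mask = labels != UNLABELED
        labels = np.where(mask, winner, UNLABELED)
    return LabelMap(labels=labels, provenance=label_map.provenance)


def write_label_map_csv(label_map: LabelMap, path) -> None:
    """Write occupied pixels as (x, y, label) rows in raster order."""
    coords = label_map.occupied_coords()
    pd.DataFrame(
        {
            "x": coords[:, 0],
            "y": coords[:, 1],
            "label": label_map.values_at(coords),
        }
    ).to_csv(path, index=False)


def read_label_map_csv(path, width: Optional[int] = None,
                       height: Optional[int] = None,
                       provenance: str = "prediction") -> LabelMap:
    frame = pd.read_csv(path)
    if width is None:
        width = int(frame["x"].max()) + 1 if len(frame) else 1
    if height is None:
        height = int(frame["y"].max()) + 1 if len(frame) else 1
    grid = np.full((height, width), UNLABELED, dtype=np.int64)
    grid[frame["y"].to_numpy(), frame["x"].to_numpy()] = frame["label"].to_numpy()
    return LabelMap(labels=grid, provenance=provenance)
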