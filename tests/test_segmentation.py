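"""Clustering, silhouette-driven cluster counts and label smoothing."""

from __future__ import annotations

import numpy as np
import pytest

from msicodec import segmentation as seg
from msicodec.types import UNLABELED, BinnedImage, LabelMap


def blob_data(seed: int, n: int = 400, centers=((10, 3), (10, -3), (-10, 3), (-10, -3)),
              spread: float = 0.3) -> tuple[np.ndarray, np.ndarray]:
    """Factorized blobs: the cluster structure splits across the two axes."""
    rng = np.random.default_rng(seed)
    centers = np.asarray(centers, dtype=float)
    which = rng.integers(0, len(centers), size=n)
    return centers[which] + rng.normal(0, spread, size=(n, 2)), which


class TestTopPeakFeatures:
    @pytest.fixture()
    def image(self):
        intensities = np.array([
            [1.0, 9.0, 3.0, 3.0],
            [1.0, 7.0, 3.0, 3.0],
        ])
        return BinnedImage(width=2, height=1, pixel_coords=[[0, 0], [1, 0]],
                           mz_axis=100.0 + np.arange(4) * 0.1,
                           intensities=intensities)

    def test_highest_mean_first(self, image):
        feats = seg.top_peak_features(image, n_peaks=1)
        assert np.array_equal(feats[:, 0], image.intensities[:, 1])

    def test_ties_break_to_lower_mz(self, image):
        feats = seg.top_peak_features(image, n_peaks=4)
        # means: bin1=8, bins 2 and 3 tie at 3, bin0=1
        assert np.array_equal(feats[:, 1], image.intensities[:, 2])
        assert np.array_equal(feats[:, 2], image.intensities[:, 3])

    def test_all_peaks_is_column_permutation(self, image):
        feats = seg.top_peak_features(image, n_peaks=4)
        assert sorted(map(tuple, feats.T)) == sorted(map(tuple, image.intensities.T))

    def test_invalid_counts(self, image):
        with pytest.raises(ValueError):
            seg.top_peak_features(image, n_peaks=0)
        with pytest.raises(ValueError):
            seg.top_peak_features(image, n_peaks=5)


class TestKmeansSegment:
    def test_separable_case_and_degenerate_k(self):
        features = np.array([[0.0], [0.1], [10.0], [10.1]])
        coords = np.array([[0, 0], [1, 0], [0, 1], [1, 1]])
        lm = seg.kmeans_segment(features, 2, coords, 2, 2, seed=0)
        labels = lm.values_at(coords)
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert labels[0] != labels[2]
        one = seg.kmeans_segment(features, 1, coords, 2, 2, seed=0)
        assert len(np.unique(one.values_at(coords))) == 1

    def test_determinism_and_errors(self):
        rng = np.random.default_rng(0)
        features = rng.normal(size=(20, 3))
        coords = np.column_stack([np.arange(20), np.zeros(20, int)])
        a = seg.kmeans_segment(features, 4, coords, 20, 1, seed=1)
        b = seg.kmeans_segment(features, 4, coords, 20, 1, seed=1)
        assert np.array_equal(a.labels, b.labels)
        with pytest.raises(ValueError):
            seg.kmeans_segment(features, 21, coords, 20, 1, seed=0)


class TestBestCount:
    def test_two_tight_clusters(self):
        rng = np.random.default_rng(0)
        values = np.concatenate([rng.normal(0, 0.1, 100), rng.normal(10, 0.1, 100)])
        assert seg.best_count_for_component(values, seed=0) == 2

    def test_single_gaussian_is_structureless(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=200)
        assert seg.best_count_for_component(values, seed=0) == 1

    def test_three_equally_spaced_clusters(self):
        rng = np.random.default_rng(2)
        values = np.concatenate([rng.normal(c, 0.1, 80) for c in (0.0, 5.0, 10.0)])
        assert seg.best_count_for_component(values, c_max=5, seed=0) == 3

    def test_constant_values_give_one(self):
        assert seg.best_count_for_component(np.full(50, 3.0), seed=0) == 1

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        values = np.concatenate([rng.normal(0, 0.1, 60), rng.normal(4, 0.1, 60)])
        c1 = seg.best_count_for_component(values, seed=0)
        c2 = seg.best_count_for_component(values * 1234.5, seed=0)
        assert c1 == c2 == 2


class TestIterativeKMeans:
    def test_target_one_returns_single_cluster_untouched(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 3))
        est = seg.IterativeKMeans(n_clusters_max=1, random_state=0).fit(X)
        assert est.n_clusters_found_ == 1
        assert est.components_used_ == 0
        assert (est.labels_ == 0).all()

    def test_factorized_blobs_recover_planted_partition(self):
        X, truth = blob_data(seed=0)
        est = seg.IterativeKMeans(n_clusters_max=4, random_state=0).fit(X)
        assert est.n_clusters_found_ == 4
        assert est.per_component_counts_ == [2, 2]
        # relabel-invariant agreement with the planted labels
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth, est.labels_) > 0.99

    def test_recovery_is_stable_over_seeds(self):
        hits = sum(
            seg.IterativeKMeans(n_clusters_max=8, random_state=s)
            .fit(blob_data(seed=s)[0]).n_clusters_found_ == 4
            for s in range(10)
        )
        assert hits >= 8

    def test_single_isotropic_blob_stays_one_cluster(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(300, 2))
        est = seg.IterativeKMeans(n_clusters_max=8, random_state=0).fit(X)
        assert est.n_clusters_found_ == 1

    def test_k_exceeding_samples_rejected(self):
        with pytest.raises(ValueError):
            seg.IterativeKMeans(n_clusters_max=10).fit(np.zeros((5, 2)))

    def test_functional_wrapper_builds_label_map(self):
        X, _ = blob_data(seed=1, n=64)
        coords = np.column_stack([np.arange(64) % 8, np.arange(64) // 8])
        result = seg.iterative_kmeans(X, 4, coords, 8, 8, seed=0)
        assert result.n_clusters_found == 4
        assert result.label_map.labels.max() == 3
        assert np.array_equal(result.label_map.values_at(coords), result.labels)


class TestConvolutionalSmooth:
    def test_homogeneous_map_is_fixed_point(self):
        lm = LabelMap(labels=np.full((4, 4), 2))
        out = seg.convolutional_smooth(lm)
        assert np.array_equal(out.labels, lm.labels)

    def test_single_outlier_flipped(self):
        labels = np.zeros((3, 3), dtype=int)
        labels[1, 1] = 5
        out = seg.convolutional_smooth(LabelMap(labels=labels))
        assert out.labels[1, 1] == 0

    def test_two_pixel_tie_goes_to_smallest_label(self):
        lm = LabelMap(labels=np.array([[0, 1]]))
        out = seg.convolutional_smooth(lm)
        assert out.labels.tolist() == [[0, 0]]

    def test_unlabeled_pixels_never_vote_nor_change(self):
        labels = np.array([
            [UNLABELED, 1, 1],
            [UNLABELED, 1, 1],
            [UNLABELED, UNLABELED, UNLABELED],
        ])
        out = seg.convolutional_smooth(LabelMap(labels=labels))
        assert np.array_equal(out.labels, labels)

    def test_never_introduces_new_labels(self):
        rng = np.random.default_rng(5)
        labels = rng.integers(0, 4, size=(10, 10))
        out = seg.convolutional_smooth(LabelMap(labels=labels), iterations=3)
        assert set(np.unique(out.labels)) <= set(np.unique(labels))

    def test_empty_map_passes_through(self):
        lm = LabelMap(labels=np.full((2, 2), UNLABELED))
        out = seg.convolutional_smooth(lm)
        assert np.array_equal(out.labels, lm.labels)


class TestLabelMapCsv:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(6)
        labels = rng.integers(-1, 3, size=(5, 4))
        lm = LabelMap(labels=labels)
        path = tmp_path / "labels.csv"
        seg.write_label_map_csv(lm, path)
        back = seg.read_label_map_csv(path, width=4, height=5)
        assert np.array_equal(back.labels, labels)
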