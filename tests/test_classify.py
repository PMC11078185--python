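"""Feature binarization, KNN classification, embeddings, clustering."""

import numpy as np
import pytest

from cordtrace import ValidationError
from cordtrace import classify as clf


class TestBinarize:
    def test_identical_events_all_zero(self):
        out = clf.binarize(np.full((5, 3), 2.0))
        assert not out.values.any()  # nothing strictly exceeds its own mean

    def test_direct_rule(self):
        out = clf.binarize(np.array([[1.0], [3.0]]))
        np.testing.assert_array_equal(out.values.ravel(), [0.0, 1.0])
        assert out.thresholds[0] == 2.0

    def test_all_zero_map(self):
        assert not clf.binarize(np.zeros((4, 8))).values.any()

    def test_empty_map_rejected(self):
        with pytest.raises(ValidationError):
            clf.binarize(np.empty((0, 4)))


class TestSplit:
    def test_balanced_counts(self):
        labels = ["A"] * 25 + ["B"] * 25 + ["C"] * 25 + ["D"] * 25
        tr, te = clf.split(labels, 0.60, seed=0)
        assert tr.size == 60 and te.size == 40
        for cls in "ABCD":
            assert sum(labels[i] == cls for i in tr) == 15
            assert sum(labels[i] == cls for i in te) == 10
        assert not set(tr) & set(te)
        assert sorted(set(tr) | set(te)) == list(range(100))

    def test_same_seed_same_split(self):
        labels = ["A", "B"] * 10
        assert np.array_equal(clf.split(labels, seed=5)[0], clf.split(labels, seed=5)[0])

    def test_singleton_class_rejected(self):
        with pytest.raises(ValidationError, match="need >= 2"):
            clf.split(["A", "A", "B"], 0.6, seed=0)


class TestKNN:
    def test_training_set_self_prediction(self, rng):
        x = rng.normal(size=(20, 8))
        labels = ["A", "B"] * 10
        res = clf.knn_classify(x, labels, x, labels, k=1)
        assert res.accuracy == 1.0

    def test_l1_metric_definition(self):
        res = clf.knn_classify(
            np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 1.0]]),
            ["near", "far"],
            np.array([[0.0, 0.0, 1.0]]),
        )
        # d(test, near) = 2, d(test, far) = 1 under city block
        assert res.predictions == ["far"]

    def test_matches_brute_force_oracle(self, rng):
        """Predictions equal an exhaustive nearest-neighbour scan."""
        x_train = rng.integers(0, 2, size=(120, 16)).astype(float)
        y_train = [f"C{i % 4}" for i in range(120)]
        x_test = rng.integers(0, 2, size=(60, 16)).astype(float)
        res = clf.knn_classify(x_train, y_train, x_test, k=1)
        from collections import Counter

        for i, row in enumerate(x_test):
            d = [sum(abs(a - b) for a, b in zip(row, tr)) for tr in x_train]
            dmin = min(d)
            tied = [y_train[j] for j, dj in enumerate(d) if dj == dmin]
            counts = Counter(tied)
            top = max(counts.values())
            # vote ties all sit at the same distance here, so the rule
            # reduces to the lowest class label among the top-voted
            expected = sorted(c for c, v in counts.items() if v == top)[0]
            assert res.predictions[i] == expected

    def test_channel_permutation_invariance(self, rng):
        x_train = rng.normal(size=(30, 10))
        y = ["A", "B", "C"] * 10
        x_test = rng.normal(size=(12, 10))
        perm = rng.permutation(10)
        a = clf.knn_classify(x_train, y, x_test, k=1)
        b = clf.knn_classify(x_train[:, perm], y, x_test[:, perm], k=1)
        assert a.predictions == b.predictions

    def test_dimension_mismatch(self):
        with pytest.raises(ValidationError):
            clf.knn_classify(np.zeros((2, 3)), ["A", "B"], np.zeros((1, 4)))

    def test_confusion_matrix_accounting(self):
        res = clf.score(["A", "A", "B", "B"], ["A", "B", "B", "B"])
        assert res.confusion.sum() == 4
        assert res.accuracy == 0.75
        assert res.per_class_loss["A"] == 0.5
        np.testing.assert_array_equal(res.confusion.sum(axis=1), [2, 2])


class TestPCA:
    def test_one_axis_data(self, rng):
        direction = np.array([1.0, 2.0, -1.0])
        x = rng.normal(size=(50, 1)) * direction[None, :]
        out = clf.reduce_pca(x, 2)
        assert out.explained_variance_ratio_[0] == pytest.approx(1.0)

    def test_variance_matches_eigendecomposition(self, rng):
        x = rng.normal(size=(200, 6)) @ rng.normal(size=(6, 6))
        out = clf.reduce_pca(x, 6)
        cov = np.cov(x - x.mean(axis=0), rowvar=False)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        np.testing.assert_allclose(
            out.explained_variance_ratio_, eig / eig.sum(), atol=1e-10
        )

    def test_full_rank_reconstruction(self, rng):
        x = rng.normal(size=(40, 5))
        out = clf.reduce_pca(x, 5)
        recon = out.model_.inverse_transform(out.values)
        np.testing.assert_allclose(recon, x, atol=1e-10)

    def test_bad_components(self, rng):
        with pytest.raises(ValidationError):
            clf.reduce_pca(np.zeros((5, 3)), 0)


class TestUMAP:
    def test_separated_clusters_stay_separated(self, rng):
        pytest.importorskip("umap")
        a = rng.normal(0, 0.1, size=(30, 8))
        b = rng.normal(5, 0.1, size=(30, 8))
        out = clf.reduce_umap(np.vstack([a, b]), 2, seed=0)
        from sklearn.metrics import silhouette_score

        labels = [0] * 30 + [1] * 30
        assert silhouette_score(out.values, labels) > 0.5


class TestCluster:
    def test_two_point_masses_perfect(self):
        x = np.vstack([np.zeros((10, 4)), np.ones((10, 4))])
        labels = ["lo"] * 10 + ["hi"] * 10
        _, agreement = clf.cluster(x, 2, seed=0, true_labels=labels)
        assert agreement == 1.0

    @pytest.mark.parametrize("method", ["kmedoids", "kmeans"])
    def test_four_separated_clusters(self, method, rng):
        centers = np.eye(4) * 6
        x = np.vstack([c + rng.normal(0, 0.3, size=(15, 4)) for c in centers])
        labels = [f"C{i}" for i in range(4) for _ in range(15)]
        _, agreement = clf.cluster(x, 4, seed=1, true_labels=labels, method=method)
        assert agreement >= 0.95

    def test_single_cluster_rejected(self):
        with pytest.raises(ValidationError):
            clf.cluster(np.zeros((5, 2)), 1)

    def test_hungarian_agreement_handles_permuted_ids(self):
        assign = np.array([1, 1, 0, 0])
        assert clf.label_agreement(assign, ["x", "x", "y", "y"]) == 1.0
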