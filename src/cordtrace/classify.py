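"""Evoked-source classification: features, KNN, embeddings, clustering.

Features are per-event, per-channel peak ECAP amplitudes, binarized at
each channel's mean peak amplitude.  Supervised classification is
k-nearest neighbours (k = 1, city-block distance) on a stratified 60/40
train/test split.  Unsupervised grouping is exemplar-based (k-medoids
under the same city-block metric, with k-means as an alternative),
scored against the true labels after Hungarian matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .types import ValidationError


@dataclass
class FeatureMatrix:
    """Events x channels feature array plus its provenance."""

    values: np.ndarray
    representation: str  # "binary" | "continuous" | "embedded"
    thresholds: np.ndarray | None = None

    @property
    def n_events(self) -> int:
        return self.values.shape[0]


@dataclass
class ClassificationResult:
    """Confusion matrix and derived accuracy for one train/test split."""

    classes: list[str]
    confusion: np.ndarray  # true x predicted counts
    accuracy: float
    per_class_loss: dict[str, float] = field(default_factory=dict)
    predictions: list[str] = field(default_factory=list)


def binarize(peak_map: np.ndarray) -> FeatureMatrix:
    """Threshold each channel at its mean peak amplitude.

    feature(e, c) = 1 if amplitude(e, c) strictly exceeds channel c's
    mean over events, else 0 (ties at the mean map to 0).
    """
    peak_map = np.asarray(peak_map, dtype=float)
    if peak_map.ndim != 2 or peak_map.shape[0] < 1:
        raise ValidationError("peak-amplitude map must be a non-empty events x channels array")
    thresholds = peak_map.mean(axis=0)
    values = (peak_map > thresholds[None, :]).astype(float)
    return FeatureMatrix(values=values, representation="binary", thresholds=thresholds)


def split(
    labels: list[str],
    train_fraction: float = 0.60,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified random train/test split of event indices.

    Each class contributes ``round(train_fraction * n_class)`` events to
    the training set (at least 1, never all); indices are disjoint and
    exhaustive.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValidationError("train_fraction must lie in (0, 1)")
    labels = list(labels)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls in sorted(set(labels)):
        idx = np.nonzero([l == cls for l in labels])[0]
        if idx.size < 2:
            raise ValidationError(f"class {cls!r} has {idx.size} event(s); need >= 2 to split")
        n_train = int(round(train_fraction * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)
        perm = rng.permutation(idx)
        train.extend(perm[:n_train])
        test.extend(perm[n_train:])
    return np.sort(np.asarray(train)), np.sort(np.asarray(test))


def knn_classify(
    train: np.ndarray,
    train_labels: list[str],
    test: np.ndarray,
    test_labels: list[str] | None = None,
    k: int = 1,
    metric: str = "cityblock",
) -> ClassificationResult:
    """K-nearest-neighbour prediction under the city-block (L1) metric.

    Each test event takes the majority label among its k nearest training
    events; ties are broken by the smaller summed distance of the tied
    classes' neighbours, then by the lower class index (sorted order).
    """
    train = np.asarray(train, dtype=float)
    test = np.asarray(test, dtype=float)
    if train.shape[0] == 0:
        raise ValidationError("training set is empty")
    if train.shape[1] != test.shape[1]:
        raise ValidationError("train/test feature dimensions differ")
    if k < 1:
        raise ValidationError("k must be >= 1")
    classes = sorted(set(train_labels))
    class_index = {c: i for i, c in enumerate(classes)}
    y = np.asarray([class_index[l] for l in train_labels])
    d = cdist(test, train, metric=metric)
    preds = []
    for row in d:
        order = np.argsort(row, kind="stable")
        # include every neighbour tied with the k-th distance, so the
        # outcome does not depend on training-set ordering
        kth = row[order[min(k, order.size) - 1]]
        nn = order[row[order] <= kth]
        votes = np.bincount(y[nn], minlength=len(classes))
        best = np.nonzero(votes == votes.max())[0]
        if best.size > 1:
            sums = np.asarray([row[nn[y[nn] == b]].sum() for b in best])
            best = best[sums == sums.min()]
        preds.append(classes[best[0]])
    if test_labels is None:
        return ClassificationResult(
            classes=classes, confusion=np.zeros((0, 0), dtype=int),
            accuracy=float("nan"), predictions=preds,
        )
    return score(list(test_labels), preds, classes)


def score(
    true_labels: list[str],
    predictions: list[str],
    classes: list[str] | None = None,
) -> ClassificationResult:
    """Confusion matrix (true x predicted), accuracy, per-class loss."""
    if classes is None:
        classes = []
    classes = sorted(set(classes) | set(true_labels) | set(predictions))
    idx = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(true_labels, predictions):
        cm[idx[t], idx[p]] += 1
    total = cm.sum()
    acc = float(np.trace(cm) / total) if total else float("nan")
    loss = {}
    for c in classes:
        row = cm[idx[c]]
        loss[c] = float(1.0 - row[idx[c]] / row.sum()) if row.sum() else float("nan")
    return ClassificationResult(
        classes=classes, confusion=cm, accuracy=acc, per_class_loss=loss,
        predictions=list(predictions),
    )


def reduce_pca(features: np.ndarray, n_components: int) -> FeatureMatrix:
    """Principal-component projection maximising retained variance."""
    from sklearn.decomposition import PCA

    features = np.asarray(features, dtype=float)
    if n_components <= 0:
        raise ValidationError("n_components must be positive")
    if n_components > features.shape[1]:
        raise ValidationError("n_components exceeds the feature dimension")
    model = PCA(n_components=n_components, svd_solver="full")
    emb = model.fit_transform(features)
    out = FeatureMatrix(values=emb, representation="embedded")
    out.explained_variance_ratio_ = model.explained_variance_ratio_
    out.model_ = model
    return out


def reduce_umap(features: np.ndarray, n_components: int = 2, seed: int = 0) -> FeatureMatrix:
    """UMAP nonlinear embedding (requires the optional umap-learn extra)."""
    try:
        import umap
    except ImportError as exc:
        raise ImportError(
            "umap-learn is not installed; install the 'umap' extra or use "
            "reduce_pca for a linear embedding instead"
        ) from exc
    reducer = umap.UMAP(n_components=n_components, random_state=seed)
    emb = reducer.fit_transform(np.asarray(features, dtype=float))
    return FeatureMatrix(values=np.asarray(emb, dtype=float), representation="embedded")


def _maximin_seeds(d: np.ndarray, n_clusters: int, first: int) -> np.ndarray:
    seeds = [first]
    for _ in range(n_clusters - 1):
        seeds.append(int(np.argmax(d[:, seeds].min(axis=1))))
    return np.asarray(seeds)


def _kmedoids_once(d: np.ndarray, medoids: np.ndarray, n_iter: int = 100):
    n_clusters = medoids.size
    for _ in range(n_iter):
        assign = np.argmin(d[:, medoids], axis=1)
        new = medoids.copy()
        for j in range(n_clusters):
            members = np.nonzero(assign == j)[0]
            if members.size == 0:
                new[j] = int(np.argmax(d[:, medoids].min(axis=1)))
                continue
            costs = d[np.ix_(members, members)].sum(axis=0)
            new[j] = members[int(np.argmin(costs))]
        if np.array_equal(np.sort(new), np.sort(medoids)):
            break
        medoids = new
    assign = np.argmin(d[:, medoids], axis=1)
    return assign, float(d[np.arange(d.shape[0]), medoids[assign]].sum())


def _kmedoids_l1(
    x: np.ndarray, n_clusters: int, seed: int, n_restarts: int = 8
) -> np.ndarray:
    """Alternating k-medoids under the city-block metric.

    One deterministic maximin (farthest-point) initialisation plus seeded
    random restarts; the partition with the lowest total within-cluster
    distance wins.
    """
    rng = np.random.default_rng(seed)
    n = x.shape[0]
    d = cdist(x, x, metric="cityblock")
    inits = [_maximin_seeds(d, n_clusters, int(np.argmin(d.sum(axis=1))))]
    for _ in range(n_restarts):
        inits.append(rng.choice(n, size=n_clusters, replace=False))
    best_assign, best_cost = None, np.inf
    for init in inits:
        assign, cost = _kmedoids_once(d, np.asarray(init))
        if cost < best_cost:
            best_assign, best_cost = assign, cost
    return best_assign


def cluster(
    features: np.ndarray,
    n_clusters: int,
    seed: int = 0,
    true_labels: list[str] | None = None,
    method: str = "kmedoids",
) -> tuple[np.ndarray, float | None]:
    """Partition events into ``n_clusters`` groups.

    ``method="kmedoids"`` (default) is exemplar-based under the
    city-block metric; ``method="kmeans"`` delegates to scikit-learn.
    If ``true_labels`` is given, returns the agreement after optimal
    cluster-to-label matching (Hungarian assignment on the contingency
    table); otherwise agreement is None.
    """
    features = np.asarray(features, dtype=float)
    if n_clusters < 2:
        raise ValidationError("n_clusters must be >= 2")
    if n_clusters > features.shape[0]:
        raise ValidationError("more clusters than events")
    if method == "kmedoids":
        assign = _kmedoids_l1(features, n_clusters, seed)
    elif method == "kmeans":
        from sklearn.cluster import KMeans

        assign = KMeans(n_clusters=n_clusters, random_state=seed, n_init=10).fit_predict(features)
    else:
        raise ValidationError(f"unknown clustering method: {method!r}")
    agreement = None
    if true_labels is not None:
        agreement = label_agreement(assign, list(true_labels))
    return assign, agreement


def label_agreement(assignments: np.ndarray, true_labels: list[str]) -> float:
    """Best-case accuracy of a clustering against reference labels.

    Builds the cluster x class contingency table and solves the optimal
    one-to-one matching with the Hungarian algorithm.
    """
    classes = sorted(set(true_labels))
    idx = {c: i for i, c in enumerate(classes)}
    n_clusters = int(np.max(assignments)) + 1
    table = np.zeros((n_clusters, len(classes)), dtype=int)
    for a, l in zip(assignments, true_labels):
        table[a, idx[l]] += 1
    r, c = linear_sum_assignment(-table)
    return float(table[r, c].sum() / len(true_labels))
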