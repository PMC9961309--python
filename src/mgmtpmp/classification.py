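"""k-NN and SVM classifiers plus stratified Jackknife K-fold cross-validation.

The k-NN implements the exact voting semantics used for the hybrid feature
set: majority vote over the k nearest (k odd, default 1), or
inverse-distance-weighted voting V(y) = sum 1/d^z over matching neighbors;
vote ties break toward the nearest neighbor, and a zero-distance neighbor
under weighted voting decides directly (infinite weight).  Distances:
standard Euclidean (default), Minkowski(r), Chebyshev, Mahalanobis, plus
two printed variants kept for replication ('euclidean-printed', scaling by
1/sqrt(k) inside the radical, and 'chebyshev-as-printed', the max-difference
formula the source tables label chi-square).

Cross-validation is stratified: within-class seeded shuffle, round-robin
fold assignment (per-class fold counts differ by at most 1), aggregate
accuracy reported as mean +- sample sd over the K folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .evaluation import (
    MetricsReport,
    aggregate_fold_metrics,
    compute_metrics,
    confusion_counts,
    roc_auc,
)
from .rejection import round_half_up

KNN_DISTANCES = (
    "euclidean",
    "minkowski",
    "chebyshev-as-printed",
    "mahalanobis",
    "euclidean-printed",
)


def minkowski_distance(q: np.ndarray, x: np.ndarray, r: float) -> float:
    """(sum |q_i - x_i|^r)^(1/r); r=2 is Euclidean, r -> inf the max norm."""
    q, x = np.asarray(q, dtype=np.float64), np.asarray(x, dtype=np.float64)
    if q.shape != x.shape:
        raise ValueError("vectors must have equal length")
    if r < 1:
        raise ValueError("Minkowski order r must be >= 1")
    return float((np.abs(q - x) ** r).sum() ** (1.0 / r))


@dataclass
class KNNConfig:
    k: int = 1
    distance: str = "euclidean"
    minkowski_r: float = 2.0
    vote: str = "majority"  # or "weighted"
    weight_exponent: float = 2.0

    def __post_init__(self) -> None:
        if self.k < 1 or self.k % 2 == 0:
            raise ValueError("k must be a positive odd integer")
        if self.distance not in KNN_DISTANCES:
            raise ValueError(f"distance must be one of {KNN_DISTANCES}")
        if self.minkowski_r < 1:
            raise ValueError("Minkowski order must be >= 1")
        if self.vote not in ("majority", "weighted"):
            raise ValueError("vote must be 'majority' or 'weighted'")


class KNNClassifier:
    """Instance-based classifier; ``fit`` just stores the training set."""

    def __init__(self, cfg: KNNConfig | None = None):
        self.cfg = cfg or KNNConfig()
        self._x = None
        self._y = None
        self._vi = None  # inverse covariance for Mahalanobis

    def fit(self, x: np.ndarray, y: np.ndarray) -> "KNNClassifier":
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y, dtype=np.int64)
        if len(x) < self.cfg.k:
            raise ValueError(f"k={self.cfg.k} exceeds training size {len(x)}")
        self._x, self._y = x, y
        if self.cfg.distance == "mahalanobis":
            cov = np.cov(x, rowvar=False)
            cov = np.atleast_2d(cov) + 1e-6 * np.eye(x.shape[1])
            self._vi = np.linalg.inv(cov)
        return self

    def _distances(self, q: np.ndarray) -> np.ndarray:
        cfg = self.cfg
        if cfg.distance == "mahalanobis":
            return cdist(q, self._x, metric="mahalanobis", VI=self._vi)
        if cfg.distance == "chebyshev-as-printed":
            return cdist(q, self._x, metric="chebyshev")
        if cfg.distance == "minkowski":
            return cdist(q, self._x, metric="minkowski", p=cfg.minkowski_r)
        d = cdist(q, self._x, metric="euclidean")
        if cfg.distance == "euclidean-printed":
            d /= np.sqrt(cfg.k)
        return d

    def predict(self, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(labels, scores) for query rows; score = positive-class vote share."""
        if self._x is None:
            raise RuntimeError("classifier is not fitted")
        q = np.atleast_2d(np.asarray(q, dtype=np.float64))
        d = self._distances(q)
        k = self.cfg.k
        nn = np.argpartition(d, k - 1, axis=1)[:, :k]
        rowd = np.take_along_axis(d, nn, axis=1)
        order = np.argsort(rowd, axis=1, kind="stable")
        nn = np.take_along_axis(nn, order, axis=1)
        rowd = np.take_along_axis(rowd, order, axis=1)
        labels = self._y[nn]

        out_y = np.empty(len(q), dtype=np.int64)
        out_s = np.empty(len(q), dtype=np.float64)
        for i in range(len(q)):
            out_y[i], out_s[i] = self._vote(labels[i], rowd[i])
        return out_y, out_s

    def _vote(self, labels: np.ndarray, dists: np.ndarray) -> tuple[int, float]:
        if self.cfg.vote == "weighted":
            zero = dists == 0
            if zero.any():
                lab = int(labels[zero][0])  # infinite weight: nearest exact match
                return lab, float(lab)
            w = 1.0 / dists ** self.cfg.weight_exponent
        else:
            w = np.ones_like(dists)
        votes = np.array([w[labels == 0].sum(), w[labels == 1].sum()])
        if votes[0] == votes[1]:
            lab = int(labels[0])  # tie broken by the nearest neighbor
        else:
            lab = int(votes.argmax())
        return lab, float(votes[1] / votes.sum())


def knn_predict(train_x, train_y, q, cfg: KNNConfig | None = None):
    """One-shot k-NN: (label, score) for a single query vector."""
    clf = KNNClassifier(cfg).fit(train_x, train_y)
    y, s = clf.predict(np.atleast_2d(q))
    return int(y[0]), float(s[0])


@dataclass
class SVMConfig:
    kernel: str = "rbf"  # linear | rbf | poly2 | poly3 | poly4
    c: float = 1.0
    gamma: str | float = "scale"
    coef0: float = 1.0

    def __post_init__(self) -> None:
        if self.kernel not in ("linear", "rbf", "poly2", "poly3", "poly4"):
            raise ValueError(f"unsupported kernel {self.kernel!r}")
        if self.c <= 0:
            raise ValueError("regularization strength must be > 0")


class SVMClassifier:
    """Soft-margin kernel SVM (backed by sklearn); score = decision value."""

    def __init__(self, cfg: SVMConfig | None = None):
        self.cfg = cfg or SVMConfig()
        self._model = None

    def fit(self, x: np.ndarray, y: np.ndarray) -> "SVMClassifier":
        from sklearn.svm import SVC

        y = np.asarray(y, dtype=np.int64)
        if len(np.unique(y)) < 2:
            raise ValueError("SVM training needs both classes present")
        cfg = self.cfg
        if cfg.kernel.startswith("poly"):
            kw = dict(kernel="poly", degree=int(cfg.kernel[4:]), coef0=cfg.coef0)
        else:
            kw = dict(kernel=cfg.kernel)
        self._model = SVC(C=cfg.c, gamma=cfg.gamma, **kw)
        self._model.fit(np.asarray(x, dtype=np.float64), y)
        return self

    @property
    def support_vectors_(self):
        return self._model.support_vectors_

    def predict(self, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if self._model is None:
            raise RuntimeError("classifier is not fitted")
        q = np.atleast_2d(np.asarray(q, dtype=np.float64))
        score = self._model.decision_function(q)
        return (score > 0).astype(np.int64), score


def svm_train(x, y, cfg: SVMConfig | None = None) -> SVMClassifier:
    return SVMClassifier(cfg).fit(x, y)


def svm_predict(model: SVMClassifier, q):
    y, s = model.predict(np.atleast_2d(q))
    return int(y[0]), float(s[0])


def make_classifier(name: str, **kwargs):
    """Classifier factory: 'knn' or 'svm' with their config fields as kwargs."""
    if name == "knn":
        return KNNClassifier(KNNConfig(**kwargs))
    if name == "svm":
        return SVMClassifier(SVMConfig(**kwargs))
    raise ValueError(f"unknown classifier {name!r}")


# ---------------------------------------------------------------------------
# stratified folds and cross-validation


@dataclass
class FoldPlan:
    folds: list  # list of index arrays, one per fold

    def __post_init__(self) -> None:
        all_idx = np.concatenate(self.folds)
        if len(np.unique(all_idx)) != len(all_idx):
            raise ValueError("folds overlap")

    @property
    def k(self) -> int:
        return len(self.folds)

    def train_test(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        test = self.folds[i]
        train = np.concatenate([f for j, f in enumerate(self.folds) if j != i])
        return train, test


def stratified_folds(labels: Sequence[int], k: int = 10, seed: int = 0) -> FoldPlan:
    """Seeded within-class shuffle, round-robin assignment into k folds."""
    y = np.asarray(labels, dtype=np.int64)
    if k < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < k:
            raise ValueError(
                f"class {cls} has only {len(idx)} members; cannot stratify "
                f"into {k} folds"
            )
        idx = rng.permutation(idx)
        for pos, sample in enumerate(idx):
            folds[pos % k].append(int(sample))
    return FoldPlan([np.array(sorted(f), dtype=np.int64) for f in folds])


def stratified_split_counts(class_sizes: dict, train_frac: float = 0.8) -> dict:
    """Per-class train/test sizes for a stratified split, rounded half-up.

    Pure bookkeeping on class totals (no data needed); the train count per
    class is round(train_frac * n).
    """
    out = {"train": {}, "test": {}}
    for cls, n in class_sizes.items():
        tr = int(round_half_up(train_frac * n, 0))
        out["train"][cls] = tr
        out["test"][cls] = n - tr
    out["train_total"] = sum(out["train"].values())
    out["test_total"] = sum(out["test"].values())
    return out


def stratified_split(labels, train_frac: float = 0.8, seed: int = 0):
    """(train_idx, test_idx) stratified 80:20-style split, seeded."""
    y = np.asarray(labels, dtype=np.int64)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == cls))
        n_tr = int(round_half_up(train_frac * len(idx), 0))
        train.extend(idx[:n_tr])
        test.extend(idx[n_tr:])
    return np.array(sorted(train)), np.array(sorted(test))


@dataclass
class FoldResults:
    fold_metrics: list = field(default_factory=list)  # MetricsReport per fold
    fold_confusions: list = field(default_factory=list)

    @property
    def accuracies(self) -> np.ndarray:
        return np.array([m.accuracy for m in self.fold_metrics])

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def accuracy_sd(self) -> float:
        a = self.accuracies
        return float(a.std(ddof=1)) if len(a) > 1 else 0.0

    def aggregate(self) -> dict:
        return aggregate_fold_metrics(self.fold_metrics)

    def to_dict(self) -> dict:
        return {
            "folds": [
                {"confusion": c.to_dict(), "metrics": m.to_dict()}
                for c, m in zip(self.fold_confusions, self.fold_metrics)
            ],
            "aggregate": self.aggregate(),
        }


def evaluate_fold(y_true, y_pred, scores=None) -> tuple:
    """(ConfusionCounts, MetricsReport) for one held-out fold."""
    c = confusion_counts(y_true, y_pred)
    auc = None
    if scores is not None and len(np.unique(y_true)) == 2:
        auc = roc_auc(y_true, scores)
    return c, compute_metrics(c, auc=auc)


def cross_validate_fn(
    labels: Sequence[int],
    fold_fn: Callable[[np.ndarray, np.ndarray], tuple],
    k: int = 10,
    seed: int = 0,
) -> FoldResults:
    """Generic stratified K-fold driver.

    ``fold_fn(train_idx, test_idx)`` must return (y_pred, scores) for the
    test indices — it owns fitting, normalization and any per-fold feature
    building, so nothing from a held-out fold can leak into it.
    """
    y = np.asarray(labels, dtype=np.int64)
    plan = stratified_folds(y, k, seed)
    results = FoldResults()
    for i in range(plan.k):
        train_idx, test_idx = plan.train_test(i)
        y_pred, scores = fold_fn(train_idx, test_idx)
        c, m = evaluate_fold(y[test_idx], y_pred, scores)
        results.fold_confusions.append(c)
        results.fold_metrics.append(m)
    return results


def cross_validate(
    x: np.ndarray,
    y: Sequence[int],
    classifier_factory: Callable[[], object],
    k: int = 10,
    seed: int = 0,
    normalize: bool = True,
) -> FoldResults:
    """Stratified K-fold CV of a classifier on a fixed feature matrix.

    Min-max normalization (when enabled) is fit on each training fold only.
    """
    from .fusion import apply_minmax, fit_minmax

    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)

    def fold_fn(train_idx, test_idx):
        xtr, xte = x[train_idx], x[test_idx]
        if normalize:
            model = fit_minmax(xtr)
            xtr, xte = apply_minmax(model, xtr), apply_minmax(model, xte)
        clf = classifier_factory()
        clf.fit(xtr, y[train_idx])
        return clf.predict(xte)

    return cross_validate_fn(y, fold_fn, k, seed)
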