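"""ML usefulness of a sub-table: CV classification accuracy, clustering
silhouette, and their equal-weight average.

Classification averages a 20-tree random forest and a hinge-loss SGD linear
model (features standardized for the SGD model only) over stratified
cross-validation.  Clustering averages the clamped mean silhouette of
k-means and Ward agglomerative clusterings into as many clusters as there
are label classes.  Missing cells are median-imputed per column first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import SGDClassifier
from sklearn.metrics import silhouette_score
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .metrics import _median_impute

if TYPE_CHECKING:  # pragma: no cover
    from .io import MasterTable, SearchConfig


@dataclass(frozen=True)
class AccuracyRecord:
    """Classification, clustering, and combined accuracy, all in [0, 1]."""

    classification_accuracy: float
    clustering_accuracy: float
    combined_accuracy: float

    def __post_init__(self) -> None:
        for value in (
            self.classification_accuracy,
            self.clustering_accuracy,
            self.combined_accuracy,
        ):
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"accuracy {value} outside [0, 1]")
        expected = (self.classification_accuracy + self.clustering_accuracy) / 2.0
        if abs(self.combined_accuracy - expected) > 1e-12:
            raise ValueError("combined accuracy must be the mean of the other two")


def _effective_folds(labels: np.ndarray, cv_folds: int) -> int:
    _, counts = np.unique(labels, return_counts=True)
    return max(2, min(cv_folds, int(counts.min())))


def classification_accuracy(
    features: np.ndarray,
    labels: np.ndarray,
    config: "SearchConfig",
    rng: np.random.Generator,
) -> float:
    """Mean stratified-CV accuracy of the forest and SGD classifiers."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("classification needs at least 2 classes")
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 members for CV")
    features = _median_impute(np.asarray(features, dtype=float))

    seed = int(rng.integers(2**31 - 1))
    folds = StratifiedKFold(
        n_splits=_effective_folds(labels, config.cv_folds),
        shuffle=True,
        random_state=seed,
    )
    forest = RandomForestClassifier(
        n_estimators=config.n_estimators, random_state=seed
    )
    sgd = make_pipeline(
        StandardScaler(), SGDClassifier(loss="hinge", random_state=seed)
    )
    scores = [
        float(cross_val_score(model, features, labels, cv=folds).mean())
        for model in (forest, sgd)
    ]
    return float(np.mean(scores))


def _clamped_silhouette(features: np.ndarray, assignment: np.ndarray) -> float:
    """Mean silhouette clamped to [0, 1]; degenerate clusterings score 0."""
    if len(np.unique(assignment)) < 2:
        return 0.0
    return max(0.0, float(silhouette_score(features, assignment)))


def clustering_accuracy(
    features: np.ndarray,
    labels: np.ndarray,
    config: "SearchConfig",
    rng: np.random.Generator,
) -> float:
    """Average clamped mean silhouette of k-means and Ward clusterings.

    The cluster count is the number of distinct labels; the silhouette is
    computed on the same imputed, unstandardized matrix that was clustered.
    """
    labels = np.asarray(labels)
    n_clusters = len(np.unique(labels))
    if n_clusters < 2:
        raise ValueError("clustering accuracy needs at least 2 label classes")
    features = _median_impute(np.asarray(features, dtype=float))
    if features.shape[0] < n_clusters + 1:
        raise ValueError("clustering accuracy needs at least n_clusters + 1 rows")

    seed = int(rng.integers(2**31 - 1))
    scores = []
    for algorithm in (
        KMeans(n_clusters=n_clusters, n_init=10, random_state=seed),
        AgglomerativeClustering(n_clusters=n_clusters, linkage="ward"),
    ):
        try:
            assignment = algorithm.fit_predict(features)
            scores.append(_clamped_silhouette(features, assignment))
        except ValueError:
            scores.append(0.0)  # degenerate geometry contributes zero
    return float(np.mean(scores))


def combined_accuracy(classification: float, clustering: float) -> float:
    """Equal-weight mean of the two accuracy signals."""
    for value in (classification, clustering):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"accuracy {value} outside [0, 1]")
    return (classification + clustering) / 2.0


def evaluate_subtable(
    table: "MasterTable", config: "SearchConfig", rng: np.random.Generator
) -> AccuracyRecord:
    """Full accuracy record for one (sub-)table; deterministic given rng state."""
    clf = classification_accuracy(table.features, table.labels, config, rng)
    clu = clustering_accuracy(table.features, table.labels, config, rng)
    return AccuracyRecord(
        classification_accuracy=clf,
        clustering_accuracy=clu,
        combined_accuracy=combined_accuracy(clf, clu),
    )
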