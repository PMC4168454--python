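"""Leaf/stem point classification on surface feature histograms.

An RBF-kernel SVM separates the two organ classes; salt-and-pepper
misclassifications are then cleaned up by region growing, which absorbs
small connected same-label regions into their dominant neighbour region.
Accuracy is reported per class (recall) and as the point-count-weighted
mean over classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import GridSearchCV, cross_val_score
from sklearn.svm import SVC

from .cloud import LABEL_NAMES, UNKNOWN, PointCloud
from .errors import ConfigError
from .features import FeatureHistogram, FeatureParams, histogram_matrix


class OrganClassifier(BaseEstimator, ClassifierMixin):
    """RBF-kernel SVM over per-point surface feature histograms.

    Parameters
    ----------
    C, gamma : SVC hyperparameters used when ``hyper_search`` is off.
    hyper_search : bool
        Grid-search C in {1, 10, 100} and gamma in {0.1, 1, 10} with
        stratified cross-validation on the training histograms.
    cv : folds for the grid search.
    feature_params : FeatureParams, optional
        Configuration the histograms were computed with; recorded so that
        application time can verify a matching setup.
    """

    def __init__(self, C: float = 10.0, gamma="scale", hyper_search: bool = False,
                 cv: int = 5, feature_params: FeatureParams | None = None):
        self.C = C
        self.gamma = gamma
        self.hyper_search = hyper_search
        self.cv = cv
        self.feature_params = feature_params

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be a 2D histogram matrix")
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("training requires at least two organ classes")
        if counts.min() < 10:
            raise ValueError("training requires >= 10 samples per class")
        if self.hyper_search:
            grid = GridSearchCV(
                SVC(kernel="rbf"),
                {"C": [1.0, 10.0, 100.0], "gamma": [0.1, 1.0, 10.0]},
                cv=self.cv, n_jobs=1)
            grid.fit(X, y)
            self.svm_ = grid.best_estimator_
            self.best_params_ = grid.best_params_
        else:
            self.svm_ = SVC(kernel="rbf", C=self.C, gamma=self.gamma).fit(X, y)
            self.best_params_ = {"C": self.C, "gamma": self.gamma}
        self.classes_ = self.svm_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise ConfigError(
                f"histogram length {X.shape[1]} does not match the "
                f"trained configuration ({self.n_features_in_})")
        return self.svm_.predict(X)

    def cross_val_accuracy(self, X, y, cv: int | None = None) -> float:
        return float(np.mean(cross_val_score(
            SVC(kernel="rbf", C=self.C, gamma=self.gamma), X, y,
            cv=cv or self.cv)))


def train(histograms: list[FeatureHistogram], labels,
          hyper_search: bool = False,
          feature_params: FeatureParams | None = None) -> OrganClassifier:
    """Train an :class:`OrganClassifier` on valid histograms only."""
    X, valid = histogram_matrix(histograms)
    y = np.asarray(labels)
    if len(y) != len(X):
        raise ValueError("labels must match histograms in length")
    keep = valid & (y != UNKNOWN)
    model = OrganClassifier(hyper_search=hyper_search,
                            feature_params=feature_params)
    return model.fit(X[keep], y[keep])


def classify(model: OrganClassifier, histograms: list[FeatureHistogram]) -> np.ndarray:
    """One organ tag per histogram; invalid histograms are tagged unknown."""
    X, valid = histogram_matrix(histograms)
    out = np.full(len(X), UNKNOWN, dtype=np.int64)
    if valid.any():
        out[valid] = model.predict(X[valid])
    return out


def save_model(model: OrganClassifier, path: str | Path) -> None:
    joblib.dump(model, path)


def load_model(path: str | Path) -> OrganClassifier:
    model = joblib.load(path)
    if not isinstance(model, OrganClassifier):
        raise ConfigError(f"{path} does not contain an OrganClassifier")
    return model


# ---------------------------------------------------------------------------
# Region growing refinement
# ---------------------------------------------------------------------------

def region_grow_refine(cloud: PointCloud, connect_radius: float = 2.0,
                       min_region: int = 50, max_iter: int = 20) -> PointCloud:
    """Absorb small connected same-label regions into their neighbours.

    Connectivity is the Euclidean radius graph at ``connect_radius``.
    Components smaller than ``min_region`` points are relabeled to the
    majority label among their boundary neighbours (ties broken toward the
    label of the largest adjacent component); the pass repeats until stable.
    Never invents a label that is not already present.
    """
    if cloud.labels is None:
        raise ValueError("region growing requires labels")
    labels = cloud.labels.copy()
    n = len(labels)
    if n == 0:
        return cloud
    tree = cKDTree(cloud.points)
    pairs = tree.query_pairs(connect_radius, output_type="ndarray")
    for _ in range(max_iter):
        if len(pairs) == 0:
            break
        same = labels[pairs[:, 0]] == labels[pairs[:, 1]]
        sp = pairs[same]
        graph = csr_matrix((np.ones(len(sp)), (sp[:, 0], sp[:, 1])), shape=(n, n))
        _, comp = connected_components(graph, directed=False)
        sizes = np.bincount(comp)
        small = set(np.flatnonzero(sizes < min_region))
        if not small:
            break
        votes: dict[int, dict[int, list]] = {}
        for i, j in pairs[~same]:
            ci, cj = comp[i], comp[j]
            if ci in small:
                votes.setdefault(ci, {}).setdefault(int(labels[j]), [0, 0])
                votes[ci][int(labels[j])][0] += 1
                votes[ci][int(labels[j])][1] = max(votes[ci][int(labels[j])][1],
                                                   int(sizes[cj]))
            if cj in small:
                votes.setdefault(cj, {}).setdefault(int(labels[i]), [0, 0])
                votes[cj][int(labels[i])][0] += 1
                votes[cj][int(labels[i])][1] = max(votes[cj][int(labels[i])][1],
                                                   int(sizes[ci]))
        changed = False
        new_labels = labels.copy()
        for c, tally in votes.items():
            # majority of boundary contacts; ties toward the largest adjacent region
            best = max(tally.items(), key=lambda kv: (kv[1][0], kv[1][1]))
            mask = comp == c
            if not (labels[mask] == best[0]).all():
                new_labels[mask] = best[0]
                changed = True
        labels = new_labels
        if not changed:
            break
    return cloud.with_labels(labels)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass
class ClassificationReport:
    """Per-class recall (%) and their point-count-weighted mean."""

    per_class_accuracy: dict[str, float]
    weighted_accuracy: float
    confusion: dict[tuple[str, str], int] = field(default_factory=dict)
    n_evaluated: int = 0


def evaluate(predicted, truth) -> ClassificationReport:
    """Score predictions against reference tags.

    Points whose truth or prediction is ``unknown`` are excluded. Per-class
    accuracy is recall: the fraction of true-class points labeled correctly;
    the weighted accuracy weights each class by its point count.
    """
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if len(predicted) != len(truth):
        raise ValueError("predicted and truth must have equal length")
    keep = (truth != UNKNOWN) & (predicted != UNKNOWN)
    p, t = predicted[keep], truth[keep]
    per_class: dict[str, float] = {}
    confusion: dict[tuple[str, str], int] = {}
    weighted = 0.0
    total = len(t)
    for c in np.unique(t):
        mask = t == c
        acc = 100.0 * float((p[mask] == c).mean())
        per_class[LABEL_NAMES.get(int(c), str(c))] = acc
        weighted += acc * mask.sum()
        for c2 in np.unique(p[mask]):
            confusion[(LABEL_NAMES.get(int(c), str(c)),
                       LABEL_NAMES.get(int(c2), str(c2)))] = int((p[mask] == c2).sum())
    weighted = weighted / total if total else 0.0
    return ClassificationReport(per_class, weighted, confusion, total)
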