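"""Random-subspace ensemble of k-nearest-neighbour weak learners.

Each weak learner is bound to a random subset of ``subspace_dim`` predictors
drawn without replacement; it scores a probe as the fraction of its k nearest
training neighbours (Euclidean distance in its subspace) that carry the
positive label.  The ensemble score is the average of the learners' scores,
which yields the continuous ranking that ROC analysis needs; hard
per-learner majority voting is available as an alternative combiner.

Ties among equidistant neighbours are resolved radius-inclusively: every
training point at the k-th smallest distance is included, which keeps the
score independent of sample ordering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier

__all__ = [
    "EnsembleConfig",
    "EnsembleModel",
    "train",
    "score",
    "classify",
    "baseline_models",
    "BASELINES",
]

BASELINES = ("knn-k2", "knn-k5", "knn-k10", "gaussian-nb")


@dataclass
class EnsembleConfig:
    """Ensemble shape: ``n_learners`` weak learners on ``subspace_dim``-sized
    random subspaces.  ``subspace_dim`` is capped at the number of available
    predictors d (the published setting of 16 is undefined for d < 16)."""

    n_learners: int = 30
    subspace_dim: int = 16
    k_neighbors: int = 1
    distance: str = "euclidean"
    vote: str = "score-average"  # or 'hard-majority'
    seed: int = 0

    def validate(self, d: int) -> int:
        """Return the effective subspace dimension for d predictors."""
        if self.n_learners < 1 or self.k_neighbors < 1 or self.subspace_dim < 1:
            raise ValueError("n_learners, k_neighbors and subspace_dim must be >= 1")
        if self.vote not in ("score-average", "hard-majority"):
            raise ValueError(f"unknown vote rule {self.vote!r}")
        return min(self.subspace_dim, d)


@dataclass
class EnsembleModel:
    subspaces: list[np.ndarray]  # per learner: column indices into X
    X_train: np.ndarray
    y_train: np.ndarray
    config: EnsembleConfig
    effective_dim: int = 0
    capped: bool = False

    @property
    def n_learners(self) -> int:
        return len(self.subspaces)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "config": self.config.__dict__,
            "effective_dim": self.effective_dim,
            "subspaces": [s.tolist() for s in self.subspaces],
            "X_train": self.X_train.tolist(),
            "y_train": self.y_train.tolist(),
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path: str | Path) -> "EnsembleModel":
        doc = json.loads(Path(path).read_text())
        return cls(
            subspaces=[np.asarray(s) for s in doc["subspaces"]],
            X_train=np.asarray(doc["X_train"], dtype=float),
            y_train=np.asarray(doc["y_train"], dtype=int),
            config=EnsembleConfig(**doc["config"]),
            effective_dim=doc["effective_dim"],
            capped=doc["effective_dim"] < doc["config"]["subspace_dim"],
        )


def train(
    X_train: np.ndarray, y_train: np.ndarray, config: EnsembleConfig | None = None
) -> EnsembleModel:
    """Build the ensemble: for each of n learners choose without replacement
    a random set of m predictors and bind the learner to the training data
    restricted to those predictors.  Reproducible from the config seed."""
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train, dtype=int)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("training set must be a non-empty 2-D matrix")
    config = config or EnsembleConfig()
    d = X.shape[1]
    m = config.validate(d)
    rng = np.random.default_rng(config.seed)
    subspaces = [np.sort(rng.choice(d, m, replace=False))
                 for _ in range(config.n_learners)]
    return EnsembleModel(
        subspaces=subspaces,
        X_train=X,
        y_train=y,
        config=config,
        effective_dim=m,
        capped=m < config.subspace_dim,
    )


def _learner_scores(model: EnsembleModel, X_probe: np.ndarray) -> np.ndarray:
    """(n_learners, n_probe) matrix of per-learner positive-class scores."""
    k = model.config.k_neighbors
    out = np.empty((model.n_learners, X_probe.shape[0]))
    for li, cols in enumerate(model.subspaces):
        D = cdist(X_probe[:, cols], model.X_train[:, cols], metric="euclidean")
        kth = np.partition(D, min(k, D.shape[1]) - 1, axis=1)[
            :, min(k, D.shape[1]) - 1
        ]
        include = D <= kth[:, None] + 1e-12  # radius-inclusive tie rule
        pos = (include * (model.y_train == 1)).sum(axis=1)
        out[li] = pos / include.sum(axis=1)
    return out


def score(model: EnsembleModel, X_probe: np.ndarray) -> np.ndarray:
    """Ensemble positive-class score in [0, 1] for each probe row."""
    X_probe = np.asarray(X_probe, dtype=float)
    if X_probe.shape[1] != model.X_train.shape[1]:
        raise ValueError("probe has a different number of predictors")
    L = _learner_scores(model, X_probe)
    if model.config.vote == "hard-majority":
        return (L >= 0.5).mean(axis=0)
    return L.mean(axis=0)


def classify(scores: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold scores into 0/1 labels; a score equal to the threshold is
    classified positive."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    return (np.asarray(scores) >= threshold).astype(int)


def baseline_models(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_probe: np.ndarray,
    which: str,
) -> np.ndarray:
    """Positive-class scores from a conventional comparator model:
    plain Euclidean kNN (k = 2, 5 or 10) or Gaussian naive Bayes."""
    X_train = np.asarray(X_train, dtype=float)
    X_probe = np.asarray(X_probe, dtype=float)
    y_train = np.asarray(y_train, dtype=int)
    if which.startswith("knn-k"):
        k = int(which.split("knn-k")[1])
        k = min(k, X_train.shape[0])
        clf = KNeighborsClassifier(n_neighbors=k, metric="euclidean")
    elif which == "gaussian-nb":
        clf = GaussianNB()
    else:
        raise ValueError(f"unknown baseline {which!r}; choose from {BASELINES}")
    clf.fit(X_train, y_train)
    proba = clf.predict_proba(X_probe)
    if proba.shape[1] == 1:  # single-class training fold
        return np.full(X_probe.shape[0], float(clf.classes_[0]))
    return proba[:, list(clf.classes_).index(1)]
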