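"""Cascade (deep) forest classifier with class-vector feature augmentation.

Each level holds an ensemble of random forests and completely-random forests
(extra-trees with single-feature splits).  A level's per-forest class
probability vectors are concatenated to the original features to form the
next level's input; class vectors for the training data are produced
out-of-fold so no level sees its own training predictions.  Levels are grown
until the cross-validated level accuracy stops improving, and prediction
averages the last retained level's forest probabilities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted, validate_data


def augment_features(X: np.ndarray, class_vectors: np.ndarray) -> np.ndarray:
    """Column-concatenate class-probability vectors onto the feature matrix."""
    X = np.asarray(X, dtype=float)
    class_vectors = np.asarray(class_vectors, dtype=float)
    if class_vectors.size == 0:
        return X
    if class_vectors.shape[0] != X.shape[0]:
        raise ValueError("row count mismatch between X and class vectors")
    return np.hstack([X, class_vectors])


@dataclass
class CascadeLevel:
    """Fitted forests of one cascade level plus its cross-validated accuracy."""

    forests: list
    accuracy: float

    def class_vectors(self, X: np.ndarray) -> np.ndarray:
        return np.hstack([f.predict_proba(X) for f in self.forests])

    def mean_proba(self, X: np.ndarray) -> np.ndarray:
        return np.mean([f.predict_proba(X) for f in self.forests], axis=0)


class CascadeForestClassifier(ClassifierMixin, BaseEstimator):
    """gcForest-style cascade of random and completely-random forests.

    Parameters
    ----------
    n_forests : int, default 2
        Forests per type per level (so each level holds ``2 * n_forests``
        forests); the tunable ``n_cascadeRF`` hyperparameter, range 1-10.
    n_trees : int, default 100
        Trees per forest; the tunable ``n_cascadeRFtree``, range 10-300.
    cv_folds : int, default 3
        Internal folds for out-of-fold class-vector generation.
    patience : int, default 1
        Levels without accuracy improvement tolerated before stopping.
    max_levels : int, default 10
    random_state : int, default 0

    Attributes
    ----------
    classes_ : ndarray
        Class labels in lexicographic order; argmax ties resolve to the first.
    levels_ : list of CascadeLevel
        Retained levels (up to the best-performing one).
    level_accuracies_ : list of float
        Cross-validated accuracy of every level grown (including discarded ones).
    n_levels_ : int
    """

    def __init__(self, n_forests: int = 2, n_trees: int = 100, cv_folds: int = 3,
                 patience: int = 1, max_levels: int = 10, random_state: int = 0):
        self.n_forests = n_forests
        self.n_trees = n_trees
        self.cv_folds = cv_folds
        self.patience = patience
        self.max_levels = max_levels
        self.random_state = random_state

    def _forest_templates(self):
        rf = RandomForestClassifier(n_estimators=self.n_trees, n_jobs=1)
        crf = ExtraTreesClassifier(n_estimators=self.n_trees, max_features=1, n_jobs=1)
        return [rf] * self.n_forests + [crf] * self.n_forests

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        if not (1 <= self.n_forests <= 10):
            raise ValueError(f"n_forests must lie in [1, 10], got {self.n_forests}")
        if not (10 <= self.n_trees <= 300):
            raise ValueError(f"n_trees must lie in [10, 300], got {self.n_trees}")
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        if self.classes_.size < 2:
            raise ValueError("cascade forest needs at least 2 classes")
        counts = np.bincount(y_enc)
        folds = min(self.cv_folds, counts.min())
        if folds < 2:
            raise ValueError("every class needs at least 2 members")
        ss = np.random.SeedSequence(self.random_state)

        self.input_dim_ = X.shape[1]
        self.levels_ = []
        self.level_accuracies_ = []
        cur = X
        best_acc, best_idx, since_improve = -np.inf, -1, 0
        all_levels: list[CascadeLevel] = []
        for li in range(self.max_levels):
            level, oof = self._fit_level(cur, y_enc, folds, ss.spawn(1)[0])
            all_levels.append(level)
            self.level_accuracies_.append(level.accuracy)
            if level.accuracy > best_acc + 1e-12:
                best_acc, best_idx, since_improve = level.accuracy, li, 0
            else:
                since_improve += 1
                if since_improve > self.patience:
                    break
            cur = augment_features(X, oof)
        self.levels_ = all_levels[: best_idx + 1]
        self.n_levels_ = len(self.levels_)
        self.validation_accuracy_ = best_acc
        return self

    def _fit_level(self, X: np.ndarray, y: np.ndarray, folds: int,
                   seed: np.random.SeedSequence):
        """Fit one level; returns it plus out-of-fold class vectors for X."""
        n, k = X.shape[0], self.classes_.size
        templates = self._forest_templates()
        seeds = seed.generate_state(2 * len(templates) + 1)
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(seeds[-1] % (2 ** 31)))
        splits = list(skf.split(X, y))

        oof = np.zeros((n, len(templates) * k))
        forests = []
        for fi, template in enumerate(templates):
            # out-of-fold probabilities for augmentation / level scoring
            for tr, te in splits:
                m = clone(template)
                m.set_params(random_state=int(seeds[2 * fi] % (2 ** 31)))
                m.fit(X[tr], y[tr])
                oof[te, fi * k:(fi + 1) * k] = self._full_proba(m, X[te], k)
            # the deployed forest is refit on all rows
            m = clone(template)
            m.set_params(random_state=int(seeds[2 * fi + 1] % (2 ** 31)))
            m.fit(X, y)
            forests.append(m)
        mean_oof = oof.reshape(n, len(templates), k).mean(axis=1)
        acc = float(np.mean(np.argmax(mean_oof, axis=1) == y))
        return CascadeLevel(forests=forests, accuracy=acc), oof

    @staticmethod
    def _full_proba(model, X: np.ndarray, k: int) -> np.ndarray:
        """Probabilities expanded to all k classes (folds may miss a class)."""
        p = model.predict_proba(X)
        if p.shape[1] == k:
            return p
        full = np.zeros((X.shape[0], k))
        full[:, model.classes_] = p
        return full

    def predict_proba(self, X):
        check_is_fitted(self, "levels_")
        X = validate_data(self, X, reset=False)
        cur = X
        for level in self.levels_[:-1]:
            cur = augment_features(X, level.class_vectors(cur))
        return self.levels_[-1].mean_proba(cur)

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]

    def save(self, directory: str | Path) -> Path:
        """Persist as a directory of serialized forests plus a JSON manifest."""
        check_is_fitted(self, "levels_")
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "n_forests": self.n_forests,
            "n_trees": self.n_trees,
            "cv_folds": self.cv_folds,
            "patience": self.patience,
            "max_levels": self.max_levels,
            "random_state": self.random_state,
            "n_levels": self.n_levels_,
            "classes": [str(c) for c in self.classes_],
            "input_dim": int(self.input_dim_),
            "level_accuracies": self.level_accuracies_,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
        for li, level in enumerate(self.levels_):
            joblib.dump(level, directory / f"level_{li}.joblib")
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "CascadeForestClassifier":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        model = cls(
            n_forests=manifest["n_forests"], n_trees=manifest["n_trees"],
            cv_folds=manifest["cv_folds"], patience=manifest["patience"],
            max_levels=manifest["max_levels"], random_state=manifest["random_state"],
        )
        model.classes_ = np.asarray(manifest["classes"])
        model.input_dim_ = manifest["input_dim"]
        model.n_features_in_ = manifest["input_dim"]
        model.level_accuracies_ = manifest["level_accuracies"]
        model.levels_ = [joblib.load(directory / f"level_{li}.joblib")
                         for li in range(manifest["n_levels"])]
        model.n_levels_ = len(model.levels_)
        model.validation_accuracy_ = max(a for a in model.level_accuracies_)
        return model


def fit_cascade(X, y, n_cascade_rf: int = 2, n_cascade_rf_tree: int = 100,
                cv_folds: int = 3, patience: int = 1, max_levels: int = 10,
                seed: int = 0) -> CascadeForestClassifier:
    """Functional wrapper over :class:`CascadeForestClassifier`."""
    return CascadeForestClassifier(
        n_forests=n_cascade_rf, n_trees=n_cascade_rf_tree, cv_folds=cv_folds,
        patience=patience, max_levels=max_levels, random_state=seed,
    ).fit(X, y)
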