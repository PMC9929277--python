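"""The three classifier families: decision tree, random forest, gradient boosting.

One uniform contract over sklearn estimators.  The decision tree splits on
entropy/information gain; the random forest bags fully grown trees on
bootstrap samples and scores by the fraction of trees voting for class 1
(majority vote at the 0.5 threshold); gradient boosting builds shallow trees
stagewise and scores through the logistic link.
"""

from __future__ import annotations

import hashlib
import pickle
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

from . import schema

__all__ = ["ModelSpec", "FittedModel", "train", "predict_proba", "predict"]

Family = Literal["decision_tree", "random_forest", "gradient_boosting"]


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one classifier.

    Hyperparameters follow common library defaults: 100 trees and unlimited
    depth for the forest; 100 stages, depth 3 and learning rate 0.1 for
    boosting.
    """

    family: Family
    split_criterion: str = "entropy"
    n_trees: int = 100
    max_depth: int | None = None
    learning_rate: float = 0.1
    bootstrap: bool = True
    max_features: str | int | None = "sqrt"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("decision_tree", "random_forest", "gradient_boosting"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.family == "gradient_boosting" and not (0.0 < self.learning_rate <= 1.0):
            raise ValueError("learning_rate must lie in (0, 1]")

    def build(self):
        if self.family == "decision_tree":
            return DecisionTreeClassifier(
                criterion=self.split_criterion,
                max_depth=self.max_depth,
                random_state=self.seed,
            )
        if self.family == "random_forest":
            return RandomForestClassifier(
                n_estimators=self.n_trees,
                criterion=self.split_criterion,
                max_depth=self.max_depth,
                bootstrap=self.bootstrap,
                max_features=self.max_features,
                random_state=self.seed,
            )
        return GradientBoostingClassifier(
            n_estimators=self.n_trees,
            max_depth=3 if self.max_depth is None else self.max_depth,
            learning_rate=self.learning_rate,
            random_state=self.seed,
        )


def _fingerprint(columns: Sequence[str]) -> str:
    return hashlib.sha256("|".join(columns).encode()).hexdigest()[:16]


@dataclass
class FittedModel:
    """A trained classifier bound to the schema it was trained on."""

    spec: ModelSpec
    estimator: object
    feature_columns: list[str]
    fingerprint: str = field(default="")

    def __post_init__(self) -> None:
        if not self.fingerprint:
            self.fingerprint = _fingerprint(self.feature_columns)

    def _check(self, table: pd.DataFrame) -> np.ndarray:
        cols = [c for c in table.columns if c != schema.LABEL_COLUMN]
        if _fingerprint(cols) != self.fingerprint:
            raise ValueError(
                f"schema mismatch: model was trained on {self.feature_columns!r}, "
                f"got {cols!r}"
            )
        return table[self.feature_columns].to_numpy(dtype=float)

    def save(self, path) -> None:
        """Persist as a versioned pickle archive."""
        with open(path, "wb") as fh:
            pickle.dump({"format": 1, "model": self}, fh)

    @classmethod
    def load(cls, path) -> "FittedModel":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        if payload.get("format") != 1:
            raise ValueError("unrecognised model archive format")
        return payload["model"]


def train(spec: ModelSpec, table: pd.DataFrame) -> FittedModel:
    """Fit a classifier on a feature table (last column = class label)."""
    y = table[schema.LABEL_COLUMN].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("training table must contain both classes")
    cols = [c for c in table.columns if c != schema.LABEL_COLUMN]
    X = table[cols].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("training table contains missing values")
    est = spec.build().fit(X, y)
    return FittedModel(spec=spec, estimator=est, feature_columns=cols)


def predict_proba(model: FittedModel, table: pd.DataFrame) -> np.ndarray:
    """Per-row class-1 score in [0, 1].

    Random forest: the fraction of trees whose majority-vote prediction is
    class 1.  Decision tree: the class-1 fraction of the leaf.  Gradient
    boosting: the logistic of the additive ensemble.
    """
    X = model._check(table)
    est = model.estimator
    if model.spec.family == "random_forest":
        votes = np.stack([t.predict(X) for t in est.estimators_])
        # tree.predict returns class indices into est.classes_
        pos = np.flatnonzero(est.classes_ == 1)
        if pos.size == 0:
            return np.zeros(len(X))
        return (votes == pos[0]).mean(axis=0)
    proba = est.predict_proba(X)
    pos = np.flatnonzero(est.classes_ == 1)
    return proba[:, pos[0]] if pos.size else np.zeros(len(X))


def predict(model: FittedModel, table: pd.DataFrame, threshold: float = 0.5) -> np.ndarray:
    """Binary labels: 1 iff score >= threshold (the boundary goes to class 1)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    return (predict_proba(model, table) >= threshold).astype(int)
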