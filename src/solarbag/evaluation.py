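"""Confusion matrices, the four classification metrics, and 10-fold CV.

Metrics follow the standard definitions — precision TP/(TP+FP), recall
TP/(TP+FN), F1 the harmonic mean, accuracy (TP+TN)/N — with the convention
that 0/0 yields 0 (an all-negative predictor scores 0 precision/recall/F1).

``cross_validate`` supports the two placements of a rebalancing transform:
``resample_before_cv`` applies it once to the whole table before splitting —
the reproduction mode, faithful to the published protocol but leaky, since
replicated or interpolated minority rows then straddle fold boundaries — and
``resample_within_fold`` applies it to each training split only, the
methodologically sound alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable, Literal

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from . import schema
from .modeling import FittedModel, ModelSpec, predict, train

__all__ = ["ConfusionMatrix", "MetricsReport", "confusion", "metrics", "cross_validate"]


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts with an explicit positive class."""

    TP: int
    FP: int
    TN: int
    FN: int
    positive_class: int = 1

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    def swapped(self) -> "ConfusionMatrix":
        """The same matrix with the other class treated as positive."""
        return ConfusionMatrix(
            TP=self.TN, FP=self.FN, TN=self.TP, FN=self.FP,
            positive_class=1 - self.positive_class,
        )


def confusion(truth, predicted, positive_class: int = 1) -> ConfusionMatrix:
    """Count TP/FP/TN/FN of a prediction vector against the truth."""
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape:
        raise ValueError(f"length mismatch: {truth.shape} vs {predicted.shape}")
    pos_t = truth == positive_class
    pos_p = predicted == positive_class
    return ConfusionMatrix(
        TP=int(np.sum(pos_t & pos_p)),
        FP=int(np.sum(~pos_t & pos_p)),
        TN=int(np.sum(~pos_t & ~pos_p)),
        FN=int(np.sum(pos_t & ~pos_p)),
        positive_class=positive_class,
    )


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


def metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Accuracy, precision, recall and F1 of one confusion matrix."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    precision = _safe_div(cm.TP, cm.TP + cm.FP)
    recall = _safe_div(cm.TP, cm.TP + cm.FN)
    f1 = _safe_div(2 * precision * recall, precision + recall)
    accuracy = (cm.TP + cm.TN) / cm.total
    return {"accuracy": accuracy, "precision": precision, "recall": recall, "f1": f1}


@dataclass
class MetricsReport:
    """Per-fold and aggregate metrics for one (model, dataset-variant) run."""

    variant: str
    model: str
    positive_class: int
    folds: list[ConfusionMatrix] = dc_field(default_factory=list)
    per_fold: list[dict[str, float]] = dc_field(default_factory=list)
    aggregate: dict[str, float] = dc_field(default_factory=dict)
    pooled: ConfusionMatrix | None = None

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "model": self.model,
            "positive_class": self.positive_class,
            "aggregate": self.aggregate,
            "per_fold": self.per_fold,
            "pooled_confusion": None
            if self.pooled is None
            else {"TP": self.pooled.TP, "FP": self.pooled.FP,
                  "TN": self.pooled.TN, "FN": self.pooled.FN},
        }


def cross_validate(
    spec: ModelSpec,
    table: pd.DataFrame,
    k: int = 10,
    resampler: Callable[..., object] | None = None,
    leakage_mode: Literal["resample_before_cv", "resample_within_fold"] = "resample_before_cv",
    seed: int = 0,
    positive_class: int = 1,
    variant: str = "original",
) -> MetricsReport:
    """Stratified k-fold cross-validation of one model spec.

    ``resampler`` is one of the transforms in :mod:`solarbag.resampling`
    (called as ``resampler(table, seed=...)``) or None for the original data.
    The aggregate is the unweighted mean over folds; a pooled confusion matrix
    over all folds is also reported.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if resampler is not None and leakage_mode == "resample_before_cv":
        table = resampler(table, seed=seed).table
    y = table[schema.LABEL_COLUMN].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("cross-validation needs both classes present")
    class_min = int(np.bincount(y.astype(int)).min())
    if k <= class_min:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:  # stratification impossible (e.g. leave-one-out); plain shuffled folds
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    report = MetricsReport(variant=variant, model=spec.family, positive_class=positive_class)
    pooled = np.zeros(4, dtype=int)  # TP FP TN FN
    for fold, (tr, te) in enumerate(splitter.split(np.zeros(len(y)), y)):
        train_tab = table.iloc[tr]
        test_tab = table.iloc[te]
        if resampler is not None and leakage_mode == "resample_within_fold":
            train_tab = resampler(train_tab.reset_index(drop=True), seed=seed + fold).table
        for part, name in ((train_tab, "training"), (test_tab, "test")):
            if part[schema.LABEL_COLUMN].nunique() < 2 and name == "training":
                raise ValueError(
                    f"fold {fold} {name} split lost a class; "
                    "use stratification or more data"
                )
        model = train(spec, train_tab)
        pred = predict(model, test_tab)
        cm = confusion(test_tab[schema.LABEL_COLUMN].to_numpy(), pred, positive_class)
        report.folds.append(cm)
        report.per_fold.append(metrics(cm))
        pooled += np.array([cm.TP, cm.FP, cm.TN, cm.FN])
    keys = report.per_fold[0].keys()
    report.aggregate = {k_: float(np.mean([m[k_] for m in report.per_fold])) for k_ in keys}
    report.pooled = ConfusionMatrix(*map(int, pooled), positive_class=positive_class)
    return report
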