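"""Class-rebalancing transforms: random over-/under-sampling and SMOTE.

All three transforms equalise the two class counts of a feature table and are
deterministic under their seed.  SMOTE interpolates new minority points on
the segment between a minority row and one of its k nearest minority
neighbours (Euclidean distance on z-scored continuous features); binary
features are copied from the seed row, so one-hot treatment flags stay valid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from . import schema

__all__ = ["ResampleResult", "random_oversample", "random_undersample", "smote", "RESAMPLERS"]


@dataclass
class ResampleResult:
    """A rebalanced table with per-row provenance.

    ``provenance`` holds one of ``original``, ``replicated`` or ``synthetic``
    per output row.
    """

    table: pd.DataFrame
    provenance: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        counts = self.table[schema.LABEL_COLUMN].value_counts()
        if len(counts) == 2 and counts.iloc[0] != counts.iloc[1]:
            raise ValueError("resample result must have equal class counts")


def _split_classes(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Row positions of (minority, majority) classes; errors on single-class."""
    y = table[schema.LABEL_COLUMN].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError(f"both classes required, found only class {classes[0]!r}")
    minority = classes[np.argmin(counts)]
    return np.flatnonzero(y == minority), np.flatnonzero(y != minority)


def random_oversample(table: pd.DataFrame, seed: int = 0) -> ResampleResult:
    """Replicate random minority rows until the classes balance.

    All original rows are retained; the appended rows are exact copies.
    """
    minority, majority = _split_classes(table)
    rng = np.random.default_rng(seed)
    deficit = len(majority) - len(minority)
    extra = rng.choice(minority, size=deficit, replace=True) if deficit else np.array([], int)
    out = pd.concat([table, table.iloc[extra]], ignore_index=True)
    provenance = np.array(["original"] * len(table) + ["replicated"] * deficit)
    return ResampleResult(table=out, provenance=provenance, seed=seed)


def random_undersample(table: pd.DataFrame, seed: int = 0) -> ResampleResult:
    """Drop random majority rows until the classes balance.

    All minority rows are retained; output rows are a subset of the input, in
    original row order.
    """
    minority, majority = _split_classes(table)
    rng = np.random.default_rng(seed)
    kept_majority = rng.choice(majority, size=len(minority), replace=False)
    keep = np.sort(np.concatenate([minority, kept_majority]))
    out = table.iloc[keep].reset_index(drop=True)
    provenance = np.array(["original"] * len(out))
    return ResampleResult(table=out, provenance=provenance, seed=seed)


def smote(table: pd.DataFrame, k: int = 5, seed: int = 0) -> ResampleResult:
    """Synthetic minority oversampling.

    Each synthetic row is ``x_i + u * (x_nn - x_i)`` on continuous features,
    with ``x_nn`` one of ``x_i``'s ``k`` nearest minority neighbours (Euclidean
    on z-scored continuous features) and ``u ~ Uniform(0, 1)``; binary
    features are copied from the seed row ``x_i``.
    """
    minority, majority = _split_classes(table)
    if len(minority) <= k:
        raise ValueError(
            f"SMOTE needs more than k={k} minority rows (found {len(minority)}); "
            "use a smaller k"
        )
    rng = np.random.default_rng(seed)
    cont = [c for c in schema.CONTINUOUS_COLUMNS if c in table.columns]
    x_min = table.iloc[minority][cont].to_numpy(dtype=float)
    sd = x_min.std(axis=0)
    sd[sd == 0] = 1.0
    z = (x_min - x_min.mean(axis=0)) / sd
    nn = NearestNeighbors(n_neighbors=k + 1).fit(z)
    _, neigh = nn.kneighbors(z)  # column 0 is the point itself
    neigh = neigh[:, 1:]

    deficit = len(majority) - len(minority)
    seeds = rng.integers(0, len(minority), size=deficit)
    picks = neigh[seeds, rng.integers(0, k, size=deficit)]
    u = rng.uniform(0.0, 1.0, size=deficit)

    synthetic = table.iloc[minority[seeds]].reset_index(drop=True).copy()
    synthetic[cont] = x_min[seeds] + u[:, None] * (x_min[picks] - x_min[seeds])
    out = pd.concat([table, synthetic], ignore_index=True)
    provenance = np.array(["original"] * len(table) + ["synthetic"] * deficit)
    return ResampleResult(table=out, provenance=provenance, seed=seed)


#: Named transforms for configs and the CLI.
RESAMPLERS = {
    "over": random_oversample,
    "under": random_undersample,
    "smote": smote,
}
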