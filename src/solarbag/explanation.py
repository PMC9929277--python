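"""Shapley additive explanations for the fitted tree models.

Attributions target the class-1 probability (the forest's vote fraction): for
an observation x, background table B and model f, feature i receives the
Shapley value of the game ``v(S) = E_r~B[ f(x_S, r_!S) ]`` — the interventional
(marginal) flavour, under which a feature no tree ever splits on is guaranteed
zero credit.  By Shapley efficiency, ``base_value + sum(phi) = f(x)`` exactly,
with ``base_value = E_r~B[f(r)]``.

Three computation routes:

``tree_path``
    Exact and fast for the decision tree and random forest.  For each
    (target, reference) pair and each leaf, the features on the leaf's path
    split into those only the target satisfies and those only the reference
    satisfies; the leaf's Shapley contribution then has a closed combinatorial
    form in the two set sizes, precomputable for all size pairs.
``exact_subsets``
    Model-agnostic brute force over all 2^p feature subsets (p <= 12); the
    independent oracle the tree route is verified against.
``sampling``
    Model-agnostic permutation Monte Carlo for any model/feature count;
    additivity holds to Monte-Carlo tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .modeling import FittedModel, predict_proba

__all__ = [
    "Attribution",
    "GlobalImportance",
    "ForceDecomposition",
    "shap_values",
    "global_importance",
    "force_decomposition",
]


@dataclass
class Attribution:
    """Per-feature Shapley credits for one observation."""

    base_value: float
    phi: pd.Series  # indexed by feature name
    model_output: float
    method: str = "tree_path"
    flavour: str = "interventional"

    def additivity_error(self) -> float:
        return abs(self.base_value + float(self.phi.sum()) - self.model_output)


@dataclass
class GlobalImportance:
    """Aggregate signed importance over a set of explained observations."""

    mean_abs_phi: pd.Series
    mean_signed_phi: pd.Series
    rank_order: list[str]
    direction: dict[str, str]


@dataclass
class ForceDecomposition:
    """Positive and negative pushes of one prediction away from the base value."""

    positive: list[tuple[str, float]]
    negative: list[tuple[str, float]]
    base_value: float
    model_output: float

    @property
    def net_push(self) -> float:
        return self.model_output - self.base_value


# ---------------------------------------------------------------------------
# model evaluation helpers


def _as_frame(X: np.ndarray, columns: Sequence[str]) -> pd.DataFrame:
    return pd.DataFrame(X, columns=list(columns))


def _model_fn(model: FittedModel):
    cols = model.feature_columns
    return lambda X: predict_proba(model, _as_frame(np.atleast_2d(X), cols))


def _prepare(
    model: FittedModel,
    background: pd.DataFrame,
    targets: pd.DataFrame,
    max_background: int | None,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    cols = model.feature_columns
    for name, tab in (("background", background), ("targets", targets)):
        missing = [c for c in cols if c not in tab.columns]
        if missing:
            raise ValueError(f"{name} table lacks model features {missing!r}")
    B = background[cols].to_numpy(dtype=float)
    X = targets[cols].to_numpy(dtype=float)
    if max_background is not None and len(B) > max_background:
        rng = np.random.default_rng(seed)
        B = B[rng.choice(len(B), size=max_background, replace=False)]
    return X, B


# ---------------------------------------------------------------------------
# exact interventional Shapley for a single tree, via leaf-path combinatorics


def _leaf_boxes(tree, n_features: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-leaf axis-aligned boxes (lo < x <= hi) and leaf node ids."""
    lo0 = np.full(n_features, -np.inf)
    hi0 = np.full(n_features, np.inf)
    los, his, leaves = [], [], []
    stack = [(0, lo0, hi0)]
    while stack:
        node, lo, hi = stack.pop()
        if tree.children_left[node] == -1:
            los.append(lo)
            his.append(hi)
            leaves.append(node)
            continue
        f, thr = int(tree.feature[node]), float(tree.threshold[node])
        lo_l, hi_l = lo.copy(), hi.copy()
        hi_l[f] = min(hi_l[f], thr)  # left: x <= thr
        lo_r, hi_r = lo.copy(), hi.copy()
        lo_r[f] = max(lo_r[f], thr)  # right: x > thr
        stack.append((int(tree.children_left[node]), lo_l, hi_l))
        stack.append((int(tree.children_right[node]), lo_r, hi_r))
    return np.array(los), np.array(his), np.array(leaves)


def _interventional_weights(p: int) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form Shapley weights for leaf contributions.

    For a leaf whose path needs ``a`` target-only features and excludes ``b``
    reference-only features (all other features free), ``w_plus[a, b]`` is the
    summed Shapley weight credited to each of the ``a`` features and
    ``w_minus[a, b]`` the weight debited from each of the ``b`` features.
    """
    fact = [math.factorial(i) for i in range(p + 1)]
    w_plus = np.zeros((p + 1, p + 1))
    w_minus = np.zeros((p + 1, p + 1))
    for a in range(p + 1):
        for b in range(p + 1 - a):
            m = p - a - b
            if a >= 1:
                num = sum(
                    math.comb(m, k) * fact[a - 1 + k] * fact[p - a - k] for k in range(m + 1)
                )
                w_plus[a, b] = num / fact[p]
            if b >= 1:
                num = sum(
                    math.comb(m, k) * fact[a + k] * fact[p - a - k - 1] for k in range(m + 1)
                )
                w_minus[a, b] = num / fact[p]
    return w_plus, w_minus


def _tree_leaf_values(estimator, tree, leaves: np.ndarray, vote: bool, pos_idx: int) -> np.ndarray:
    """Class-1 output of each leaf: hard vote (forest) or class fraction (tree)."""
    counts = tree.value[leaves, 0, :]  # (L, n_classes); proportions in sklearn >= 1.3
    if counts.shape[1] == 1:
        frac = np.full(len(leaves), float(pos_idx == 0))
    else:
        frac = counts[:, pos_idx] / counts.sum(axis=1)
    if vote:
        return (counts.argmax(axis=1) == pos_idx).astype(float)
    return frac


def _tree_shap_interventional(
    model: FittedModel, X: np.ndarray, B: np.ndarray, chunk: int = 32
) -> np.ndarray:
    """Exact interventional Shapley values for DT/RF, shape (n_targets, p)."""
    est = model.estimator
    family = model.spec.family
    if family == "random_forest":
        trees = [t.tree_ for t in est.estimators_]
        vote = True
    elif family == "decision_tree":
        trees = [est.tree_]
        vote = False
    else:
        raise ValueError(
            "tree_path supports decision_tree and random_forest; "
            "use method='sampling' for gradient_boosting"
        )
    classes = np.asarray(est.classes_)
    pos = np.flatnonzero(classes == 1)
    pos_idx = int(pos[0]) if pos.size else -1
    p = X.shape[1]
    w_plus, w_minus = _interventional_weights(p)
    phi = np.zeros((len(X), p))
    m = len(B)
    for tree in trees:
        lo, hi, leaves = _leaf_boxes(tree, p)
        if pos_idx < 0:
            continue
        val = _tree_leaf_values(est, tree, leaves, vote, pos_idx)
        keep = val != 0.0  # zero-valued leaves contribute nothing
        lo_k, hi_k, val_k = lo[keep], hi[keep], val[keep]
        if len(val_k) == 0:
            continue
        sat_b = (B[:, None, :] > lo_k[None]) & (B[:, None, :] <= hi_k[None])  # (m,L,p)
        for start in range(0, len(X), chunk):
            Xc = X[start : start + chunk]
            sat_x = (Xc[:, None, :] > lo_k[None]) & (Xc[:, None, :] <= hi_k[None])  # (n,L,p)
            A = sat_x[:, None, :, :]
            Bm = sat_b[None, :, :, :]
            fx = A & ~Bm  # target-only features (n,m,L,p)
            fr = Bm & ~A  # reference-only
            ok = (A | Bm).all(axis=-1)  # reachable by some subset
            a = fx.sum(axis=-1)
            b = fr.sum(axis=-1)
            wp = np.where(ok, w_plus[a, b], 0.0) * val_k[None, None, :]
            wm = np.where(ok, w_minus[a, b], 0.0) * val_k[None, None, :]
            phi[start : start + chunk] += (
                (fx * wp[..., None]).sum(axis=(1, 2)) - (fr * wm[..., None]).sum(axis=(1, 2))
            ) / m
    return phi / len(trees)


# ---------------------------------------------------------------------------
# brute-force subset oracle and permutation sampling


def _exact_subsets_shap(model: FittedModel, X: np.ndarray, B: np.ndarray) -> np.ndarray:
    p = X.shape[1]
    if p > 12:
        raise ValueError(
            f"exact_subsets enumerates 2^p coalitions and is limited to p <= 12 "
            f"features (got p = {p}); use tree_path or sampling"
        )
    f = _model_fn(model)
    fact = [math.factorial(i) for i in range(p + 1)]
    phi = np.zeros((len(X), p))
    for xi, x in enumerate(X):
        v = {}
        for size in range(p + 1):
            for S in combinations(range(p), size):
                hybrid = B.copy()
                hybrid[:, list(S)] = x[list(S)]
                v[S] = float(np.mean(f(hybrid)))
        for i in range(p):
            others = [j for j in range(p) if j != i]
            for size in range(p):
                w = fact[size] * fact[p - size - 1] / fact[p]
                for S in combinations(others, size):
                    phi[xi, i] += w * (v[tuple(sorted(S + (i,)))] - v[S])
    return phi


def _sampling_shap(
    model: FittedModel, X: np.ndarray, B: np.ndarray, n_samples: int, seed: int
) -> np.ndarray:
    p = X.shape[1]
    f = _model_fn(model)
    rng = np.random.default_rng(seed)
    phi = np.zeros((len(X), p))
    for xi, x in enumerate(X):
        perms = np.array([rng.permutation(p) for _ in range(n_samples)])
        refs = B[rng.integers(0, len(B), size=n_samples)]
        # build all intermediate hybrids: (n_samples, p+1, p)
        hybrids = np.repeat(refs[:, None, :], p + 1, axis=1)
        for s in range(n_samples):
            cur = refs[s].copy()
            for step, j in enumerate(perms[s]):
                cur[j] = x[j]
                hybrids[s, step + 1] = cur
        outs = f(hybrids.reshape(-1, p)).reshape(n_samples, p + 1)
        deltas = np.diff(outs, axis=1)  # (n_samples, p) in permutation order
        for s in range(n_samples):
            phi[xi, perms[s]] += deltas[s]
        phi[xi] /= n_samples
    return phi


# ---------------------------------------------------------------------------
# public surface


def shap_values(
    model: FittedModel,
    background: pd.DataFrame,
    targets: pd.DataFrame,
    method: Literal["exact_subsets", "tree_path", "sampling"] = "tree_path",
    n_samples: int = 2000,
    seed: int = 0,
    max_background: int | None = None,
) -> list[Attribution]:
    """Explain each target row against a background table.

    Returns one :class:`Attribution` per target row; ``base_value`` is the
    mean model output over the (possibly subsampled) background.
    """
    X, B = _prepare(model, background, targets, max_background, seed)
    f = _model_fn(model)
    base = float(np.mean(f(B)))
    outputs = f(X)
    if method == "tree_path":
        phi = _tree_shap_interventional(model, X, B)
    elif method == "exact_subsets":
        phi = _exact_subsets_shap(model, X, B)
    elif method == "sampling":
        phi = _sampling_shap(model, X, B, n_samples, seed)
    else:
        raise ValueError(f"unknown method {method!r}")
    cols = model.feature_columns
    return [
        Attribution(
            base_value=base,
            phi=pd.Series(phi[i], index=cols),
            model_output=float(outputs[i]),
            method=method,
        )
        for i in range(len(X))
    ]


def global_importance(attributions: Sequence[Attribution]) -> GlobalImportance:
    """Rank features by mean |phi| (descending, ties alphabetical)."""
    if not attributions:
        raise ValueError("need at least one attribution")
    mat = pd.DataFrame([a.phi for a in attributions])
    mean_abs = mat.abs().mean(axis=0)
    mean_signed = mat.mean(axis=0)
    order = sorted(mean_abs.index, key=lambda fcol: (-mean_abs[fcol], fcol))
    direction = {
        fcol: ("positive" if s > 0 else "negative" if s < 0 else "zero")
        for fcol, s in mean_signed.items()
    }
    return GlobalImportance(
        mean_abs_phi=mean_abs,
        mean_signed_phi=mean_signed,
        rank_order=order,
        direction=direction,
    )


def force_decomposition(attribution: Attribution) -> ForceDecomposition:
    """Split one attribution into positive and negative pushes, largest first."""
    items = [(str(k), float(v)) for k, v in attribution.phi.items() if v != 0.0]
    positive = sorted([kv for kv in items if kv[1] > 0], key=lambda kv: -abs(kv[1]))
    negative = sorted([kv for kv in items if kv[1] < 0], key=lambda kv: -abs(kv[1]))
    return ForceDecomposition(
        positive=positive,
        negative=negative,
        base_value=attribution.base_value,
        model_output=attribution.model_output,
    )


def attributions_to_frame(attributions: Sequence[Attribution]) -> pd.DataFrame:
    """Long-format table (row_id, feature, phi, base_value, model_output)."""
    rows = []
    for i, a in enumerate(attributions):
        for fcol, v in a.phi.items():
            rows.append(
                {
                    "row_id": i,
                    "feature": fcol,
                    "phi": float(v),
                    "base_value": a.base_value,
                    "model_output": a.model_output,
                }
            )
    return pd.DataFrame(rows)
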