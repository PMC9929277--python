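"""Field thermal statistics: time above 40 °C, degree-minutes, ANOVA, Tukey.

Daily summaries of the bag-bottom record — minutes spent strictly above the
lethal threshold and degree-minutes (°C·min of excess over the base, the
classical thermal-dose statistic) — followed by the homogeneity-of-variance
and mean-comparison tests used on such treatment summaries: classical
(mean-centred) Levene, one-way ANOVA, and Tukey-Kramer HSD with a compact
letter display.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .labeling import TemperatureSeries

__all__ = [
    "TreatmentDailySummary",
    "AnovaResult",
    "time_above",
    "degree_minutes",
    "daily_summaries",
    "levene",
    "anova_tukey",
]


def _infer_cadence(series: TemperatureSeries) -> float:
    if len(series) < 2:
        return 15.0
    return float((series.timestamps[1] - series.timestamps[0]).total_seconds() / 60.0)


def time_above(series: TemperatureSeries, threshold: float = 40.0) -> pd.Series:
    """Minutes per calendar day spent strictly above ``threshold`` °C."""
    cadence = _infer_cadence(series)
    series.validate(int(cadence))
    hot = pd.Series(
        (series.temperatures > threshold).astype(float) * cadence,
        index=series.timestamps,
    )
    return hot.groupby(hot.index.date).sum()


def degree_minutes(series: TemperatureSeries, base: float = 40.0) -> pd.Series:
    """Degree-minutes per calendar day: sum of max(0, t - base) * cadence."""
    cadence = _infer_cadence(series)
    series.validate(int(cadence))
    excess = pd.Series(
        np.clip(series.temperatures - base, 0.0, None) * cadence,
        index=series.timestamps,
    )
    return excess.groupby(excess.index.date).sum()


@dataclass
class TreatmentDailySummary:
    """Per-day thermal summary of one treatment's sensor record."""

    treatment_id: str
    day: object
    minutes_above_threshold: float
    degree_minutes: float


def daily_summaries(
    series_by_treatment: Mapping[str, TemperatureSeries],
    threshold: float = 40.0,
    base: float = 40.0,
) -> pd.DataFrame:
    """Tabulate per-day time-above and degree-minutes for several treatments."""
    rows = []
    for tid, series in series_by_treatment.items():
        ta = time_above(series, threshold)
        dm = degree_minutes(series, base)
        for day in ta.index:
            rows.append(
                TreatmentDailySummary(
                    treatment_id=tid,
                    day=day,
                    minutes_above_threshold=float(ta[day]),
                    degree_minutes=float(dm[day]),
                )
            )
    return pd.DataFrame([r.__dict__ for r in rows])


def levene(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """Classical (mean-centred) Levene test of variance homogeneity."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("Levene needs >= 2 groups with >= 2 observations each")
    W, p = stats.levene(*[np.asarray(g, float) for g in groups], center="mean")
    return float(W), float(p)


@dataclass
class AnovaResult:
    """One-way ANOVA with Tukey-Kramer post-hoc letters."""

    F: float
    df_between: int
    df_within: int
    p: float
    group_means: dict[str, float]
    group_sem: dict[str, float]
    letters: dict[str, str]
    pairwise_p: pd.DataFrame
    alpha: float


def _compact_letters(names: list[str], significant: np.ndarray, means: np.ndarray) -> dict[str, str]:
    """Compact letter display from a pairwise significance matrix.

    Each maximal clique of the "not significantly different" graph gets one
    letter, so significant pairs never share a letter and non-significant
    pairs always share at least one.  Letters are ordered by the clique's
    highest group mean.
    """
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(len(names)))
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if not significant[i, j]:
                g.add_edge(i, j)
    cliques = list(nx.find_cliques(g))
    cliques.sort(key=lambda c: -max(means[i] for i in c))
    letters: dict[str, list[str]] = {n: [] for n in names}
    for li, clique in enumerate(cliques):
        letter = chr(ord("a") + li)
        for i in clique:
            letters[names[i]].append(letter)
    return {n: "".join(sorted(v)) for n, v in letters.items()}


def anova_tukey(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> AnovaResult:
    """One-way ANOVA followed by Tukey-Kramer HSD with letters.

    ``groups`` maps group name to its observations.  The Tukey-Kramer
    procedure uses the studentised-range distribution with the unequal-n
    correction; pairs with adjusted p < alpha are declared different.
    """
    names = list(groups)
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("ANOVA needs >= 2 groups with >= 2 observations each")
    g = len(arrays)
    N = sum(len(a) for a in arrays)
    F, p = stats.f_oneway(*arrays)
    if not np.isfinite(F):  # zero variance within and between: no effect
        F, p = 0.0, 1.0
    means = np.array([a.mean() for a in arrays])
    sems = np.array([a.std(ddof=1) / np.sqrt(len(a)) for a in arrays])
    ns = np.array([len(a) for a in arrays])
    mse = sum(((a - a.mean()) ** 2).sum() for a in arrays) / (N - g)
    # Tukey-Kramer: q = |mi - mj| / sqrt(mse/2 * (1/ni + 1/nj))
    pair_p = np.ones((g, g))
    for i in range(g):
        for j in range(i + 1, g):
            if mse == 0:
                pij = 1.0 if means[i] == means[j] else 0.0
            else:
                q = abs(means[i] - means[j]) / np.sqrt(mse / 2 * (1 / ns[i] + 1 / ns[j]))
                pij = float(stats.studentized_range.sf(q, g, N - g))
            pair_p[i, j] = pair_p[j, i] = pij
    significant = pair_p < alpha
    letters = _compact_letters(names, significant, means)
    return AnovaResult(
        F=float(F),
        df_between=g - 1,
        df_within=N - g,
        p=float(p),
        group_means=dict(zip(names, means.tolist())),
        group_sem=dict(zip(names, sems.tolist())),
        letters=letters,
        pairwise_p=pd.DataFrame(pair_p, index=names, columns=names),
        alpha=alpha,
    )
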