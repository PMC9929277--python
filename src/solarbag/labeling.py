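"""Amortised thermal-lethality scoring of temperature episodes.

A temperature episode is a maximal run of readings at or above the lethal
threshold ``T`` (40 °C for rice weevil).  Within an episode, every minute at a
binned temperature level ``t >= T`` counts towards a weighted sum

    raw = sum_t  g_t / (D * 2**-(t - T))

where ``g_t`` is the accumulated minutes at level ``t`` and ``D`` is one day
(1440 min).  A full day at exactly ``T`` therefore scores 1, and each +1 °C
halves the required exposure.  The floored score ``s_hat = floor(raw)`` labels
an episode effective (lethal heating reached) when ``s_hat >= 1``.  The sum is
reset to zero whenever the temperature drops below the threshold — a
deliberately conservative rule: only uninterrupted heat exposure counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "LabelingConfig",
    "TemperatureSeries",
    "Episode",
    "EffectivenessScore",
    "SeriesValidationError",
    "segment_episodes",
    "required_minutes",
    "amortised_score",
    "label_series",
    "read_temperature_log",
    "write_labels",
]

#: Absolute slack applied before flooring, so that exposures that reach the
#: lethal dose exactly (raw == k) are not dropped to k-1 by float round-off.
_FLOOR_EPS = 1e-9


class SeriesValidationError(ValueError):
    """A temperature series violates its sampling invariants."""


@dataclass(frozen=True)
class LabelingConfig:
    """Parameters of the lethality score.

    Parameters
    ----------
    T : float
        Lethal temperature threshold in °C (default 40, the rice-weevil limit).
    D : int
        Minutes per day; the normaliser of the score (default 1440).
    bin_width : float
        Width in °C of the temperature bins the sum runs over (default 1).
        Readings are binned downward (conservative: exposure is never
        overstated).
    cadence : int
        Sampling interval of the logger in minutes (default 15).
    mode : {"running", "end_of_episode"}
        When, within an episode, per-reading labels flip to 1: as soon as the
        running sum reaches 1 (default), or retroactively for the whole
        episode once its final score is effective.
    """

    T: float = 40.0
    D: int = 1440
    bin_width: float = 1.0
    cadence: int = 15
    mode: Literal["running", "end_of_episode"] = "running"

    def __post_init__(self) -> None:
        if not (self.T > 0 and self.D > 0 and self.bin_width > 0 and self.cadence > 0):
            raise ValueError("T, D, bin_width and cadence must all be positive")
        if int(self.D) != self.D:
            raise ValueError("D must be an integer number of minutes")
        if self.mode not in ("running", "end_of_episode"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def bin_level(self, temperature: float) -> float:
        """Binned temperature level of a reading (downward, anchored at T)."""
        return self.T + math.floor((temperature - self.T) / self.bin_width) * self.bin_width


@dataclass
class TemperatureSeries:
    """Regularly sampled readings from one sensor position of one bag."""

    timestamps: pd.DatetimeIndex
    temperatures: np.ndarray
    position: str = "bottom"
    treatment_id: str = ""

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        if len(self.timestamps) != len(self.temperatures):
            raise SeriesValidationError(
                f"{len(self.timestamps)} timestamps vs {len(self.temperatures)} temperatures"
            )

    def __len__(self) -> int:
        return len(self.temperatures)

    def validate(self, cadence: int) -> None:
        """Check strictly increasing, constant-spacing timestamps and finite values."""
        if len(self) == 0:
            return
        if not np.all(np.isfinite(self.temperatures)):
            i = int(np.flatnonzero(~np.isfinite(self.temperatures))[0])
            raise SeriesValidationError(f"non-finite temperature at index {i}")
        if len(self) > 1:
            deltas = np.diff(self.timestamps.asi8) / 60e9  # minutes
            bad = np.flatnonzero(deltas <= 0)
            if bad.size:
                raise SeriesValidationError(
                    f"timestamps not strictly increasing at index {int(bad[0]) + 1}"
                )
            bad = np.flatnonzero(deltas != cadence)
            if bad.size:
                raise SeriesValidationError(
                    f"irregular cadence at index {int(bad[0]) + 1}: "
                    f"{deltas[bad[0]]:g} min, expected {cadence} min"
                )


@dataclass
class Episode:
    """A maximal contiguous run of readings at or above the threshold."""

    start_index: int
    end_index: int  # inclusive
    minutes_per_bin: dict[float, float] = field(default_factory=dict)

    @property
    def n_readings(self) -> int:
        return self.end_index - self.start_index + 1

    @property
    def total_minutes(self) -> float:
        return float(sum(self.minutes_per_bin.values()))


@dataclass(frozen=True)
class EffectivenessScore:
    """The amortised score of one episode and its binary verdict."""

    raw: float
    s_hat: int
    effective: bool

    @classmethod
    def from_raw(cls, raw: float) -> "EffectivenessScore":
        if raw < 0:
            raise ValueError(f"raw score must be non-negative, got {raw}")
        s_hat = int(math.floor(raw + _FLOOR_EPS))
        return cls(raw=raw, s_hat=s_hat, effective=s_hat >= 1)


def segment_episodes(series: TemperatureSeries, config: LabelingConfig) -> list[Episode]:
    """Split a series into maximal above-threshold episodes.

    Each reading in an episode contributes ``cadence`` minutes to the bin of
    its (downward-binned) temperature level.
    """
    series.validate(config.cadence)
    temps = series.temperatures
    hot = temps >= config.T
    episodes: list[Episode] = []
    if len(temps) == 0:
        return episodes
    # boundaries of runs of True
    padded = np.concatenate([[False], hot, [False]])
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:]) - 1
    for s, e in zip(starts, ends):
        bins: dict[float, float] = {}
        for temp in temps[s : e + 1]:
            level = config.bin_level(float(temp))
            bins[level] = bins.get(level, 0.0) + config.cadence
        episodes.append(Episode(start_index=int(s), end_index=int(e), minutes_per_bin=bins))
    return episodes


def required_minutes(t: float, config: LabelingConfig = LabelingConfig()) -> float:
    """Exposure minutes at level ``t`` that amount to one lethal dose.

    Equals ``D * 2**-(t - T)``: a full day at the threshold itself, halving
    with every degree above it (the logarithmic amortisation).
    """
    if t < config.T:
        raise ValueError(f"temperature level {t} below threshold T={config.T}")
    return config.D * 2.0 ** (-(t - config.T))


def amortised_score(episode: Episode, config: LabelingConfig = LabelingConfig()) -> EffectivenessScore:
    """Score one episode: ``raw = sum_t g_t / required_minutes(t)``."""
    raw = 0.0
    for level, minutes in episode.minutes_per_bin.items():
        if level < config.T:
            raise ValueError(
                f"episode bin {level} °C below threshold T={config.T} (invariant violation)"
            )
        raw += minutes / required_minutes(level, config)
    return EffectivenessScore.from_raw(raw)


def label_series(
    series: TemperatureSeries, config: LabelingConfig = LabelingConfig()
) -> tuple[np.ndarray, list[EffectivenessScore]]:
    """Label every reading of a series and score its episodes.

    Returns
    -------
    labels : ndarray of int
        Per-reading 0/1 labels.  Readings below the threshold are always 0.
        In ``running`` mode a reading is 1 once the episode's cumulative raw
        score, up to and including that reading, reaches 1; in
        ``end_of_episode`` mode all readings of a finally-effective episode
        are 1.
    scores : list of EffectivenessScore
        One final score per episode, in episode order.
    """
    episodes = segment_episodes(series, config)
    labels = np.zeros(len(series), dtype=int)
    scores: list[EffectivenessScore] = []
    for ep in episodes:
        scores.append(amortised_score(ep, config))
        if config.mode == "end_of_episode":
            if scores[-1].effective:
                labels[ep.start_index : ep.end_index + 1] = 1
        else:  # running
            cum = 0.0
            for i in range(ep.start_index, ep.end_index + 1):
                level = config.bin_level(float(series.temperatures[i]))
                cum += config.cadence / required_minutes(level, config)
                if cum + _FLOOR_EPS >= 1.0:
                    labels[i] = 1
    return labels, scores


# ---------------------------------------------------------------------------
# CSV interfaces


def read_temperature_log(path) -> list[TemperatureSeries]:
    """Read a thermocouple log CSV into one series per (treatment, position).

    Expected columns: ``timestamp`` (ISO-8601), ``position``,
    ``temperature_C``, ``treatment_id``.
    """
    frame = pd.read_csv(path, parse_dates=["timestamp"])
    required = {"timestamp", "position", "temperature_C", "treatment_id"}
    if not required <= set(frame.columns):
        raise ValueError(f"log must have columns {sorted(required)}")
    out = []
    for (treatment, position), grp in frame.groupby(["treatment_id", "position"], sort=True):
        grp = grp.sort_values("timestamp")
        out.append(
            TemperatureSeries(
                timestamps=pd.DatetimeIndex(grp["timestamp"]),
                temperatures=grp["temperature_C"].to_numpy(),
                position=str(position),
                treatment_id=str(treatment),
            )
        )
    return out


def write_labels(
    series: TemperatureSeries,
    config: LabelingConfig,
    path,
) -> pd.DataFrame:
    """Label a series and write readings + (raw_score, s_hat, label) as CSV.

    ``raw_score``/``s_hat`` report each reading's episode final score (0 for
    readings below the threshold); ``label`` follows the configured mode.
    """
    labels, scores = label_series(series, config)
    episodes = segment_episodes(series, config)
    raw = np.zeros(len(series))
    s_hat = np.zeros(len(series), dtype=int)
    for ep, sc in zip(episodes, scores):
        raw[ep.start_index : ep.end_index + 1] = sc.raw
        s_hat[ep.start_index : ep.end_index + 1] = sc.s_hat
    frame = pd.DataFrame(
        {
            "timestamp": series.timestamps,
            "position": series.position,
            "temperature_C": series.temperatures,
            "treatment_id": series.treatment_id,
            "raw_score": raw,
            "s_hat": s_hat,
            "label": labels,
        }
    )
    if path is not None:
        frame.to_csv(path, index=False)
    return frame
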