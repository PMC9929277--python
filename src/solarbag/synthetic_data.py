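"""Synthetic field data: weather forcing, bag thermal response, feature table.

Emulates a summer field campaign in which clear polyethylene bags of wheat
(16/21/25 kg in wooden boxes, plus 21 kg without a box) sit in the sun while a
weather station logs ambient conditions and thermocouples log bag temperatures
every 15 minutes.  The default scenario mirrors an 11-day campaign split into
a first 5-day part with nightly mixing/stacking of the bags and a second 6-day
part without.

No physically calibrated heat-transfer model of grain bulks is attempted; the
bag-bottom temperature is a first-order lumped response to an equilibrium
forcing (ambient + solar gain + mixing boost) whose gain and time constant
depend on grain mass and the wooden box.  The calibration plants the study's
qualitative structure: the 21 kg boxed bag heats most (an interior optimum in
grain mass), above-threshold episodes are rare, and the class label produced
by the lethality engine is severely imbalanced (~1-2% positive).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from . import schema
from .labeling import LabelingConfig, TemperatureSeries, label_series

__all__ = [
    "WeatherConfig",
    "TreatmentSpec",
    "BagThermalParams",
    "DEFAULT_TREATMENTS",
    "default_thermal_params",
    "simulate_weather",
    "simulate_bag_temperature",
    "build_feature_table",
    "Scenario",
    "generate_scenario",
]


@dataclass(frozen=True)
class WeatherConfig:
    """Diurnal weather generator settings.

    Defaults emulate a hot Canadian-prairie summer spell: mean ambient 23 °C
    with an 8 °C diurnal swing peaking mid-afternoon, day-to-day heat-wave
    offsets, clear-sky solar flux peaking at 900 kJ/m² per 15-min interval
    (~1 kW/m²), RH anti-correlated with temperature, and occasional rain days
    with attenuated sun.
    """

    n_days: int = 11
    cadence: int = 15  # minutes
    ambient_mean: float = 23.0  # °C
    ambient_amplitude: float = 8.0  # °C, half the diurnal swing
    day_sigma: float = 1.0  # °C, sd of day-level heat-wave offset
    noise_sd: float = 0.35  # °C, within-day AR(1) noise
    rh_mean: float = 62.0  # %
    rh_amplitude: float = 14.0  # %
    solar_peak: float = 26.0  # MJ/m², clear-sky daily cumulative radiation
    flux_peak: float = 900.0  # kJ/m² per interval at solar noon, clear sky
    wind_mean: float = 2.5  # m/s
    pressure_mean: float = 96.0  # kPa
    rain_prob: float = 0.15  # probability a day is rainy
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.cadence <= 0:
            raise ValueError("cadence must be positive")
        if self.ambient_amplitude < 0 or self.rh_amplitude < 0:
            raise ValueError("amplitudes must be >= 0")
        if not 0.0 <= self.rain_prob <= 1.0:
            raise ValueError("rain_prob must lie in [0, 1]")


@dataclass(frozen=True)
class TreatmentSpec:
    """One experimental treatment: grain mass, wooden box, mixing/stacking."""

    mass_kg: int
    in_box: bool
    mixing_stacking: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        if self.mass_kg not in (16, 21, 25):
            raise ValueError("mass_kg must be one of 16, 21, 25")
        if self.mass_kg != 21 and not self.in_box:
            raise ValueError("only the 21 kg treatment was run without a box")
        if not self.name:
            suffix = "box" if self.in_box else "no_box"
            object.__setattr__(self, "name", f"kg{self.mass_kg}_{suffix}")


#: The four field treatments, keyed by their one-hot flag column.
DEFAULT_TREATMENTS: tuple[TreatmentSpec, ...] = (
    TreatmentSpec(16, True),
    TreatmentSpec(21, True),
    TreatmentSpec(25, True),
    TreatmentSpec(21, False),
)


@dataclass(frozen=True)
class BagThermalParams:
    """Lumped first-order thermal response of the bag bottom.

    ``solar_gain`` is the equilibrium temperature excess per kJ/m² of
    15-minute solar flux; ``time_constant`` (minutes) grows with grain mass —
    grain is a good insulator, so thicker bulks lag the forcing more;
    ``loss_rate`` scales the relaxation rate while cooling (grain sheds heat
    more slowly than it gains it); ``mixing_boost`` is the additive °C applied
    while the bags are mixed and stacked.
    """

    solar_gain: float  # °C per (kJ/m² per interval)
    time_constant: float  # minutes
    loss_rate: float = 0.9
    mixing_boost: float = 0.0
    #: sd (°C) of slowly varying unobserved bag-level disturbance — substrate,
    #: handling and sensor-placement effects the weather station cannot see
    response_noise_sd: float = 2.6

    def __post_init__(self) -> None:
        if self.time_constant <= 0:
            raise ValueError("time_constant must be positive")
        if self.solar_gain < 0:
            raise ValueError("solar_gain must be >= 0")


# gain rises with mass (bigger absorber) while the lag also rises, so the
# peak response has an interior maximum at the 21 kg boxed bag
_GAIN_BY_MASS = {16: 0.0100, 21: 0.0198, 25: 0.0115}
_TAU_BY_MASS = {16: 110.0, 21: 150.0, 25: 215.0}
_NO_BOX_GAIN_FACTOR = 0.42


def default_thermal_params(treatment: TreatmentSpec) -> BagThermalParams:
    """Default calibration for one treatment."""
    gain = _GAIN_BY_MASS[treatment.mass_kg]
    if not treatment.in_box:
        gain *= _NO_BOX_GAIN_FACTOR
    return BagThermalParams(
        solar_gain=gain,
        time_constant=_TAU_BY_MASS[treatment.mass_kg],
        loss_rate=0.9,
        mixing_boost=1.0,
    )


def simulate_weather(config: WeatherConfig) -> pd.DataFrame:
    """Generate a 15-minute weather-station record.

    Returns a DataFrame indexed by timestamp with columns ``ambient_temp_C``,
    ``air_rh_pct``, ``solar_radiation_MJ_m2`` (day-cumulative),
    ``solar_flux_KJ_m2`` (instantaneous per interval), ``wind_speed_m_s``,
    ``wind_direction_deg``, ``air_pressure_kPa`` and ``rain`` (day flag).
    Identical seeds give identical series.
    """
    rng = np.random.default_rng(config.seed)
    per_day = (24 * 60) // config.cadence
    n = config.n_days * per_day
    index = pd.date_range("2018-07-26", periods=n, freq=f"{config.cadence}min")
    hour = index.hour.to_numpy() + index.minute.to_numpy() / 60.0
    day = np.repeat(np.arange(config.n_days), per_day)

    # day-level heat-wave offsets, standardised within the campaign so every
    # campaign has a comparable hottest-spell excursion (randomly placed)
    day_offset = rng.normal(0.0, 1.0, size=config.n_days)
    if config.n_days > 1 and day_offset.std() > 0:
        day_offset = (day_offset - day_offset.mean()) / day_offset.std()
    day_offset = day_offset * config.day_sigma
    rain_day = rng.random(config.n_days) < config.rain_prob
    # cloudiness: clear-ish on dry days, heavily overcast on rain days
    cloud = rng.uniform(0.96, 1.0, size=config.n_days)
    cloud[rain_day] = rng.uniform(0.15, 0.35, size=int(rain_day.sum()))

    # short-memory measurement noise (persistence kept low: slowly varying
    # station noise would act as a day fingerprint no physical driver explains)
    eps = rng.normal(0.0, config.noise_sd, size=n)
    noise = np.empty(n)
    acc = 0.0
    for i in range(n):
        acc = 0.3 * acc + eps[i]
        noise[i] = acc

    diurnal = np.sin(2 * np.pi * (hour - 9.0) / 24.0)  # peaks at 15:00
    ambient = (
        config.ambient_mean
        + config.ambient_amplitude * diurnal
        + day_offset[day]
        - 2.0 * rain_day[day]
        + noise
    )

    daylight = np.clip(np.sin(np.pi * (hour - 6.0) / 12.0), 0.0, None)
    flux = config.flux_peak * daylight * cloud[day]
    flux += rng.normal(0.0, 8.0, size=n) * (flux > 0)
    flux = np.clip(flux, 0.0, None)
    # day-cumulative radiation in MJ/m²
    radiation = np.concatenate(
        [np.cumsum(flux[day == d]) / 1000.0 for d in range(config.n_days)]
    )
    radiation *= config.solar_peak / max(
        1e-9, config.flux_peak * daylight[:per_day].sum() / 1000.0
    )
    radiation = np.clip(radiation + rng.normal(0.0, 0.6, size=n), 0.0, None)

    rh = (
        config.rh_mean
        - config.rh_amplitude * diurnal
        - 0.8 * day_offset[day]
        + 12.0 * rain_day[day]
        + rng.normal(0.0, 7.0, size=n)
    )
    rh = np.clip(rh, 0.0, 100.0)

    wind = np.abs(rng.normal(config.wind_mean, 0.9, size=n))
    direction = np.mod(
        rng.uniform(0, 360) + rng.normal(0, 30.0, size=n), 360.0
    )
    pressure = config.pressure_mean + rng.normal(0.0, 0.15, size=n)

    return pd.DataFrame(
        {
            "ambient_temp_C": ambient,
            "air_rh_pct": rh,
            "solar_radiation_MJ_m2": radiation,
            "solar_flux_KJ_m2": flux,
            "wind_speed_m_s": wind,
            "wind_direction_deg": direction,
            "air_pressure_kPa": pressure,
            "rain": rain_day[day].astype(int),
        },
        index=index,
    )


def simulate_bag_temperature(
    weather: pd.DataFrame,
    treatment: TreatmentSpec,
    params: BagThermalParams | None = None,
    mixing: np.ndarray | None = None,
    cadence: int | None = None,
    seed: int = 0,
) -> TemperatureSeries:
    """Integrate the bag-bottom temperature under the weather forcing.

    Explicit-Euler first-order relaxation towards the instantaneous
    equilibrium ``T_eq = ambient + solar_gain * flux + mixing_boost * mix``,
    plus a slowly varying seeded AR(1) disturbance of sd
    ``params.response_noise_sd`` representing bag-level effects the weather
    record cannot explain.  ``mixing`` optionally supplies a per-interval 0/1
    array overriding the treatment's constant flag.
    """
    if params is None:
        params = default_thermal_params(treatment)
    if cadence is None:
        step = weather.index[1] - weather.index[0]
        cadence = int(step.total_seconds() // 60)
    if params.time_constant <= cadence / 2:
        raise ValueError(
            f"time_constant {params.time_constant} min is unstably short for "
            f"cadence {cadence} min (requires > cadence/2)"
        )
    ambient = weather["ambient_temp_C"].to_numpy()
    flux = weather["solar_flux_KJ_m2"].to_numpy()
    n = len(ambient)
    if mixing is None:
        mixing = np.full(n, float(treatment.mixing_stacking))
    mixing = np.asarray(mixing, dtype=float)
    t_eq = ambient + params.solar_gain * flux + params.mixing_boost * mixing
    if params.response_noise_sd > 0:
        rng = np.random.default_rng(seed)
        # AR(1) with ~5 h correlation time at 15-min cadence
        phi = 0.95 ** (cadence / 15.0)
        innov = rng.normal(0.0, params.response_noise_sd * np.sqrt(1 - phi**2), size=n)
        disturb = np.empty(n)
        acc = rng.normal(0.0, params.response_noise_sd)
        for i in range(n):
            acc = phi * acc + innov[i]
            disturb[i] = acc
        t_eq = t_eq + disturb
    temp = np.empty(n)
    temp[0] = ambient[0]
    for i in range(1, n):
        drive = t_eq[i - 1] - temp[i - 1]
        rate = cadence / params.time_constant
        if drive < 0:
            rate *= params.loss_rate
        temp[i] = temp[i - 1] + rate * drive
    return TemperatureSeries(
        timestamps=weather.index,
        temperatures=temp,
        position="bottom",
        treatment_id=treatment.name,
    )


def build_feature_table(
    weather: pd.DataFrame,
    labels_by_treatment: Mapping[str, np.ndarray],
    mixing: np.ndarray | None = None,
) -> pd.DataFrame:
    """Assemble the 14-column observation table: one row per (timestamp x treatment).

    ``labels_by_treatment`` maps treatment flag names (e.g. ``kg21_box``) to
    per-reading 0/1 labels from the lethality engine, aligned with
    ``weather``'s index.
    """
    n = len(weather)
    if mixing is None:
        mixing = np.zeros(n)
    frames = []
    for name, labels in labels_by_treatment.items():
        if name not in schema.TREATMENT_COLUMNS:
            raise ValueError(f"unknown treatment {name!r}")
        labels = np.asarray(labels)
        if len(labels) != n:
            raise ValueError(
                f"labels for {name} have {len(labels)} rows but weather has {n} "
                "(timestamp misalignment)"
            )
        block = pd.DataFrame(
            {
                "air_rh_pct": weather["air_rh_pct"].to_numpy(),
                "ambient_temp_C": weather["ambient_temp_C"].to_numpy(),
                "solar_radiation_MJ_m2": weather["solar_radiation_MJ_m2"].to_numpy(),
                "solar_flux_KJ_m2": weather["solar_flux_KJ_m2"].to_numpy(),
                "wind_speed_m_s": weather["wind_speed_m_s"].to_numpy(),
                "air_pressure_kPa": weather["air_pressure_kPa"].to_numpy(),
                "wind_direction_deg": weather["wind_direction_deg"].to_numpy(),
                "rain": weather["rain"].to_numpy(),
                "mixing_stacking": np.asarray(mixing, dtype=int),
                "class_label": labels.astype(int),
            }
        )
        for col in schema.TREATMENT_COLUMNS:
            block[col] = int(col == name)
        frames.append(block)
    table = pd.concat(frames, ignore_index=True)
    return schema.validate_feature_table(table)


@dataclass
class Scenario:
    """A fully generated campaign: weather, bag series, labels, feature table."""

    weather: pd.DataFrame
    series: dict[str, TemperatureSeries]
    labels: dict[str, np.ndarray]
    table: pd.DataFrame
    mixing: np.ndarray
    config: WeatherConfig
    labeling: LabelingConfig = field(default_factory=LabelingConfig)

    @property
    def prevalence(self) -> float:
        """Positive-class fraction of the feature table."""
        return float(self.table["class_label"].mean())


def generate_scenario(
    config: WeatherConfig | None = None,
    labeling: LabelingConfig | None = None,
    seed: int | None = None,
    mixing_days: int = 5,
) -> Scenario:
    """Run the full default campaign: weather -> bag temps -> labels -> table.

    The first ``mixing_days`` days carry the mixing/stacking flag (the first
    field part), the remainder do not.  Labels come from the bag-bottom
    sensor, the coldest and hence most conservative position.
    """
    config = config or WeatherConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    labeling = labeling or LabelingConfig(cadence=config.cadence)
    weather = simulate_weather(config)
    per_day = (24 * 60) // config.cadence
    day = np.arange(len(weather)) // per_day
    mixing = (day < mixing_days).astype(float)
    series: dict[str, TemperatureSeries] = {}
    labels: dict[str, np.ndarray] = {}
    for ti, treatment in enumerate(DEFAULT_TREATMENTS):
        s = simulate_bag_temperature(
            weather, treatment, mixing=mixing, seed=config.seed * 7919 + ti
        )
        series[treatment.name] = s
        labels[treatment.name], _ = label_series(s, labeling)
    table = build_feature_table(weather, labels, mixing=mixing)
    return Scenario(
        weather=weather,
        series=series,
        labels=labels,
        table=table,
        mixing=mixing,
        config=config,
        labeling=labeling,
    )
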