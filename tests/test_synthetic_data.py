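"""Tests for the synthetic field-campaign generator."""

import numpy as np
import pandas as pd
import pytest

from solarbag import schema
from solarbag.resampling import random_undersample
from solarbag.synthetic_data import (
    DEFAULT_TREATMENTS,
    BagThermalParams,
    TreatmentSpec,
    WeatherConfig,
    build_feature_table,
    default_thermal_params,
    generate_scenario,
    simulate_bag_temperature,
    simulate_weather,
)


class TestWeather:
    def test_config_validation(self):
        with pytest.raises(ValueError):
            WeatherConfig(n_days=0)
        with pytest.raises(ValueError):
            WeatherConfig(cadence=0)
        with pytest.raises(ValueError):
            WeatherConfig(rain_prob=1.5)

    def test_determinism_and_seed_sensitivity(self):
        a = simulate_weather(WeatherConfig(n_days=3, seed=5))
        b = simulate_weather(WeatherConfig(n_days=3, seed=5))
        c = simulate_weather(WeatherConfig(n_days=3, seed=6))
        pd.testing.assert_frame_equal(a, b)
        assert not np.allclose(a["ambient_temp_C"], c["ambient_temp_C"])

    def test_degenerate_forcing_gives_constant_ambient(self):
        cfg = WeatherConfig(
            n_days=2, ambient_amplitude=0, day_sigma=0, noise_sd=0, rain_prob=0
        )
        w = simulate_weather(cfg)
        assert np.allclose(w["ambient_temp_C"], cfg.ambient_mean)

    def test_physical_ranges_on_default_week(self):
        w = simulate_weather(WeatherConfig(n_days=6, seed=1))
        assert w["air_rh_pct"].between(0, 100).all()
        assert (w["solar_flux_KJ_m2"] >= 0).all()
        assert (w["solar_radiation_MJ_m2"] >= 0).all()
        assert w["wind_direction_deg"].between(0, 360, inclusive="left").all()
        # night-time flux is zero
        night = w.index.hour < 5
        assert np.allclose(w.loc[night, "solar_flux_KJ_m2"], 0.0)


class TestTreatments:
    def test_the_four_field_treatments_are_expressible(self):
        names = {t.name for t in DEFAULT_TREATMENTS}
        assert names == {"kg16_box", "kg21_box", "kg25_box", "kg21_no_box"}

    def test_no_box_only_for_21kg(self):
        with pytest.raises(ValueError):
            TreatmentSpec(16, False)

    def test_mass_dependent_lag(self):
        taus = [default_thermal_params(TreatmentSpec(m, True)).time_constant for m in (16, 21, 25)]
        assert taus == sorted(taus)


class TestBagTemperature:
    def test_pure_relaxation_converges_to_ambient(self):
        cfg = WeatherConfig(n_days=3, ambient_amplitude=0, day_sigma=0, noise_sd=0, rain_prob=0)
        w = simulate_weather(cfg)
        params = BagThermalParams(solar_gain=0, time_constant=120, response_noise_sd=0)
        s = simulate_bag_temperature(w, DEFAULT_TREATMENTS[1], params=params)
        gaps = np.abs(s.temperatures - w["ambient_temp_C"].to_numpy())
        assert gaps[-1] < 1e-6

    def test_doubled_time_constant_lowers_the_peak(self):
        w = simulate_weather(WeatherConfig(n_days=4, seed=2))
        base = BagThermalParams(solar_gain=0.018, time_constant=120, response_noise_sd=0)
        slow = BagThermalParams(solar_gain=0.018, time_constant=240, response_noise_sd=0)
        t1 = simulate_bag_temperature(w, DEFAULT_TREATMENTS[1], params=base)
        t2 = simulate_bag_temperature(w, DEFAULT_TREATMENTS[1], params=slow)
        assert t2.temperatures.max() < t1.temperatures.max()

    def test_unstable_time_constant_is_an_error(self):
        w = simulate_weather(WeatherConfig(n_days=1))
        with pytest.raises(ValueError, match="unstabl"):
            simulate_bag_temperature(
                w, DEFAULT_TREATMENTS[0], params=BagThermalParams(0.01, time_constant=7.0)
            )

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_interior_maximum_in_mass(self, seed, scenarios):
        """The 21 kg boxed bag spends by far the most time above 40 °C — the
        single interior maximum in grain mass among the boxed treatments."""
        sc = scenarios(seed)
        mins = {k: int((s.temperatures > 40).sum()) for k, s in sc.series.items()}
        assert mins["kg21_box"] > max(
            mins["kg16_box"], mins["kg25_box"], mins["kg21_no_box"]
        )

    def test_mean_exceedance_ordering_over_campaigns(self, scenarios):
        """Averaged over campaigns the boxed masses order 21 > 16 > 25, with
        the boxless bag weakest."""
        totals = {k: 0 for k in ("kg16_box", "kg21_box", "kg25_box", "kg21_no_box")}
        for seed in range(4):
            for k, s in scenarios(seed).series.items():
                totals[k] += int((s.temperatures > 40).sum())
        assert totals["kg21_box"] > totals["kg16_box"] > totals["kg25_box"]
        assert totals["kg16_box"] > totals["kg21_no_box"]


class TestFeatureTable:
    def test_row_count_one_day_four_treatments(self):
        cfg = WeatherConfig(n_days=1, seed=0)
        w = simulate_weather(cfg)
        labels = {t.name: np.zeros(len(w), dtype=int) for t in DEFAULT_TREATMENTS}
        table = build_feature_table(w, labels)
        assert len(table) == 96 * 4

    def test_all_cold_weather_gives_all_negative(self):
        sc = generate_scenario(WeatherConfig(ambient_mean=8.0, n_days=3, seed=0))
        assert sc.table["class_label"].sum() == 0

    def test_one_hot_and_schema_hold(self, scenarios):
        table = scenarios(0).table
        assert schema.validate_feature_table(table) is not None
        assert (table[schema.TREATMENT_COLUMNS].sum(axis=1) == 1).all()

    def test_misaligned_labels_are_a_join_error(self):
        w = simulate_weather(WeatherConfig(n_days=1))
        with pytest.raises(ValueError, match="misalignment"):
            build_feature_table(w, {"kg21_box": np.zeros(10)})


class TestPlantedStructure:
    def test_prevalence_in_calibrated_band(self, scenarios):
        assert 0.005 <= scenarios(0).prevalence <= 0.03

    def test_prevalence_monotone_in_ambient_mean(self):
        prevs = [
            generate_scenario(WeatherConfig(ambient_mean=m, seed=3)).prevalence
            for m in (21.0, 23.0, 25.0)
        ]
        assert prevs[0] <= prevs[1] <= prevs[2]
        assert prevs[2] > prevs[0]

    @pytest.mark.parametrize("seed", [1, 2])
    def test_planted_drivers_dominate_their_feature_groups(self, seed, scenarios):
        """On the class-balanced view, the 21 kg box flag is the strongest
        binary association and ambient temperature the strongest continuous
        one — the ground truth the explanation stage must recover."""
        table = random_undersample(scenarios(seed).table, seed=seed).table
        y = table["class_label"].to_numpy()

        def assoc(col):
            v = np.corrcoef(table[col], y)[0, 1]
            return 0.0 if np.isnan(v) else abs(v)

        top_binary = max(schema.BINARY_COLUMNS, key=assoc)
        cont_sorted = sorted(schema.CONTINUOUS_COLUMNS, key=assoc, reverse=True)
        assert top_binary == "kg21_box"
        assert "ambient_temp_C" in cont_sorted[:2]

    def test_distinct_seeds_give_distinct_labels(self, scenarios):
        a = scenarios(0).table["class_label"].to_numpy()
        b = scenarios(1).table["class_label"].to_numpy()
        assert not np.array_equal(a, b)
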