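"""Unit and property tests for the amortised lethality score."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from solarbag.labeling import (
    Episode,
    LabelingConfig,
    SeriesValidationError,
    amortised_score,
    label_series,
    required_minutes,
    segment_episodes,
)

from conftest import make_series

CFG = LabelingConfig()


def minute_oracle(temps, config=CFG):
    """Independent per-minute simulator: expand each reading into one-minute
    ticks and accumulate tick / required_minutes(bin), resetting below T."""
    raws, cur, inside = [], 0.0, False
    for t in temps:
        if t >= config.T:
            level = config.bin_level(float(t))
            for _ in range(config.cadence):
                cur += 1.0 / required_minutes(level, config)
            inside = True
        else:
            if inside:
                raws.append(cur)
            cur, inside = 0.0, False
    if inside:
        raws.append(cur)
    return raws


class TestRequiredMinutes:
    @pytest.mark.parametrize(
        "t,expected",
        [(40.0, 1440.0), (45.0, 45.0), (50.0, 1.40625), (41.0, 720.0)],
    )
    def test_halving_per_degree(self, t, expected):
        assert required_minutes(t, CFG) == pytest.approx(expected, abs=1e-12)

    def test_below_threshold_is_domain_error(self):
        with pytest.raises(ValueError, match="below threshold"):
            required_minutes(39.9, CFG)


class TestSegmentEpisodes:
    def test_all_cold_gives_no_episodes(self):
        assert segment_episodes(make_series([30, 35, 39.9]), CFG) == []

    def test_all_hot_gives_one_full_episode(self):
        eps = segment_episodes(make_series([41, 44, 42, 40]), CFG)
        assert len(eps) == 1
        assert (eps[0].start_index, eps[0].end_index) == (0, 3)
        assert eps[0].total_minutes == 4 * 15

    def test_two_episode_example(self):
        eps = segment_episodes(make_series([38, 41, 42, 39, 45]), CFG)
        assert [(e.start_index, e.end_index) for e in eps] == [(1, 2), (4, 4)]
        assert eps[0].minutes_per_bin == {41.0: 15.0, 42.0: 15.0}
        assert eps[1].minutes_per_bin == {45.0: 15.0}

    def test_irregular_cadence_names_offending_index(self):
        import pandas as pd

        from solarbag.labeling import TemperatureSeries

        idx = pd.to_datetime(["2018-07-26 00:00", "2018-07-26 00:15", "2018-07-26 00:45"])
        s = TemperatureSeries(timestamps=idx, temperatures=np.array([41.0, 42.0, 43.0]))
        with pytest.raises(SeriesValidationError, match="index 2"):
            segment_episodes(s, CFG)

    def test_non_monotone_timestamps_rejected(self):
        import pandas as pd

        from solarbag.labeling import TemperatureSeries

        idx = pd.to_datetime(["2018-07-26 00:00", "2018-07-26 00:30", "2018-07-26 00:15"])
        s = TemperatureSeries(timestamps=idx, temperatures=np.array([41.0, 42.0, 43.0]))
        with pytest.raises(SeriesValidationError, match="increasing"):
            segment_episodes(s, CFG)


class TestAmortisedScore:
    @pytest.mark.parametrize(
        "temps,raw,s_hat,effective",
        [
            ([40.0] * 96, 1.0, 1, True),  # a full day at the threshold
            ([45.0] * 3, 1.0, 1, True),  # 45 min at 45 °C
            ([45.0] * 2, 30 / 45, 0, False),
        ],
    )
    def test_worked_examples(self, temps, raw, s_hat, effective):
        (ep,) = segment_episodes(make_series(temps), CFG)
        score = amortised_score(ep, CFG)
        assert score.raw == pytest.approx(raw, abs=1e-12)
        assert score.s_hat == s_hat
        assert score.effective is effective

    def test_cold_bin_key_violates_invariant(self):
        ep = Episode(start_index=0, end_index=0, minutes_per_bin={39.0: 15.0})
        with pytest.raises(ValueError, match="invariant"):
            amortised_score(ep, CFG)

    def test_empty_episode_scores_zero(self):
        score = amortised_score(Episode(0, -1, {}), CFG)
        assert score.raw == 0.0 and not score.effective


class TestLabelSeries:
    def test_all_cold_all_zero(self):
        labels, scores = label_series(make_series([35] * 10), CFG)
        assert labels.sum() == 0 and scores == []

    def test_running_mode_flips_at_cumulative_dose(self):
        labels, scores = label_series(make_series([45, 45, 45]), CFG)
        assert labels.tolist() == [0, 0, 1]
        assert scores[0].s_hat == 1

    def test_end_of_episode_mode_labels_whole_episode(self):
        cfg = LabelingConfig(mode="end_of_episode")
        labels, _ = label_series(make_series([45, 45, 45]), cfg)
        assert labels.tolist() == [1, 1, 1]

    def test_readings_below_threshold_never_labelled(self):
        labels, _ = label_series(make_series([39, 45, 45, 45, 39]), CFG)
        assert labels[0] == 0 and labels[-1] == 0


temps_strategy = st.lists(
    st.floats(min_value=25.0, max_value=55.0, allow_nan=False, allow_infinity=False),
    min_size=1,
    max_size=60,
)


class TestScoreProperties:
    @given(temps=temps_strategy)
    @settings(max_examples=150, derandomize=True)
    def test_oracle_equivalence(self, temps):
        eps = segment_episodes(make_series(temps), CFG)
        raws = [amortised_score(e, CFG).raw for e in eps]
        oracle = minute_oracle(temps)
        assert len(raws) == len(oracle)
        assert np.allclose(raws, oracle, atol=1e-9, rtol=0)

    @given(temps=st.lists(st.floats(40.0, 54.0, allow_nan=False), min_size=1, max_size=30))
    @settings(max_examples=100, derandomize=True)
    def test_appending_hot_reading_never_decreases_raw(self, temps):
        (ep,) = segment_episodes(make_series(temps), CFG)
        (ep2,) = segment_episodes(make_series(temps + [41.0]), CFG)
        assert amortised_score(ep2, CFG).raw >= amortised_score(ep, CFG).raw

    @given(
        temps=st.lists(st.floats(40.0, 50.0, allow_nan=False), min_size=1, max_size=30),
        idx=st.integers(0, 29),
        bump=st.floats(0.0, 4.0, allow_nan=False),
    )
    @settings(max_examples=100, derandomize=True)
    def test_raising_a_reading_never_decreases_raw(self, temps, idx, bump):
        idx %= len(temps)
        hotter = list(temps)
        hotter[idx] += bump
        (ep,) = segment_episodes(make_series(temps), CFG)
        (ep2,) = segment_episodes(make_series(hotter), CFG)
        assert amortised_score(ep2, CFG).raw >= amortised_score(ep, CFG).raw - 1e-12

    @given(level=st.integers(40, 53), m=st.integers(1, 40))
    @settings(max_examples=80, derandomize=True)
    def test_doubling_law(self, level, m):
        # m minutes at T+1 scores exactly as 2m minutes at T (integer bins)
        hi = Episode(0, 0, {float(level + 1): float(m)})
        lo = Episode(0, 0, {float(level): float(2 * m)})
        cfg = LabelingConfig(T=float(level))
        assert amortised_score(hi, cfg).raw == amortised_score(lo, cfg).raw

    @given(
        left=st.lists(st.floats(40.0, 50.0, allow_nan=False), min_size=1, max_size=15),
        right=st.lists(st.floats(40.0, 50.0, allow_nan=False), min_size=1, max_size=15),
    )
    @settings(max_examples=80, derandomize=True)
    def test_reset_splits_never_gain(self, left, right):
        merged = segment_episodes(make_series(left + right), CFG)
        merged_raw = sum(amortised_score(e, CFG).raw for e in merged)
        split = segment_episodes(make_series(left + [35.0] + right), CFG)
        assert len(split) == 2
        for e in split:
            assert amortised_score(e, CFG).raw <= merged_raw + 1e-12
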