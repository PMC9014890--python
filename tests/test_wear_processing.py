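import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wearweek import device_io, wear_processing
from wearweek.exceptions import ValidationError
from wearweek.wear_processing import WearConfig

from conftest import make_epoch_day
from oracles import mvpa_minutes_oracle, wear_mask_oracle

CFG = WearConfig()


def minutes_from_cadence(cadence, day="2020-02-17", start_minute=540):
    ts = pd.Timestamp(day) + pd.to_timedelta(start_minute + np.arange(len(cadence)), unit="m")
    cadence = np.asarray(cadence, dtype=np.int64)
    return pd.DataFrame(
        {
            "participant_id": "P1",
            "timestamp": ts,
            "steps": cadence,
            "motion_intensity": np.where(cadence > 0, np.maximum(cadence // 10, 1), 0),
        }
    )


class TestDetectNonwear:
    def test_short_and_long_zero_runs(self):
        epochs = make_epoch_day([0, 0, 0, 2, 0, 0])
        wear = wear_processing.detect_nonwear(epochs, CFG)
        assert wear.tolist() == [False, False, False, True, True, True]

    def test_run_below_threshold_is_wear(self):
        epochs = make_epoch_day([0, 0])
        assert wear_processing.detect_nonwear(epochs, CFG).tolist() == [True, True]

    def test_unordered_input_rejected(self):
        epochs = make_epoch_day([0, 1, 0]).iloc[::-1].reset_index(drop=True)
        with pytest.raises(ValidationError):
            wear_processing.detect_nonwear(epochs, CFG)

    def test_zero_run_split_at_midnight(self):
        # two zero epochs before midnight + two after: neither day reaches 3
        start = pd.Timestamp("2020-02-17 23:30")
        epochs = pd.DataFrame(
            {
                "participant_id": "P1",
                "epoch_start": start + pd.to_timedelta(np.arange(4) * 15, unit="m"),
                "steps": 0,
                "max_motion_intensity": 0,
                "n_minutes_observed": 0,
            }
        )
        assert wear_processing.detect_nonwear(epochs, CFG).all()

    def test_random_sequences_match_window_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(300):
            n = int(rng.integers(1, 97))
            pattern = rng.integers(0, 2, size=n)
            epochs = make_epoch_day(pattern)
            wear = wear_processing.detect_nonwear(epochs, CFG)
            np.testing.assert_array_equal(wear, wear_mask_oracle(pattern, 3))

    def test_nonzero_intensity_epochs_always_wear(self):
        rng = np.random.default_rng(4)
        pattern = rng.integers(0, 3, size=96)
        epochs = make_epoch_day(pattern)
        wear = wear_processing.detect_nonwear(epochs, CFG)
        assert wear[pattern > 0].all()

    @given(st.integers(min_value=1, max_value=6))
    @settings(derandomize=True)
    def test_min_run_parameter_respected(self, min_run):
        cfg = WearConfig(nonwear_min_run_epochs=min_run)
        pattern = [0] * (min_run - 1) + [1] + [0] * min_run
        epochs = make_epoch_day(pattern)
        wear = wear_processing.detect_nonwear(epochs, cfg)
        assert wear[: min_run - 1].all() and wear[min_run - 1]
        assert not wear[min_run:].any()


class TestWearMinutesInWindow:
    def test_all_window_epochs_worn(self):
        epochs = make_epoch_day([1] * 96)  # full day, all worn
        wear = wear_processing.detect_nonwear(epochs, CFG)
        got = wear_processing.wear_minutes_in_window(epochs, wear, dt.date(2020, 2, 17), CFG)
        assert got == 720

    def test_eight_hour_boundary(self):
        # worn for exactly 32 epochs starting 09:00, zero elsewhere
        pattern = np.zeros(96, int)
        pattern[36:68] = 1
        epochs = make_epoch_day(pattern)
        wear = wear_processing.detect_nonwear(epochs, CFG)
        got = wear_processing.wear_minutes_in_window(epochs, wear, dt.date(2020, 2, 17), CFG)
        assert got == 480

    def test_random_masks_match_enumeration(self):
        rng = np.random.default_rng(5)
        epochs = make_epoch_day(rng.integers(0, 2, size=96))
        for _ in range(50):
            mask = rng.random(96) < 0.5
            got = wear_processing.wear_minutes_in_window(
                epochs, mask, dt.date(2020, 2, 17), CFG
            )
            expected = 15 * sum(
                bool(m) and dt.time(9) <= ts.time() < dt.time(21)
                for m, ts in zip(mask, epochs["epoch_start"])
            )
            assert got == expected

    def test_misaligned_mask_rejected(self):
        epochs = make_epoch_day([1, 1, 1])
        with pytest.raises(ValidationError):
            wear_processing.wear_minutes_in_window(
                epochs, np.ones(2, bool), dt.date(2020, 2, 17), CFG
            )


class TestDetectMvpaMinutes:
    @pytest.mark.parametrize(
        "cadence,expected",
        [
            ([105] * 10, 10),  # exactly meets the 10-min walking bout
            ([105] * 9, 0),  # below bout length
            ([140], 1),  # a single running minute counts
            ([105] * 9 + [140], 10),  # run minute completes a walk bout
            ([50] * 5 + [105] * 10 + [50] * 5, 10),
            ([140, 0, 140], 2),  # two separate running minutes
        ],
    )
    def test_bout_rule_examples(self, cadence, expected):
        minutes = minutes_from_cadence(cadence)
        assert wear_processing.detect_mvpa_minutes(minutes, CFG) == expected

    def test_timestamp_gap_breaks_walking_bout(self):
        minutes = minutes_from_cadence([105] * 10)
        minutes.loc[5:, "timestamp"] += pd.Timedelta(minutes=3)
        assert wear_processing.detect_mvpa_minutes(minutes, CFG) == 0

    def test_multi_day_input_rejected(self):
        minutes = minutes_from_cadence([105] * 10)
        minutes.loc[9, "timestamp"] += pd.Timedelta(days=1)
        with pytest.raises(ValidationError):
            wear_processing.detect_mvpa_minutes(minutes, CFG)

    def test_sub_minute_resolution_rejected(self):
        minutes = minutes_from_cadence([105, 105])
        minutes.loc[1, "timestamp"] += pd.Timedelta(seconds=30)
        with pytest.raises(ValidationError):
            wear_processing.detect_mvpa_minutes(minutes, CFG)

    def test_random_sequences_match_window_oracle(self):
        rng = np.random.default_rng(6)
        cadences = {0: 30, 1: 110, 2: 150}
        for _ in range(300):
            n = int(rng.integers(1, 121))
            classes = rng.integers(0, 3, size=n)
            cadence = np.array([cadences[c] for c in classes])
            got = wear_processing.mvpa_minutes_from_cadence(np.arange(n), cadence, CFG)
            assert got == mvpa_minutes_oracle(classes)

    @given(
        st.lists(st.sampled_from([0, 1, 2]), min_size=1, max_size=40),
        st.integers(min_value=2, max_value=12),
        st.integers(min_value=1, max_value=3),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_bout_parameters_match_oracle(self, classes, walk_bout, run_bout):
        cfg = WearConfig(mvpa_walk_bout_minutes=walk_bout, mvpa_run_bout_minutes=run_bout)
        cadence = np.array([0, 110, 150])[classes]
        got = wear_processing.mvpa_minutes_from_cadence(
            np.arange(len(classes)), cadence, cfg
        )
        assert got == mvpa_minutes_oracle(classes, walk_bout, run_bout)


class TestSummarizeDays:
    @pytest.mark.parametrize(
        "wear_minutes,steps,expected_valid",
        [(480, 600, True), (720, 499, False), (465, 10000, False), (480, 500, True)],
    )
    def test_valid_day_thresholds(self, wear_minutes, steps, expected_valid):
        # worn epochs only inside the window, one active epoch carrying all steps
        n_worn = wear_minutes // 15
        pattern = np.zeros(96, int)
        pattern[36 : 36 + n_worn] = 1
        step_col = np.zeros(96, int)
        step_col[36] = steps
        epochs = make_epoch_day(pattern, steps=step_col)
        wear = wear_processing.detect_nonwear(epochs, CFG)
        days = wear_processing.summarize_days(epochs, wear, pd.DataFrame(), CFG)
        assert len(days) == 1
        row = days.iloc[0]
        assert row["wear_minutes_window"] == wear_minutes
        assert row["total_steps"] == steps
        assert bool(row["is_valid"]) is expected_valid

    def test_weekend_flag(self):
        days = []
        for date in ("2020-02-21", "2020-02-22", "2020-02-23", "2020-02-24"):
            epochs = make_epoch_day([1] * 96, day=date)
            wear = wear_processing.detect_nonwear(epochs, CFG)
            days.append(wear_processing.summarize_days(epochs, wear, pd.DataFrame(), CFG))
        flags = pd.concat(days)["is_weekend"].tolist()
        assert flags == [False, True, True, False]  # Fri, Sat, Sun, Mon

    def test_days_without_observed_epochs_omitted(self):
        # 3 days of grid, data only on first and last
        start = pd.Timestamp("2020-02-17 09:00")
        ts = [start, start + pd.Timedelta(days=2)]
        minutes = pd.DataFrame(
            {
                "participant_id": "P1",
                "timestamp": ts,
                "steps": [10, 10],
                "motion_intensity": [1, 1],
            }
        )
        epochs = device_io.aggregate_to_epochs(minutes)
        wear = wear_processing.detect_nonwear(epochs, CFG)
        days = wear_processing.summarize_days(epochs, wear, minutes, CFG)
        assert days["date"].dt.day.tolist() == [17, 19]

    def test_steps_conservation_under_mask(self):
        rng = np.random.default_rng(8)
        pattern = rng.integers(0, 2, size=96)
        steps = np.where(pattern > 0, rng.integers(0, 300, size=96), 0)
        epochs = make_epoch_day(pattern, steps=steps)
        wear = wear_processing.detect_nonwear(epochs, CFG)
        days = wear_processing.summarize_days(epochs, wear, pd.DataFrame(), CFG)
        assert days["total_steps"].iloc[0] <= epochs["steps"].sum()
        all_wear = np.ones(len(epochs), bool)
        days_all = wear_processing.summarize_days(epochs, all_wear, pd.DataFrame(), CFG)
        assert days_all["total_steps"].iloc[0] == epochs["steps"].sum()

    def test_validity_monotone_in_wear_and_steps(self):
        base = dict(wear=480, steps=500)
        records = []
        for wear_minutes in (465, 480, 720):
            for steps in (499, 500, 10000):
                n_worn = wear_minutes // 15
                pattern = np.zeros(96, int)
                pattern[36 : 36 + n_worn] = 1
                step_col = np.zeros(96, int)
                step_col[36] = steps
                epochs = make_epoch_day(pattern, steps=step_col)
                wear = wear_processing.detect_nonwear(epochs, CFG)
                day = wear_processing.summarize_days(epochs, wear, pd.DataFrame(), CFG).iloc[0]
                records.append((wear_minutes, steps, bool(day["is_valid"])))
        for w1, s1, v1 in records:
            for w2, s2, v2 in records:
                if w2 >= w1 and s2 >= s1:
                    assert v2 >= v1
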