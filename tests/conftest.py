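import datetime as dt

import numpy as np
import pandas as pd
import pytest

from wearweek import device_io, synthetic_data, wear_processing
from wearweek import weekly_aggregation as wk


@pytest.fixture(scope="session")
def design():
    return wk.StudyDesign(study_start_date=dt.date(2020, 2, 17), n_weeks=8, closure_week=5)


@pytest.fixture(scope="session")
def small_config():
    """A compact cohort: quick to generate, still exercises every stage."""
    return synthetic_data.SyntheticConfig(n_participants=5, n_weeks=4, closure_week=3)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return synthetic_data.generate_cohort(small_config, seed=7)


def run_day_pipeline(minutes: pd.DataFrame, config=None) -> pd.DataFrame:
    """minutes -> epochs -> nonwear -> day summaries (no week assignment)."""
    config = config or wear_processing.WearConfig()
    epochs = device_io.aggregate_to_epochs(minutes)
    wear = wear_processing.detect_nonwear(epochs, config)
    return wear_processing.summarize_days(epochs, wear, minutes, config)


def make_epoch_day(intensities, steps=None, pid="P1", day="2020-02-17"):
    """One participant-day of epoch records from an intensity sequence."""
    intensities = np.asarray(intensities)
    if steps is None:
        steps = np.where(intensities > 0, 10, 0)
    start = pd.Timestamp(day)
    return pd.DataFrame(
        {
            "participant_id": pid,
            "epoch_start": start + pd.to_timedelta(np.arange(len(intensities)) * 15, unit="m"),
            "steps": np.asarray(steps, dtype=np.int64),
            "max_motion_intensity": intensities.astype(np.int64),
            "n_minutes_observed": np.where(intensities > 0, 15, 0).astype(np.int64),
        }
    )


def make_day_row(
    pid="P1",
    date="2020-02-17",
    wear=720,
    steps=8000,
    mvpa=10,
    valid=None,
):
    date = pd.Timestamp(date)
    is_weekend = date.dayofweek >= 5
    if valid is None:
        valid = wear >= 480 and steps >= 500
    return {
        "participant_id": pid,
        "date": date,
        "wear_minutes_window": wear,
        "total_steps": steps,
        "mvpa_minutes": mvpa,
        "is_weekend": is_weekend,
        "is_valid": valid,
    }
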