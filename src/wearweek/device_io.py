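"""I/O and epoch aggregation for minute-level wearable exports.

Collections are plain :class:`pandas.DataFrame` objects with fixed column
schemas (the module-level ``*_COLUMNS`` constants). Three tabular artifacts
move through the pipeline:

minute samples
    One row per observed minute per participant: ``participant_id``,
    ``timestamp`` (timezone-naive local time at minute resolution), ``steps``
    (steps accumulated in that minute) and ``motion_intensity`` (the device's
    opaque non-negative motion measure; only zero vs nonzero matters
    downstream). Minutes in which the device recorded nothing are absent from
    the file — gaps are preserved, never imputed.

epoch records
    Minute samples aggregated onto a fixed 15-minute clock grid anchored at
    midnight (epoch starts at :00/:15/:30/:45): steps are summed, motion
    intensity is maxed, and ``n_minutes_observed`` counts the minutes that
    actually appeared in the export. Grid cells inside the observation span
    with no data are emitted with zeros so that downstream run-length rules
    see an unbroken sequence.

day / week summaries and demographics
    Flat CSV round-trip formats defined by ``DAY_COLUMNS``, ``WEEK_COLUMNS``
    and ``DEMOGRAPHICS_COLUMNS``.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

EPOCH_MINUTES = 15
EPOCH_FREQ = "15min"

MINUTE_COLUMNS = ["participant_id", "timestamp", "steps", "motion_intensity"]
EPOCH_COLUMNS = [
    "participant_id",
    "epoch_start",
    "steps",
    "max_motion_intensity",
    "n_minutes_observed",
]
DAY_COLUMNS = [
    "participant_id",
    "date",
    "wear_minutes_window",
    "total_steps",
    "mvpa_minutes",
    "is_weekend",
    "is_valid",
]
WEEK_COLUMNS = [
    "participant_id",
    "study_week",
    "period",
    "steps_per_day",
    "mvpa_min_per_day",
    "mvpa_min_per_week",
    "n_valid_weekdays",
    "n_valid_weekend_days",
    "is_valid_week",
]
DEMOGRAPHICS_COLUMNS = [
    "participant_id",
    "group",
    "race_ethnicity",
    "gender",
    "income_bracket",
]

GROUP_CATEGORIES = ["included", "excluded"]
RACE_CATEGORIES = ["Black", "Hispanic/Latinx", "White", "Other/no response"]
GENDER_CATEGORIES = ["Male", "Female", "Other/no response"]
INCOME_CATEGORIES = ["<=1000", "1000-2000", "2000-3000", "3000-4000", ">=4000"]


def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")


def read_minute_csv(path, participant_id: str) -> pd.DataFrame:
    """Read one participant's minute-level export.

    Parameters
    ----------
    path
        CSV with columns ``timestamp,steps,motion_intensity``.
    participant_id
        Identifier attached to every returned row (the files themselves are
        per-participant and carry no id column).

    Returns
    -------
    DataFrame with ``MINUTE_COLUMNS``, sorted by timestamp.

    Raises
    ------
    FormatError
        If a required column is absent.
    ValidationError
        On duplicate or non-increasing timestamps, negative values, or a
        minute with positive steps but zero motion intensity.
    """
    df = pd.read_csv(path)
    _require_columns(df, ["timestamp", "steps", "motion_intensity"], path)
    ts = pd.to_datetime(df["timestamp"], format="ISO8601")
    steps = df["steps"].to_numpy()
    intensity = df["motion_intensity"].to_numpy()

    diffs = ts.diff()
    bad = np.flatnonzero(diffs.iloc[1:].le(pd.Timedelta(0)).to_numpy())
    if bad.size:
        row = int(bad[0]) + 1
        raise ValidationError(
            f"{path}: timestamps must be strictly increasing; "
            f"row {row} ({ts.iloc[row]}) does not advance past row {row - 1}"
        )
    if (steps < 0).any():
        row = int(np.flatnonzero(steps < 0)[0])
        raise ValidationError(f"{path}: negative steps at row {row}")
    if (intensity < 0).any():
        row = int(np.flatnonzero(intensity < 0)[0])
        raise ValidationError(f"{path}: negative motion_intensity at row {row}")
    offending = (steps > 0) & (intensity == 0)
    if offending.any():
        row = int(np.flatnonzero(offending)[0])
        raise ValidationError(
            f"{path}: row {row} has steps > 0 but motion_intensity == 0"
        )

    out = pd.DataFrame(
        {
            "participant_id": participant_id,
            "timestamp": ts,
            "steps": steps.astype(np.int64),
            "motion_intensity": intensity.astype(np.int64),
        }
    )
    return out.reset_index(drop=True)


def write_minute_csv(minutes: pd.DataFrame, path) -> None:
    """Write one participant's minute samples in the documented dialect."""
    out = minutes[["timestamp", "steps", "motion_intensity"]].copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def _floor_epoch(ts: pd.Series) -> pd.Series:
    return ts.dt.floor(EPOCH_FREQ)


def aggregate_to_epochs(minutes: pd.DataFrame) -> pd.DataFrame:
    """Aggregate minute samples onto the 15-minute clock grid.

    For every participant, one row is produced for every grid cell between
    the first and last observed minute (inclusive); cells with no samples get
    ``steps = 0``, ``max_motion_intensity = 0``, ``n_minutes_observed = 0``.
    Steps are conserved: the epoch step total over any span equals the minute
    step total.
    """
    if minutes.empty:
        return pd.DataFrame(
            {
                "participant_id": pd.Series([], dtype=object),
                "epoch_start": pd.Series([], dtype="datetime64[ns]"),
                "steps": pd.Series([], dtype=np.int64),
                "max_motion_intensity": pd.Series([], dtype=np.int64),
                "n_minutes_observed": pd.Series([], dtype=np.int64),
            }
        )

    pieces = []
    for pid, grp in minutes.groupby("participant_id", sort=False):
        floors = _floor_epoch(grp["timestamp"])
        agg = grp.groupby(floors).agg(
            steps=("steps", "sum"),
            max_motion_intensity=("motion_intensity", "max"),
            n_minutes_observed=("steps", "size"),
        )
        grid = pd.date_range(floors.iloc[0], floors.iloc[-1], freq=EPOCH_FREQ)
        agg = agg.reindex(grid, fill_value=0)
        agg.index.name = "epoch_start"
        agg = agg.reset_index()
        agg.insert(0, "participant_id", pid)
        pieces.append(agg)
    out = pd.concat(pieces, ignore_index=True)
    for col in ("steps", "max_motion_intensity", "n_minutes_observed"):
        out[col] = out[col].astype(np.int64)
    return out


def write_day_summaries(days: pd.DataFrame, path) -> None:
    out = days.reindex(columns=DAY_COLUMNS).copy()
    if not out.empty:
        out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_day_summaries(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, DAY_COLUMNS, path)
    df["date"] = pd.to_datetime(df["date"])
    for col in ("wear_minutes_window", "total_steps", "mvpa_minutes"):
        df[col] = df[col].astype(np.int64)
    for col in ("is_weekend", "is_valid"):
        df[col] = df[col].astype(bool)
    return df[DAY_COLUMNS]


def write_week_summaries(weeks: pd.DataFrame, path) -> None:
    weeks.reindex(columns=WEEK_COLUMNS).to_csv(path, index=False)


def read_week_summaries(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, WEEK_COLUMNS, path)
    df["study_week"] = df["study_week"].astype(np.int64)
    for col in ("n_valid_weekdays", "n_valid_weekend_days"):
        df[col] = df[col].astype(np.int64)
    df["is_valid_week"] = df["is_valid_week"].astype(bool)
    return df[WEEK_COLUMNS]


def write_demographics(demographics: pd.DataFrame, path) -> None:
    demographics.reindex(columns=DEMOGRAPHICS_COLUMNS).to_csv(path, index=False)


def read_demographics(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, DEMOGRAPHICS_COLUMNS, path)
    if df["participant_id"].duplicated().any():
        dup = df["participant_id"][df["participant_id"].duplicated()].iloc[0]
        raise ValidationError(f"{path}: duplicate participant_id {dup!r}")
    closed = {
        "group": GROUP_CATEGORIES,
        "race_ethnicity": RACE_CATEGORIES,
        "gender": GENDER_CATEGORIES,
        "income_bracket": INCOME_CATEGORIES,
    }
    for col, categories in closed.items():
        unknown = set(df[col].dropna()) - set(categories)
        if unknown:
            raise ValidationError(
                f"{path}: column {col!r} has values outside the closed set: "
                f"{sorted(unknown)}"
            )
    return df[DEMOGRAPHICS_COLUMNS]


def minute_files_in(directory) -> dict[str, str]:
    """Map participant id -> minute CSV path for ``<participant_id>.csv`` files."""
    reserved = {"demographics.csv", "day_summaries.csv", "week_summaries.csv"}
    out = {}
    for name in sorted(os.listdir(directory)):
        if name.endswith(".csv") and name not in reserved:
            out[name[:-4]] = os.path.join(directory, name)
    return out
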