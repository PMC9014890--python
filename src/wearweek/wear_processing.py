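"""Nonwear detection, valid-day classification and bout-based MVPA minutes.

The rules implemented here are the standard consumer-accelerometer processing
conventions for step-counting wristbands without a heart-rate channel:

* **Nonwear**: within each calendar day, any maximal run of at least
  ``nonwear_min_run_epochs`` consecutive 15-minute epochs whose maximum
  motion intensity is zero is flagged as device-off time. Shorter zero runs
  (a still child, a nap on the couch) remain wear.
* **Valid day**: at least ``valid_day_min_wear_minutes`` minutes of wear
  between 9 AM and 9 PM *and* at least ``valid_day_min_steps`` steps over the
  worn part of the day. Both clauses must hold.
* **MVPA minutes**: a cadence-based reading of the device's activity
  detector. A minute is a *run* minute at cadence ≥ ``mvpa_run_cadence``
  steps/min and a *walk* minute at cadence in
  [``mvpa_walk_cadence``, ``mvpa_run_cadence``). Run minutes count whenever
  they sit in a consecutive block of at least ``mvpa_run_bout_minutes`` run
  minutes (default 1, i.e. always); walk minutes count only when they sit
  inside a maximal consecutive stretch of at least ``mvpa_walk_bout_minutes``
  non-idle (walk-or-run) minutes. A gap in the minute record breaks a bout.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "WearConfig",
    "detect_nonwear",
    "wear_minutes_in_window",
    "detect_mvpa_minutes",
    "mvpa_minutes_from_cadence",
    "summarize_days",
]

#: class codes used by the MVPA minute classifier
IDLE, WALK, RUN = 0, 1, 2


@dataclass(frozen=True)
class WearConfig:
    """Tunable thresholds of the wear-processing rules (see module docstring)."""

    nonwear_min_run_epochs: int = 3
    valid_day_min_wear_minutes: int = 480
    valid_day_min_steps: int = 500
    window_start: dt.time = dt.time(9, 0)
    window_end: dt.time = dt.time(21, 0)
    mvpa_walk_cadence: int = 100
    mvpa_run_cadence: int = 130
    mvpa_walk_bout_minutes: int = 10
    mvpa_run_bout_minutes: int = 1

    def __post_init__(self):
        if self.nonwear_min_run_epochs < 1:
            raise ValidationError("nonwear_min_run_epochs must be >= 1")
        if not (0 < self.mvpa_walk_cadence < self.mvpa_run_cadence):
            raise ValidationError("need 0 < walk cadence < run cadence")
        if self.mvpa_walk_bout_minutes < 1 or self.mvpa_run_bout_minutes < 1:
            raise ValidationError("bout lengths must be >= 1 minute")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "WearConfig":
        """Build from a flat config mapping with dotted keys.

        Recognised keys: ``nonwear.min_run_epochs``, ``valid_day.min_wear_minutes``,
        ``valid_day.min_steps``, ``window.start``, ``window.end``,
        ``mvpa.walk_cadence``, ``mvpa.run_cadence``, ``mvpa.walk_bout_minutes``,
        ``mvpa.run_bout_minutes``.
        """
        alias = {
            "nonwear.min_run_epochs": "nonwear_min_run_epochs",
            "valid_day.min_wear_minutes": "valid_day_min_wear_minutes",
            "valid_day.min_steps": "valid_day_min_steps",
            "window.start": "window_start",
            "window.end": "window_end",
            "mvpa.walk_cadence": "mvpa_walk_cadence",
            "mvpa.run_cadence": "mvpa_run_cadence",
            "mvpa.walk_bout_minutes": "mvpa_walk_bout_minutes",
            "mvpa.run_bout_minutes": "mvpa_run_bout_minutes",
        }
        kwargs = {}
        fields = {f.name for f in dataclasses.fields(cls)}
        for key, value in mapping.items():
            name = alias.get(key, key)
            if name not in fields:
                raise ValidationError(f"unknown wear-processing config key {key!r}")
            if name in ("window_start", "window_end") and isinstance(value, str):
                value = dt.time.fromisoformat(value)
            kwargs[name] = value
        return cls(**kwargs)


def _check_epoch_order(epochs: pd.DataFrame) -> None:
    for pid, grp in epochs.groupby("participant_id", sort=False):
        deltas = grp["epoch_start"].diff().iloc[1:]
        if deltas.empty:
            continue
        if not (deltas == pd.Timedelta(minutes=15)).all():
            raise ValidationError(
                f"participant {pid}: epochs must be ordered and gap-free on the "
                "15-minute grid (emit empty epochs with n_minutes_observed=0)"
            )


def detect_nonwear(
    epochs: pd.DataFrame, config: WearConfig | None = None
) -> np.ndarray:
    """Return a boolean wear mask aligned to ``epochs`` (True = worn).

    An epoch is nonwear iff it belongs to a maximal run of at least
    ``config.nonwear_min_run_epochs`` consecutive epochs with zero maximum
    motion intensity; runs are evaluated within each calendar day (a zero run
    spanning midnight is split at midnight before the length test).
    """
    config = config or WearConfig()
    if epochs.empty:
        return np.zeros(0, dtype=bool)
    _check_epoch_order(epochs)

    zero = epochs["max_motion_intensity"].to_numpy() == 0
    day = epochs["epoch_start"].dt.normalize()
    pid = epochs["participant_id"]
    boundary = (
        (pid != pid.shift())
        | (day != day.shift())
        | (pd.Series(zero, index=epochs.index) != pd.Series(zero, index=epochs.index).shift())
    )
    run_id = boundary.cumsum()
    run_len = run_id.map(run_id.value_counts()).to_numpy()
    nonwear = zero & (run_len >= config.nonwear_min_run_epochs)
    return ~nonwear


def wear_minutes_in_window(
    epochs: pd.DataFrame,
    wear_mask: np.ndarray,
    date: dt.date,
    config: WearConfig | None = None,
) -> int:
    """Minutes of wear on ``date`` whose epoch start lies in the daytime window.

    With the default 09:00–21:00 half-open window this is 15 × (number of
    worn epochs among the 48 window epochs), i.e. an integer in [0, 720].
    """
    config = config or WearConfig()
    if len(wear_mask) != len(epochs):
        raise ValidationError("wear mask is not aligned to the epoch sequence")
    starts = epochs["epoch_start"]
    on_date = starts.dt.date.to_numpy() == date
    t = _minutes_of_day(starts)
    in_window = (t >= _as_minutes(config.window_start)) & (
        t < _as_minutes(config.window_end)
    )
    return int(np.sum(on_date & in_window & np.asarray(wear_mask))) * 15


def _minutes_of_day(ts: pd.Series) -> np.ndarray:
    return (ts.dt.hour * 60 + ts.dt.minute).to_numpy()


def _as_minutes(t: dt.time) -> int:
    return t.hour * 60 + t.minute


def classify_cadence(cadence: np.ndarray, config: WearConfig) -> np.ndarray:
    """Map steps/min to IDLE/WALK/RUN class codes."""
    cls = np.zeros(len(cadence), dtype=np.int8)
    cls[cadence >= config.mvpa_walk_cadence] = WALK
    cls[cadence >= config.mvpa_run_cadence] = RUN
    return cls


def mvpa_minutes_from_cadence(
    minute_index: np.ndarray,
    cadence: np.ndarray,
    config: WearConfig | None = None,
) -> int:
    """Count MVPA minutes from per-minute cadences within one day.

    ``minute_index`` gives each observation's minute-of-day (used to detect
    gaps: non-consecutive minutes break a bout). Vectorised run-length
    implementation.
    """
    config = config or WearConfig()
    cls = classify_cadence(np.asarray(cadence), config)
    idx = np.asarray(minute_index)
    keep = cls != IDLE
    if not keep.any():
        return 0
    idx = idx[keep]
    cls = cls[keep]
    n = len(idx)

    new_seg = np.ones(n, dtype=bool)
    new_seg[1:] = np.diff(idx) != 1
    seg_id = np.cumsum(new_seg) - 1
    seg_len = np.bincount(seg_id)
    walk_count = int(np.sum((cls == WALK) & (seg_len[seg_id] >= config.mvpa_walk_bout_minutes)))

    isrun = cls == RUN
    prev_run = np.zeros(n, dtype=bool)
    prev_run[1:] = isrun[:-1]
    run_start = isrun & (new_seg | ~prev_run)
    if isrun.any():
        run_id = np.cumsum(run_start) - 1
        run_len = np.bincount(run_id[isrun], minlength=run_start.sum())
        run_count = int(np.sum(run_len[run_id[isrun]] >= config.mvpa_run_bout_minutes))
    else:
        run_count = 0
    return walk_count + run_count


def detect_mvpa_minutes(
    minutes: pd.DataFrame, config: WearConfig | None = None
) -> int:
    """MVPA minutes for one participant-day of minute samples.

    Cadence is the per-minute step count. Raises :class:`ValidationError` if
    the input spans more than one calendar day or is not at minute
    resolution.
    """
    config = config or WearConfig()
    if minutes.empty:
        return 0
    ts = minutes["timestamp"]
    if ts.dt.normalize().nunique() > 1:
        raise ValidationError("detect_mvpa_minutes expects a single calendar day")
    if (ts.dt.second != 0).any() or ts.duplicated().any():
        raise ValidationError("input must be unique minute-resolution timestamps")
    return mvpa_minutes_from_cadence(
        _minutes_of_day(ts), minutes["steps"].to_numpy(), config
    )


def summarize_days(
    epochs: pd.DataFrame,
    wear_mask: np.ndarray,
    minutes: pd.DataFrame,
    config: WearConfig | None = None,
) -> pd.DataFrame:
    """Produce one DaySummary row per participant-day with any observed epoch.

    ``total_steps`` sums steps over *worn* epochs only; ``mvpa_minutes`` comes
    from the day's minute samples; validity follows the two-clause rule
    (wear minutes in window and total steps). Days with no observed epoch are
    omitted (no data synced, rather than worn-but-inactive).
    """
    config = config or WearConfig()
    if len(wear_mask) != len(epochs):
        raise ValidationError("wear mask is not aligned to the epoch sequence")
    if epochs.empty:
        return pd.DataFrame(columns=[
            "participant_id", "date", "wear_minutes_window", "total_steps",
            "mvpa_minutes", "is_weekend", "is_valid",
        ])

    df = epochs[["participant_id", "epoch_start", "steps", "n_minutes_observed"]].copy()
    df["wear"] = np.asarray(wear_mask, dtype=bool)
    df["date"] = df["epoch_start"].dt.normalize()
    t = _minutes_of_day(df["epoch_start"])
    df["in_window"] = (t >= _as_minutes(config.window_start)) & (
        t < _as_minutes(config.window_end)
    )

    df["worn_window_epoch"] = df["wear"] & df["in_window"]
    df["worn_steps"] = df["steps"].where(df["wear"], 0)
    summary = (
        df.groupby(["participant_id", "date"], sort=True)
        .agg(
            worn_window_epochs=("worn_window_epoch", "sum"),
            total_steps=("worn_steps", "sum"),
            observed=("n_minutes_observed", "sum"),
        )
        .reset_index()
    )
    summary["wear_minutes_window"] = 15 * summary.pop("worn_window_epochs")
    summary = summary[summary["observed"] > 0].drop(columns="observed")

    # MVPA from the raw minute record of each day
    mvpa = {}
    if not minutes.empty:
        mdf = minutes.copy()
        mdf["date"] = mdf["timestamp"].dt.normalize()
        for key, g in mdf.groupby(["participant_id", "date"], sort=False):
            mvpa[key] = mvpa_minutes_from_cadence(
                _minutes_of_day(g["timestamp"]), g["steps"].to_numpy(), config
            )
    summary["mvpa_minutes"] = [
        mvpa.get((pid, date), 0)
        for pid, date in zip(summary["participant_id"], summary["date"])
    ]
    summary["is_weekend"] = summary["date"].dt.dayofweek >= 5
    summary["is_valid"] = (
        summary["wear_minutes_window"] >= config.valid_day_min_wear_minutes
    ) & (summary["total_steps"] >= config.valid_day_min_steps)
    for col in ("wear_minutes_window", "total_steps", "mvpa_minutes"):
        summary[col] = summary[col].astype(np.int64)
    return summary[
        [
            "participant_id",
            "date",
            "wear_minutes_window",
            "total_steps",
            "mvpa_minutes",
            "is_weekend",
            "is_valid",
        ]
    ].reset_index(drop=True)
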