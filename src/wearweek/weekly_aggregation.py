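"""Study-week assignment, weighted weekly values, and inclusion filtering.

A study is a sequence of consecutive 7-day blocks anchored at a Monday start
date; an interruption (here, a school closure) splits the blocks into a *pre*
and a *post* period. Daily summaries are rolled up to weekly values with the
standard weekday/weekend weighting

    (mean over valid weekdays x 5 + mean over valid weekend days x 2) / 7,

falling back to the plain mean over all valid days when a week lacks either a
valid weekday or a valid weekend day. A week is *valid* when it contains at
least one valid day; a participant enters the analysis only with at least one
valid week in each period.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .exceptions import InsufficientDataError, ValidationError

PRE, POST = "pre", "post"


@dataclass(frozen=True)
class StudyDesign:
    """Calendar anchors of the natural experiment.

    Parameters
    ----------
    study_start_date
        First day of study week 1; must be a Monday so weekday/weekend day
        counts within a study week are exactly 5 and 2.
    n_weeks
        Total number of consecutive study weeks.
    closure_week
        First study week of the *post* period (1-based). Weeks
        ``1..closure_week-1`` are *pre*, ``closure_week..n_weeks`` are *post*.
    """

    study_start_date: dt.date = dt.date(2020, 2, 17)
    n_weeks: int = 8
    closure_week: int = 5

    def __post_init__(self):
        if isinstance(self.study_start_date, str):
            object.__setattr__(
                self, "study_start_date", dt.date.fromisoformat(self.study_start_date)
            )
        if self.study_start_date.weekday() != 0:
            raise ValidationError(
                f"study_start_date {self.study_start_date} is not a Monday"
            )
        if not (1 < self.closure_week <= self.n_weeks):
            raise ValidationError(
                "closure_week must lie in (1, n_weeks] so both periods are non-empty"
            )

    @property
    def pre_weeks(self) -> range:
        return range(1, self.closure_week)

    @property
    def post_weeks(self) -> range:
        return range(self.closure_week, self.n_weeks + 1)

    @property
    def study_end_date(self) -> dt.date:
        """First date after the study span (exclusive)."""
        return self.study_start_date + dt.timedelta(days=7 * self.n_weeks)

    def period_of(self, study_week: int) -> str:
        return PRE if study_week < self.closure_week else POST

    def week_of(self, date: dt.date) -> int:
        if not (self.study_start_date <= date < self.study_end_date):
            raise ValidationError(f"date {date} lies outside the study span")
        return 1 + (date - self.study_start_date).days // 7

    @classmethod
    def from_dict(cls, d: dict) -> "StudyDesign":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "StudyDesign":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "study_start_date": self.study_start_date.isoformat(),
                    "n_weeks": self.n_weeks,
                    "closure_week": self.closure_week,
                },
                fh,
            )


def assign_study_weeks(days: pd.DataFrame, design: StudyDesign) -> pd.DataFrame:
    """Annotate DaySummary rows with ``study_week`` and ``period``.

    Raises :class:`ValidationError` naming the first date outside the study
    span.
    """
    out = days.copy()
    dates = pd.to_datetime(out["date"])
    start = pd.Timestamp(design.study_start_date)
    end = pd.Timestamp(design.study_end_date)
    outside = (dates < start) | (dates >= end)
    if outside.any():
        bad = dates[outside].iloc[0].date()
        raise ValidationError(f"date {bad} lies outside the study span")
    out["study_week"] = ((dates - start).dt.days // 7 + 1).astype(np.int64)
    out["period"] = np.where(out["study_week"] < design.closure_week, PRE, POST)
    return out


_OUTCOME_COLUMNS = {"steps": "total_steps", "mvpa": "mvpa_minutes"}


def weighted_weekly_value(week_days: pd.DataFrame, outcome: str) -> float:
    """Weighted weekly daily value over one participant-week of *valid* days.

    ``outcome`` is ``"steps"`` (total_steps) or ``"mvpa"`` (mvpa_minutes).
    With at least one valid weekday and one valid weekend day the value is
    (weekday mean x 5 + weekend mean x 2) / 7; otherwise the unweighted mean
    of all valid days.
    """
    col = _OUTCOME_COLUMNS[outcome]
    valid = week_days[week_days["is_valid"]]
    if valid.empty:
        raise InsufficientDataError(
            "weighted weekly value requires at least one valid day; apply the "
            "valid-week rule first"
        )
    weekday = valid.loc[~valid["is_weekend"], col]
    weekend = valid.loc[valid["is_weekend"], col]
    if len(weekday) and len(weekend):
        return float((weekday.mean() * 5 + weekend.mean() * 2) / 7)
    return float(valid[col].mean())


def summarize_weeks(days: pd.DataFrame, design: StudyDesign) -> pd.DataFrame:
    """Roll day summaries up to one WeekSummary row per observed participant-week.

    Weighted outcome values are present only for valid weeks (NaN otherwise);
    ``mvpa_min_per_week`` is exactly 7 x the weighted daily MVPA value.
    """
    if "study_week" not in days.columns:
        days = assign_study_weeks(days, design)
    rows = []
    for (pid, week), g in days.groupby(["participant_id", "study_week"], sort=True):
        valid = g[g["is_valid"]]
        n_wd = int((valid["is_weekend"] == False).sum())  # noqa: E712
        n_we = int((valid["is_weekend"] == True).sum())  # noqa: E712
        is_valid_week = (n_wd + n_we) >= 1
        if is_valid_week:
            steps_per_day = weighted_weekly_value(g, "steps")
            mvpa_per_day = weighted_weekly_value(g, "mvpa")
            mvpa_per_week = 7.0 * mvpa_per_day
        else:
            steps_per_day = mvpa_per_day = mvpa_per_week = np.nan
        rows.append(
            {
                "participant_id": pid,
                "study_week": int(week),
                "period": design.period_of(int(week)),
                "steps_per_day": steps_per_day,
                "mvpa_min_per_day": mvpa_per_day,
                "mvpa_min_per_week": mvpa_per_week,
                "n_valid_weekdays": n_wd,
                "n_valid_weekend_days": n_we,
                "is_valid_week": is_valid_week,
            }
        )
    columns = [
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
    return pd.DataFrame(rows, columns=columns)


def filter_participants(weeks: pd.DataFrame, design: StudyDesign) -> set:
    """Participants with >=1 valid pre week AND >=1 valid post week."""
    valid = weeks[weeks["is_valid_week"]]
    pre_ids = set(valid.loc[valid["period"] == PRE, "participant_id"])
    post_ids = set(valid.loc[valid["period"] == POST, "participant_id"])
    return pre_ids & post_ids
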