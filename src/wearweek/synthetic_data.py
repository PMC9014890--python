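"""Synthetic wearable cohorts with the structure of a school-closure study.

The generator emulates the raw data of a pre/post natural experiment on
youth physical activity: 17 middle-schoolers wearing a consumer step-counting
wristband over 8 study weeks, with an abrupt activity drop from study week 5
(the school closure), imperfect daily wear compliance (about 5.2 valid days
per valid week), and all-or-nothing post-closure sync dropout (some
participants simply stop uploading once devices are no longer synced at
school).

Two simulators are exposed:

* :func:`generate_cohort` builds minute-level device exports (the full
  pipeline input): per participant-day wear blocks with random off-gaps,
  walking/running bouts sized so that expected daily steps and MVPA minutes
  match the participant's true means, idle worn minutes with low nonzero
  motion intensity and zero steps, and nothing at all for non-worn minutes.
* :func:`generate_week_summaries` draws valid-week outcomes directly from the
  mixed-model generative structure (participant random effect x period mean,
  day-level noise averaged over the realized valid days). It is the fast
  route for model calibration and parameter-recovery simulation.

Ground truth (true per-participant means, wear schedule, dropout) is returned
alongside the data so recovery tests can compare against what was injected.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import math
import os
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from . import device_io
from .exceptions import ValidationError
from .weekly_aggregation import POST, PRE, StudyDesign

#: length of the walking stretch placed per day before topping up with runs
_WALK_BOUT_LEN = 10

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_cohort",
    "generate_week_summaries",
    "generate_demographics",
    "write_cohort",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of the emulated cohort.

    Defaults reproduce the headline magnitudes of the emulated study in
    expectation: ~8003 steps/day and ~11.45 MVPA min/day (80.18 min/week)
    pre-closure, post/pre ratios 0.546 (steps) and 0.575 (MVPA), a mean of
    about 5.2 valid days per valid week, and post-closure sync dropout.
    """

    n_participants: int = 17
    n_weeks: int = 8
    closure_week: int = 5
    study_start_date: dt.date = dt.date(2020, 2, 17)

    pre_steps_mean: float = 8003.0  # weighted steps/day, pre period
    post_pre_ratio: float = 0.546
    pre_mvpa_min_per_day: float = 11.45  # 80.18 min/week / 7
    mvpa_post_pre_ratio: float = 0.575

    between_participant_sd: float = 1200.0  # steps/day scale
    within_participant_day_sd: float = 1800.0  # steps/day scale
    mvpa_between_sd: float = 1.5  # MVPA min/day scale
    mvpa_within_sd: float = 3.5  # MVPA min/day scale

    wear_day_prob: float = 0.75  # P(device worn on a given day)
    wear_gap_prob: float = 0.5  # P(one off-body gap within a worn day)
    post_dropout_prob: float = 0.2  # P(participant stops syncing post-closure)
    weekend_step_ratio: float = 0.8  # weekend day mean / weekday day mean

    walk_cadence_range: tuple = (100, 129)  # steps/min, walk band
    run_cadence_range: tuple = (130, 180)  # steps/min, run band

    seed: int = 0

    def __post_init__(self):
        for name in ("wear_day_prob", "wear_gap_prob", "post_dropout_prob"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1], got {p}")
        for name in ("post_pre_ratio", "mvpa_post_pre_ratio"):
            r = getattr(self, name)
            if not (0.0 < r <= 1.0):
                raise ValidationError(f"{name} must be in (0, 1], got {r}")
        if self.walk_cadence_range[0] >= self.run_cadence_range[0]:
            raise ValidationError("walk cadence band must lie below the run band")
        if not (1 < self.closure_week <= self.n_weeks):
            raise ValidationError("closure_week must lie in (1, n_weeks]")

    @property
    def design(self) -> StudyDesign:
        return StudyDesign(
            study_start_date=self.study_start_date,
            n_weeks=self.n_weeks,
            closure_week=self.closure_week,
        )

    @classmethod
    def from_mapping(cls, mapping: dict) -> "SyntheticConfig":
        kwargs = dict(mapping)
        if "study_start_date" in kwargs and isinstance(kwargs["study_start_date"], str):
            kwargs["study_start_date"] = dt.date.fromisoformat(kwargs["study_start_date"])
        for key in ("walk_cadence_range", "run_cadence_range"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(kwargs) - fields
        if unknown:
            raise ValidationError(f"unknown synthetic config keys: {sorted(unknown)}")
        return cls(**kwargs)


@dataclass
class GroundTruth:
    """What the generator actually injected, for recovery tests."""

    participants: pd.DataFrame  # per-participant true means, dropout flag
    wear_schedule: dict = field(default_factory=dict)  # pid -> [ISO dates worn]

    def included_eligible(self) -> set:
        """Participants whose realized wear/dropout gives data in both periods."""
        out = set()
        for _, row in self.participants.iterrows():
            pid = row["participant_id"]
            sched = self.wear_schedule.get(pid, [])
            if sched and row["has_pre_data"] and row["has_post_data"]:
                out.add(pid)
        return out

    def to_json(self, path) -> None:
        payload = {
            # round-trip through pandas' JSON encoder to shed numpy scalar types
            "participants": json.loads(self.participants.to_json(orient="records")),
            "wear_schedule": self.wear_schedule,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _participant_ids(n: int) -> list:
    return [f"P{i:03d}" for i in range(1, n + 1)]


def _lognormal_multipliers(rng, n: int, cv: float) -> np.ndarray:
    """Unit-mean lognormal multipliers with coefficient of variation ~cv."""
    if cv <= 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-(sigma**2) / 2, sigma=sigma, size=n)


def _weekday_mean(overall_mean: float, weekend_ratio: float) -> float:
    # solve (5*w + 2*r*w)/7 = overall for the weekday mean w
    return overall_mean * 7.0 / (5.0 + 2.0 * weekend_ratio)


def _clipped_normal(rng, mean: float, sd: float, size=None) -> np.ndarray:
    """``max(0, Normal)`` day-value noise whose expectation equals ``mean``.

    Clipping at zero inflates the mean of a plain normal; the location is
    shifted down so that E[max(0, N(loc, sd))] = mean exactly, keeping the
    configured means true in expectation even when mean/sd is small.
    """
    if mean <= 0:
        return np.zeros(size if size is not None else ())
    loc = _clipped_normal_loc(float(mean), float(sd))
    return np.maximum(0.0, rng.normal(loc, sd, size))


@lru_cache(maxsize=4096)
def _clipped_normal_loc(mean: float, sd: float) -> float:
    """Location m solving E[max(0, N(m, sd))] = m*Phi(m/sd) + sd*phi(m/sd) = mean."""
    if mean / sd > 8:  # clipped mass negligible
        return mean
    inv_sqrt2 = 0.7071067811865476
    inv_sqrt2pi = 0.3989422804014327
    m = mean
    for _ in range(100):
        a = m / sd
        cdf = 0.5 * math.erfc(-a * inv_sqrt2)
        pdf = inv_sqrt2pi * math.exp(-0.5 * a * a)
        f = m * cdf + sd * pdf - mean
        if abs(f) < 1e-10 * max(1.0, mean):
            break
        m -= f / max(cdf, 1e-12)  # Newton: d/dm = Phi(m/sd)
    return m


def generate_demographics(
    n: int, rng: np.random.Generator, group: str = "included"
) -> pd.DataFrame:
    """Sample a demographics table from the study's included-group margins.

    Race/ethnicity, gender and the five monthly-income bands are drawn
    independently with probabilities proportional to the included-group
    counts (7/8/2/0, 7/10/0 and 4/4/5/2/2 out of 17).
    """
    race_w = np.array([7, 8, 2, 0], dtype=float)
    gender_w = np.array([7, 10, 0], dtype=float)
    income_w = np.array([4, 4, 5, 2, 2], dtype=float)
    return pd.DataFrame(
        {
            "participant_id": _participant_ids(n),
            "group": group,
            "race_ethnicity": rng.choice(
                device_io.RACE_CATEGORIES, size=n, p=race_w / race_w.sum()
            ),
            "gender": rng.choice(
                device_io.GENDER_CATEGORIES, size=n, p=gender_w / gender_w.sum()
            ),
            "income_bracket": rng.choice(
                device_io.INCOME_CATEGORIES, size=n, p=income_w / income_w.sum()
            ),
        }
    )


def _draw_truth(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_participants
    step_mult = _lognormal_multipliers(
        rng, n, config.between_participant_sd / config.pre_steps_mean
    )
    mvpa_mult = _lognormal_multipliers(
        rng, n, config.mvpa_between_sd / config.pre_mvpa_min_per_day
    )
    dropped = rng.random(n) < config.post_dropout_prob
    return pd.DataFrame(
        {
            "participant_id": _participant_ids(n),
            "pre_steps_mean": config.pre_steps_mean * step_mult,
            "post_steps_mean": config.pre_steps_mean * step_mult * config.post_pre_ratio,
            "pre_mvpa_mean": config.pre_mvpa_min_per_day * mvpa_mult,
            "post_mvpa_mean": config.pre_mvpa_min_per_day
            * mvpa_mult
            * config.mvpa_post_pre_ratio,
            "dropped_post": dropped,
        }
    )


def _day_minutes(
    rng: np.random.Generator,
    day: dt.date,
    target_steps: float,
    target_mvpa: int,
    config: SyntheticConfig,
) -> pd.DataFrame:
    """Minute samples for one worn day.

    Wear block roughly 07:30-21:45 with at most one random off-gap of
    45-75 minutes; MVPA placed as one contiguous walk bout (>=10 min) plus
    run minutes; the remaining step budget spread over other worn minutes at
    sub-walk cadence; idle worn minutes get motion intensity 1 and 0 steps.
    """
    start = 7 * 60 + int(rng.integers(0, 91))  # 07:00-08:30
    end = 21 * 60 + int(rng.integers(0, 91))  # 21:00-22:30
    worn = np.ones(24 * 60, dtype=bool)
    worn[:start] = False
    worn[end:] = False
    if rng.random() < config.wear_gap_prob:  # one off-body gap
        gap_len = int(rng.integers(45, 76))
        gap_start = int(rng.integers(start, max(start + 1, end - gap_len)))
        worn[gap_start : gap_start + gap_len] = False
    idx = np.flatnonzero(worn)

    steps = np.zeros(24 * 60, dtype=np.int64)
    # contiguous placement for the MVPA bout: use the longest worn segment
    mvpa_total = int(target_mvpa)
    bout_idx = np.array([], dtype=np.int64)
    if mvpa_total > 0:
        breaks = np.flatnonzero(np.diff(idx) != 1)
        segments = np.split(idx, breaks + 1)
        seg = max(segments, key=len)
        mvpa_total = min(mvpa_total, len(seg))
        offset = int(rng.integers(0, len(seg) - mvpa_total + 1))
        bout_idx = seg[offset : offset + mvpa_total]
        # one 10-min walking stretch when the budget allows it, run minutes
        # for the rest; short budgets become pure run minutes so every MVPA
        # minute still counts under the bout rules
        n_walk = _WALK_BOUT_LEN if mvpa_total >= _WALK_BOUT_LEN else 0
        walk_lo, walk_hi = config.walk_cadence_range
        run_lo, run_hi = config.run_cadence_range
        cadences = np.concatenate(
            [
                rng.integers(walk_lo, walk_hi + 1, size=n_walk),
                rng.integers(run_lo, run_hi + 1, size=mvpa_total - n_walk),
            ]
        )
        steps[bout_idx] = cadences

    remainder = int(round(target_steps)) - int(steps.sum())
    other = np.setdiff1d(idx, bout_idx)
    if remainder > 0 and len(other):
        alloc = rng.multinomial(remainder, np.full(len(other), 1.0 / len(other)))
        np.minimum(alloc, config.walk_cadence_range[0] - 1, out=alloc)
        steps[other] = alloc

    intensity = np.maximum(steps // 10, 1).astype(np.int64)  # worn => nonzero
    base = pd.Timestamp(day)
    return pd.DataFrame(
        {
            "timestamp": base + pd.to_timedelta(idx, unit="m"),
            "steps": steps[idx],
            "motion_intensity": intensity[idx],
        }
    )


def generate_cohort(
    config: SyntheticConfig | None = None, seed: int | None = None
) -> tuple[dict, pd.DataFrame, GroundTruth]:
    """Generate a full minute-level cohort.

    Returns ``(minutes_by_participant, demographics, ground_truth)`` where
    ``minutes_by_participant`` maps participant id to a minute-sample
    DataFrame (``device_io.MINUTE_COLUMNS``). Fully reproducible: one global
    seed spawns a per-participant seed sequence, so any participant can be
    regenerated independently.
    """
    config = config or SyntheticConfig()
    seed = config.seed if seed is None else seed
    root = np.random.SeedSequence(seed)
    truth_rng = np.random.default_rng(root.spawn(1)[0])
    truth = _draw_truth(config, truth_rng)
    demographics = generate_demographics(
        config.n_participants, np.random.default_rng(root.spawn(1)[0])
    )

    design = config.design
    n_days = 7 * config.n_weeks
    closure_start = design.study_start_date + dt.timedelta(
        days=7 * (config.closure_week - 1)
    )
    # weekday mean as a multiple of the overall (5/2-weighted) mean
    wd_scale = _weekday_mean(1.0, config.weekend_step_ratio)

    minutes_by_pid: dict = {}
    schedule: dict = {}
    participant_seeds = root.spawn(config.n_participants)
    for row, pseed in zip(truth.itertuples(index=False), participant_seeds):
        rng = np.random.default_rng(pseed)
        frames = []
        worn_dates = []
        for d in range(n_days):
            day = design.study_start_date + dt.timedelta(days=d)
            post = day >= closure_start
            if post and row.dropped_post:
                continue
            if rng.random() >= config.wear_day_prob:
                continue
            steps_mean = row.post_steps_mean if post else row.pre_steps_mean
            mvpa_mean = row.post_mvpa_mean if post else row.pre_mvpa_mean
            ratio = config.weekend_step_ratio if day.weekday() >= 5 else 1.0
            day_steps_mean = steps_mean * wd_scale * ratio
            day_mvpa_mean = mvpa_mean * wd_scale * ratio
            target_steps = float(
                _clipped_normal(rng, day_steps_mean, config.within_participant_day_sd)
            )
            target_mvpa = int(
                round(float(_clipped_normal(rng, day_mvpa_mean, config.mvpa_within_sd)))
            )
            frames.append(
                _day_minutes(rng, day, target_steps, target_mvpa, config)
            )
            worn_dates.append(day.isoformat())
        if frames:
            df = pd.concat(frames, ignore_index=True)
        else:
            df = pd.DataFrame(
                {
                    "timestamp": pd.Series([], dtype="datetime64[ns]"),
                    "steps": pd.Series([], dtype=np.int64),
                    "motion_intensity": pd.Series([], dtype=np.int64),
                }
            )
        df.insert(0, "participant_id", row.participant_id)
        minutes_by_pid[row.participant_id] = df
        schedule[row.participant_id] = worn_dates

    truth = truth.copy()
    pre_dates = {
        pid: [d for d in ds if dt.date.fromisoformat(d) < closure_start]
        for pid, ds in schedule.items()
    }
    post_dates = {
        pid: [d for d in ds if dt.date.fromisoformat(d) >= closure_start]
        for pid, ds in schedule.items()
    }
    truth["has_pre_data"] = [bool(pre_dates[p]) for p in truth["participant_id"]]
    truth["has_post_data"] = [bool(post_dates[p]) for p in truth["participant_id"]]
    return minutes_by_pid, demographics, GroundTruth(truth, schedule)


def generate_week_summaries(
    config: SyntheticConfig | None = None, seed: int | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw WeekSummary rows directly from the generative week-level model.

    For each non-dropped participant-week, valid weekday/weekend day counts
    are Binomial(5, p) and Binomial(2, p) with ``p = wear_day_prob``; weeks
    with zero valid days are omitted. The weekly value applies the standard
    5/2 weighting (or the all-valid-day mean fallback) to day values drawn
    around the participant's true period mean — the same arithmetic the
    day-level pipeline performs, without materializing minutes.
    """
    config = config or SyntheticConfig()
    seed = config.seed if seed is None else seed
    root = np.random.SeedSequence(seed)
    truth_rng = np.random.default_rng(root.spawn(1)[0])
    truth = _draw_truth(config, truth_rng)
    design = config.design

    wd_scale = _weekday_mean(1.0, config.weekend_step_ratio)
    rows = []
    participant_seeds = root.spawn(config.n_participants)
    for row, pseed in zip(truth.itertuples(index=False), participant_seeds):
        rng = np.random.default_rng(pseed)
        for week in range(1, config.n_weeks + 1):
            post = week >= config.closure_week
            if post and row.dropped_post:
                continue
            n_wd = int(rng.binomial(5, config.wear_day_prob))
            n_we = int(rng.binomial(2, config.wear_day_prob))
            if n_wd + n_we == 0:
                continue
            steps_mean = row.post_steps_mean if post else row.pre_steps_mean
            mvpa_mean = row.post_mvpa_mean if post else row.pre_mvpa_mean

            def weekly(mean, sd, n_wd=n_wd, n_we=n_we, rng=rng):
                wd_mean = mean * wd_scale
                we_mean = wd_mean * config.weekend_step_ratio
                wd_vals = _clipped_normal(rng, wd_mean, sd, size=n_wd)
                we_vals = _clipped_normal(rng, we_mean, sd, size=n_we)
                if n_wd and n_we:
                    return float((wd_vals.mean() * 5 + we_vals.mean() * 2) / 7)
                return float(np.concatenate([wd_vals, we_vals]).mean())

            steps_per_day = weekly(steps_mean, config.within_participant_day_sd)
            mvpa_per_day = weekly(mvpa_mean, config.mvpa_within_sd)
            rows.append(
                {
                    "participant_id": row.participant_id,
                    "study_week": week,
                    "period": POST if post else PRE,
                    "steps_per_day": steps_per_day,
                    "mvpa_min_per_day": mvpa_per_day,
                    "mvpa_min_per_week": 7.0 * mvpa_per_day,
                    "n_valid_weekdays": n_wd,
                    "n_valid_weekend_days": n_we,
                    "is_valid_week": True,
                }
            )
    weeks = pd.DataFrame(rows, columns=device_io.WEEK_COLUMNS)
    truth = truth.copy()
    has_pre = weeks[weeks["period"] == PRE].groupby("participant_id").size()
    has_post = weeks[weeks["period"] == POST].groupby("participant_id").size()
    truth["has_pre_data"] = [p in has_pre.index for p in truth["participant_id"]]
    truth["has_post_data"] = [p in has_post.index for p in truth["participant_id"]]
    return weeks, GroundTruth(truth, {})


def write_cohort(
    out_dir,
    config: SyntheticConfig | None = None,
    seed: int | None = None,
) -> tuple[dict, pd.DataFrame, GroundTruth]:
    """Generate a cohort and write it as pipeline-ready files.

    Writes one ``<participant_id>.csv`` minute file per participant,
    ``demographics.csv``, ``ground_truth.json`` and the ``design.yaml``
    consumed by the processing stages.
    """
    config = config or SyntheticConfig()
    os.makedirs(out_dir, exist_ok=True)
    minutes_by_pid, demographics, truth = generate_cohort(config, seed=seed)
    for pid, df in minutes_by_pid.items():
        device_io.write_minute_csv(df, os.path.join(out_dir, f"{pid}.csv"))
    device_io.write_demographics(demographics, os.path.join(out_dir, "demographics.csv"))
    truth.to_json(os.path.join(out_dir, "ground_truth.json"))
    config.design.to_yaml(os.path.join(out_dir, "design.yaml"))
    return minutes_by_pid, demographics, truth
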