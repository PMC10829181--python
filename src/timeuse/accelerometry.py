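"""Epoch-level accelerometry to daily time-use compositions.

Takes epoch-summarised wrist ENMO traces (mean acceleration magnitude
per epoch, in milli-g) together with participant sleep logs, classifies
every epoch as sleep / MVPA / LPA / SB / non-wear, aggregates to day
summaries, screens days and participants for validity, and averages to
a per-participant 24-hour time-use composition.

Classification rules
--------------------
* Epochs inside the logged bed-to-wake window or a logged nap are sleep,
  regardless of ENMO.
* Epochs flagged non-wear (device flag or a logged removal interval)
  outside sleep are non-wear.
* Remaining waking epochs are labelled by ENMO against wrist cut points:
  MVPA strictly above 93 mg, LPA strictly above 48 mg, otherwise SB.
  Ties sit with the lower class (93 mg -> LPA, 48 mg -> SB), a literal
  reading of the strict inequalities.

Validity screening
------------------
A day is valid when it has at least 10 waking-wear hours (600 min) and
less than 6 h (360 min) of non-wear -- jointly implying at least 18 h of
average wear per 24-h period.  A participant is included with at least
three valid weekdays, one valid weekend day, and an average recorded
daily total of at most 1500 min.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coda import DEFAULT_KAPPA, closure

__all__ = [
    "CutPoints",
    "EpochSeries",
    "SleepLogDay",
    "SleepLog",
    "DaySummary",
    "TimeUseSummary",
    "classify_epochs",
    "summarize_day",
    "assess_validity",
    "summarize_participant",
    "extract_participant",
    "read_epoch_csv",
    "read_sleep_log_csv",
]

LABELS = ("sleep", "mvpa", "lpa", "sb", "nonwear")
BEHAVIOURS = ("mvpa", "lpa", "sb", "sleep")

MIN_WAKING_WEAR_MIN = 600.0   # at least 10 waking hours of wear
MAX_NONWEAR_MIN = 360.0       # less than six hours of non-wear
MIN_VALID_WEEKDAYS = 3
MIN_VALID_WEEKEND_DAYS = 1
MAX_AVG_DAILY_TOTAL_MIN = 1500.0


@dataclass(frozen=True)
class CutPoints:
    """Wrist ENMO cut points (mg); MVPA strictly above ``mvpa``, LPA strictly above ``lpa``."""

    mvpa: float = 93.0
    lpa: float = 48.0


@dataclass
class EpochSeries:
    """Uniformly spaced epoch ENMO series spanning whole calendar days."""

    participant_id: str
    timestamps: pd.DatetimeIndex
    enmo: np.ndarray          # mg, >= 0
    wear: np.ndarray          # bool
    epoch_seconds: int = 60

    def __post_init__(self):
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.enmo = np.asarray(self.enmo, dtype=float)
        self.wear = np.asarray(self.wear, dtype=bool)
        n = len(self.timestamps)
        if not (len(self.enmo) == len(self.wear) == n):
            raise ValueError("timestamps, enmo and wear must have equal length")
        if n > 1:
            steps = np.diff(self.timestamps.asi8)
            if steps.min() <= 0 or steps.min() != steps.max():
                raise ValueError("timestamps must be strictly increasing with constant step")
            if steps[0] != self.epoch_seconds * 1_000_000_000:
                raise ValueError(
                    f"timestamp step does not match epoch_seconds={self.epoch_seconds}"
                )
        if np.any(self.enmo < 0):
            raise ValueError("ENMO values must be non-negative")
        per_day = 86400 // self.epoch_seconds
        if n % per_day:
            raise ValueError("series must span whole calendar days")

    @property
    def dates(self):
        return self.timestamps.normalize().date


@dataclass
class SleepLogDay:
    """Logged sleep anchors for one calendar day.

    ``wake_time`` ends the overnight sleep that spills into this day;
    ``bed_time`` starts the evening sleep.  Naps and device-removal
    intervals are (start, end) timestamp pairs inside the day.
    """

    date: dt.date
    wake_time: pd.Timestamp
    bed_time: pd.Timestamp
    naps: list = field(default_factory=list)
    removals: list = field(default_factory=list)

    def __post_init__(self):
        for name, ivals in (("nap", self.naps), ("removal", self.removals)):
            for start, end in ivals:
                if not start < end:
                    raise ValueError(f"malformed {name} interval on {self.date}: {start} !< {end}")
        if not self.wake_time < self.bed_time:
            raise ValueError(f"wake time must precede bed time on {self.date}")


@dataclass
class SleepLog:
    days: dict  # date -> SleepLogDay

    def day(self, date: dt.date) -> SleepLogDay:
        try:
            return self.days[date]
        except KeyError:
            raise KeyError(f"sleep log has no entry for day {date}") from None


def classify_epochs(series: EpochSeries, log: SleepLog,
                    cuts: CutPoints = CutPoints()) -> np.ndarray:
    """Label each epoch as sleep / mvpa / lpa / sb / nonwear.

    Sleep-log windows take precedence over everything (an epoch inside
    the bed-to-wake window is sleep whatever its ENMO), then non-wear,
    then ENMO cut points.
    """
    ts = series.timestamps
    labels = np.where(series.enmo > cuts.mvpa, "mvpa",
                      np.where(series.enmo > cuts.lpa, "lpa", "sb")).astype(object)

    nonwear = ~series.wear
    sleep = np.zeros(len(ts), dtype=bool)
    for date in pd.unique(series.dates):
        day = log.day(date)  # raises naming the day if missing
        in_day = series.dates == date
        t = ts[in_day]
        day_sleep = (t < day.wake_time) | (t >= day.bed_time)
        for start, end in day.naps:
            day_sleep |= (t >= start) & (t < end)
        day_nonwear = np.zeros(in_day.sum(), dtype=bool)
        for start, end in day.removals:
            day_nonwear |= (t >= start) & (t < end)
        sleep[in_day] = day_sleep
        nonwear[in_day] |= day_nonwear

    labels[nonwear] = "nonwear"
    labels[sleep] = "sleep"
    return labels


@dataclass
class DaySummary:
    date: dt.date
    is_weekend: bool
    minutes: dict               # label -> minutes, incl. nonwear
    waking_wear_minutes: float
    nonwear_minutes: float
    valid: bool = False


def summarize_day(labels: np.ndarray, date: dt.date,
                  epoch_seconds: int = 60) -> DaySummary:
    """Aggregate one full calendar day of epoch labels to minutes."""
    per_day = 86400 // epoch_seconds
    labels = np.asarray(labels, dtype=object)
    if len(labels) != per_day:
        raise ValueError(
            f"day {date}: expected {per_day} epochs at {epoch_seconds} s, got {len(labels)}"
        )
    epoch_min = epoch_seconds / 60.0
    minutes = {lab: float((labels == lab).sum()) * epoch_min for lab in LABELS}
    day = DaySummary(
        date=date,
        is_weekend=date.weekday() >= 5,
        minutes=minutes,
        waking_wear_minutes=minutes["mvpa"] + minutes["lpa"] + minutes["sb"],
        nonwear_minutes=minutes["nonwear"],
    )
    day.valid = assess_validity(day)
    return day


def assess_validity(day: DaySummary) -> bool:
    """Valid wear day: >= 10 waking-wear hours and < 6 h non-wear."""
    return (day.waking_wear_minutes >= MIN_WAKING_WEAR_MIN
            and day.nonwear_minutes < MAX_NONWEAR_MIN)


@dataclass
class TimeUseSummary:
    participant_id: str
    mean_minutes: dict          # behaviour -> average min/day over valid days (pre-closure)
    composition: np.ndarray     # closed to kappa, None when excluded
    n_valid_weekdays: int
    n_valid_weekend_days: int
    included: bool
    exclusion_reason: str = ""
    zero_replaced: tuple = ()


def summarize_participant(days, participant_id: str = "",
                          epoch_seconds: int = 60,
                          kappa: float = DEFAULT_KAPPA) -> TimeUseSummary:
    """Average valid days and apply participant-level inclusion rules.

    Exclusions are reported on the returned summary, never raised.
    Behaviours never observed on any valid day are replaced by half the
    smallest observable increment (half an epoch, in minutes) before
    closure so the composition stays strictly positive; replaced parts
    are flagged in ``zero_replaced``.
    """
    days = list(days)
    if not days:
        raise ValueError("summarize_participant requires at least one day")
    valid = [d for d in days if d.valid]
    n_wk = sum(1 for d in valid if not d.is_weekend)
    n_we = sum(1 for d in valid if d.is_weekend)

    def excluded(reason):
        return TimeUseSummary(participant_id, {}, None, n_wk, n_we, False, reason)

    if not valid:
        return excluded("no_valid_days")
    if n_wk < MIN_VALID_WEEKDAYS:
        return excluded("insufficient_weekdays")
    if n_we < MIN_VALID_WEEKEND_DAYS:
        return excluded("no_weekend_day")

    mean_minutes = {
        b: float(np.mean([d.minutes[b] for d in valid])) for b in BEHAVIOURS
    }
    if sum(mean_minutes.values()) > MAX_AVG_DAILY_TOTAL_MIN:
        return excluded("overfull_day")

    half_epoch_min = epoch_seconds / 60.0 * 0.5
    replaced = tuple(b for b in BEHAVIOURS if mean_minutes[b] == 0.0)
    pre = np.array([mean_minutes[b] if mean_minutes[b] > 0 else half_epoch_min
                    for b in BEHAVIOURS])
    return TimeUseSummary(
        participant_id=participant_id,
        mean_minutes=mean_minutes,
        composition=closure(pre, kappa),
        n_valid_weekdays=n_wk,
        n_valid_weekend_days=n_we,
        included=True,
        zero_replaced=replaced,
    )


def extract_participant(series: EpochSeries, log: SleepLog,
                        cuts: CutPoints = CutPoints(),
                        kappa: float = DEFAULT_KAPPA) -> TimeUseSummary:
    """Classify, summarise per day, and screen one participant end to end."""
    labels = classify_epochs(series, log, cuts)
    per_day = 86400 // series.epoch_seconds
    days = []
    for k, date in enumerate(pd.unique(series.dates)):
        chunk = labels[k * per_day:(k + 1) * per_day]
        days.append(summarize_day(chunk, date, series.epoch_seconds))
    return summarize_participant(days, series.participant_id,
                                 series.epoch_seconds, kappa)


def read_epoch_csv(path, participant_id: str = "") -> EpochSeries:
    """Read an epoch CSV with columns timestamp (ISO-8601), enmo_mg, wear (0/1)."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    ts = pd.DatetimeIndex(df["timestamp"])
    if len(ts) < 2:
        raise ValueError("epoch CSV must contain at least two epochs")
    step = int((ts[1] - ts[0]).total_seconds())
    return EpochSeries(
        participant_id=participant_id or str(df.get("participant_id", pd.Series(["?"])).iloc[0]),
        timestamps=ts,
        enmo=df["enmo_mg"].to_numpy(),
        wear=df["wear"].to_numpy().astype(bool),
        epoch_seconds=step,
    )


def read_sleep_log_csv(path) -> SleepLog:
    """Read a sleep-log CSV: date, wake_time, bed_time, optional nap/removal intervals.

    Rows with the same date are merged; nap_start/nap_end and
    removal_start/removal_end columns may repeat across rows.
    """
    df = pd.read_csv(path)
    days = {}
    for _, row in df.iterrows():
        date = pd.Timestamp(row["date"]).date()
        if date not in days:
            days[date] = SleepLogDay(
                date=date,
                wake_time=pd.Timestamp(f"{date} {row['wake_time']}"),
                bed_time=pd.Timestamp(f"{date} {row['bed_time']}"),
            )
        day = days[date]
        for kind, target in (("nap", day.naps), ("removal", day.removals)):
            start, end = row.get(f"{kind}_start"), row.get(f"{kind}_end")
            if pd.notna(start) and pd.notna(end):
                target.append((pd.Timestamp(f"{date} {start}"),
                               pd.Timestamp(f"{date} {end}")))
        # re-validate after appending intervals
        SleepLogDay(day.date, day.wake_time, day.bed_time, day.naps, day.removals)
    return SleepLog(days)
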