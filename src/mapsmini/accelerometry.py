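"""Accelerometer epoch processing: wear time, valid days, MVPA minutes.

Counts arrive as fixed-length epochs (30 s for youth devices, 60 s for
older adults).  Non-wear is detected as maximal runs of consecutive
zero-count epochs at least as long as an age-specific window (20 / 30 / 45
minutes for children / adolescents / older adults); a single non-zero epoch
terminates a run, with no interruption allowance.  A valid monitoring day
has at least 10 hours of wear.  Moderate-to-vigorous physical activity
(MVPA) minutes are wear epochs at or above an intensity cut point expressed
in counts per minute; 30-s epoch counts are doubled onto the
counts-per-minute scale rather than re-integrated to 60-s epochs.

Cut points are configuration, not constants.  The shipped defaults are the
Freedson adult moderate threshold (1952 counts/min, 3 METs) and the
Freedson/Trost youth age-specific regression
``METs = 2.757 + 0.0015*cpm - 0.08957*age - 0.000038*cpm*age`` solved for
the target MET level; both are provisional and overrideable.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AgeGroup",
    "EpochSeries",
    "WearMask",
    "LocationIntervals",
    "AccelConfig",
    "DailySummary",
    "FREEDSON_ADULT_MODERATE_CPM",
    "freedson_youth_cutpoint",
    "detect_nonwear",
    "mvpa_minutes",
    "filter_nonschool",
    "link_neighborhood",
    "summarize_days",
    "mean_daily_mvpa",
    "read_epoch_csv",
    "write_epoch_csv",
]


class AgeGroup(str, enum.Enum):
    CHILD = "child"
    ADOLESCENT = "adolescent"
    ADULT = "adult"
    OLDER_ADULT = "older_adult"


#: Freedson 1998 adult moderate-intensity (3 MET) threshold, counts/min.
FREEDSON_ADULT_MODERATE_CPM = 1952.0


def freedson_youth_cutpoint(age_years: float, mets: float) -> float:
    """Counts/min threshold from the Freedson/Trost youth energy-expenditure
    regression, solved for the requested MET level at the given age."""
    denom = 0.0015 - 0.000038 * age_years
    if denom <= 0:
        raise ValueError(f"youth equation undefined for age {age_years}")
    return (mets - 2.757 + 0.08957 * age_years) / denom


#: Consecutive-zero non-wear windows in minutes, by age group.
DEFAULT_NONWEAR_MINUTES = {
    AgeGroup.CHILD: 20,
    AgeGroup.ADOLESCENT: 30,
    AgeGroup.OLDER_ADULT: 45,
}

DEFAULT_EPOCH_SECONDS = {
    AgeGroup.CHILD: 30,
    AgeGroup.ADOLESCENT: 30,
    AgeGroup.OLDER_ADULT: 60,
}


@dataclass
class EpochSeries:
    """Timestamped activity counts at a fixed epoch length.

    Freshly read series are contiguous; the window/location filters return
    non-contiguous subsets of the same type.
    """

    participant_id: str
    epoch_length: int  # seconds, 30 or 60
    timestamps: pd.DatetimeIndex
    counts: np.ndarray

    def __post_init__(self) -> None:
        if self.epoch_length not in (30, 60):
            raise ValueError(f"epoch_length must be 30 or 60 s, got {self.epoch_length}")
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        if len(self.timestamps) != len(self.counts):
            raise ValueError("timestamps and counts must be the same length")

    @classmethod
    def from_start(cls, participant_id: str, epoch_length: int,
                   start_time, counts: Sequence[int]) -> "EpochSeries":
        start = pd.Timestamp(start_time)
        n = len(counts)
        ts = start + pd.to_timedelta(np.arange(n) * epoch_length, unit="s")
        return cls(participant_id, epoch_length, pd.DatetimeIndex(ts), np.asarray(counts))

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def is_contiguous(self) -> bool:
        if len(self) < 2:
            return True
        deltas = np.diff(self.timestamps.asi8) / 1e9
        return bool(np.all(deltas == self.epoch_length))

    @property
    def counts_per_min(self) -> np.ndarray:
        return self.counts * (60.0 / self.epoch_length)

    def subset(self, keep: np.ndarray) -> "EpochSeries":
        return EpochSeries(self.participant_id, self.epoch_length,
                           self.timestamps[keep], self.counts[keep])


@dataclass
class WearMask:
    """Per-epoch wear flag aligned with an :class:`EpochSeries` (True = worn)."""

    wear: np.ndarray

    def __post_init__(self) -> None:
        self.wear = np.asarray(self.wear, dtype=bool)

    def __len__(self) -> int:
        return len(self.wear)

    def subset(self, keep: np.ndarray) -> "WearMask":
        return WearMask(self.wear[keep])


@dataclass
class LocationIntervals:
    """Reported times in neighborhood locations, as [start, end) intervals."""

    participant_id: str
    intervals: list[tuple[pd.Timestamp, pd.Timestamp]]

    def __post_init__(self) -> None:
        self.intervals = [(pd.Timestamp(a), pd.Timestamp(b)) for a, b in self.intervals]
        for a, b in self.intervals:
            if not b > a:
                raise ValueError(f"interval end {b} not after start {a}")


@dataclass
class AccelConfig:
    age_group: AgeGroup
    nonwear_window: float  # minutes of consecutive zeros
    cutpoint_counts_per_min: float
    min_valid_hours: float = 10.0
    school_window: tuple[int, int] = (15, 23)  # weekday [15:00, 23:00)

    def __post_init__(self) -> None:
        self.age_group = AgeGroup(self.age_group)
        if self.nonwear_window <= 0:
            raise ValueError("nonwear_window must be positive")
        if not 0 < self.min_valid_hours <= 24:
            raise ValueError("min_valid_hours must be in (0, 24]")
        if self.cutpoint_counts_per_min <= 0:
            raise ValueError("cutpoint must be positive")

    @classmethod
    def for_age_group(cls, age_group: AgeGroup | str,
                      age_years: Optional[float] = None) -> "AccelConfig":
        """Default configuration per study protocol: children scored at the
        youth 3-MET cut point, adolescents at the youth 4-MET cut point,
        older adults at the adult 3-MET cut point.  ``age_years`` feeds the
        youth age-specific equation (defaults: 10 for children, 14 for
        adolescents)."""
        age_group = AgeGroup(age_group)
        if age_group is AgeGroup.ADULT:
            raise ValueError("adults did not wear accelerometers in this protocol")
        if age_group is AgeGroup.CHILD:
            cut = freedson_youth_cutpoint(age_years if age_years is not None else 10.0, 3.0)
        elif age_group is AgeGroup.ADOLESCENT:
            cut = freedson_youth_cutpoint(age_years if age_years is not None else 14.0, 4.0)
        else:
            cut = FREEDSON_ADULT_MODERATE_CPM
        return cls(age_group=age_group,
                   nonwear_window=DEFAULT_NONWEAR_MINUTES[age_group],
                   cutpoint_counts_per_min=cut)


@dataclass
class DailySummary:
    date: date
    wear_minutes: float
    valid: bool
    mvpa_minutes: float
    mvpa_minutes_windowed: float
    mvpa_minutes_neighborhood: Optional[float]


# ---------------------------------------------------------------------------


def detect_nonwear(series: EpochSeries, window_minutes: float) -> WearMask:
    """Flag non-wear: every maximal run of zero-count epochs lasting at
    least ``window_minutes`` (boundary inclusive).  Requires a contiguous
    series; a single non-zero epoch terminates a run."""
    if window_minutes <= 0:
        raise ValueError("window_minutes must be positive")
    n = len(series)
    if n == 0:
        return WearMask(np.zeros(0, dtype=bool))
    window_epochs = int(np.ceil(window_minutes * 60.0 / series.epoch_length))
    zero = series.counts == 0
    wear = np.ones(n, dtype=bool)
    # run-length encode the zero indicator
    change = np.flatnonzero(np.diff(zero.astype(np.int8)))
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [n]))
    for s, e in zip(starts, ends):
        if zero[s] and (e - s) >= window_epochs:
            wear[s:e] = False
    return WearMask(wear)


def mvpa_minutes(series: EpochSeries, mask: WearMask,
                 cutpoint_counts_per_min: float) -> pd.Series:
    """MVPA minutes per calendar day: wear epochs whose counts-per-minute
    reach the cut point, times the epoch length."""
    if cutpoint_counts_per_min <= 0:
        raise ValueError("cutpoint must be positive")
    if len(mask) != len(series):
        raise ValueError("mask not aligned with series")
    active = mask.wear & (series.counts_per_min >= cutpoint_counts_per_min)
    days = series.timestamps.normalize()
    per_day = pd.Series(active, index=days).groupby(level=0).sum()
    return per_day * (series.epoch_length / 60.0)


def _nonschool_selector(series: EpochSeries, window: tuple[int, int] = (15, 23)) -> np.ndarray:
    ts = series.timestamps
    weekend = ts.dayofweek >= 5  # Saturday, Sunday
    in_window = (ts.hour >= window[0]) & (ts.hour < window[1])
    return np.asarray(weekend | in_window)


def filter_nonschool(series: EpochSeries,
                     window: tuple[int, int] = (15, 23)) -> EpochSeries:
    """Keep weekday epochs starting within the after-school clock window
    (default [15:00, 23:00), half-open) plus all weekend epochs."""
    return series.subset(_nonschool_selector(series, window))


def _interval_selector(series: EpochSeries, intervals: LocationIntervals) -> np.ndarray:
    keep = np.zeros(len(series), dtype=bool)
    ts = series.timestamps
    for start, end in intervals.intervals:
        keep |= np.asarray((ts >= start) & (ts < end))  # half-open [start, end)
    return keep


def link_neighborhood(series: EpochSeries, intervals: LocationIntervals) -> EpochSeries:
    """Keep epochs whose start time lies inside any reported neighborhood
    interval (half-open [start, end))."""
    return series.subset(_interval_selector(series, intervals))


def summarize_days(
    series: EpochSeries,
    mask: WearMask,
    cfg: AccelConfig,
    intervals: Optional[LocationIntervals] = None,
) -> list[DailySummary]:
    """Per-calendar-day wear and MVPA summaries.

    Wear minutes and validity are judged over the whole day; the windowed
    (non-school) and neighborhood MVPA fields restrict which epochs may
    contribute activity, not the wear-time denominator.
    """
    if len(mask) != len(series):
        raise ValueError("mask not aligned with series")
    if len(series) == 0:
        return []
    epoch_min = series.epoch_length / 60.0
    days = series.timestamps.normalize()
    wear_by_day = pd.Series(mask.wear, index=days).groupby(level=0).sum() * epoch_min
    mvpa_all = mvpa_minutes(series, mask, cfg.cutpoint_counts_per_min)

    sel_win = _nonschool_selector(series, cfg.school_window)
    mvpa_win = mvpa_minutes(series.subset(sel_win), mask.subset(sel_win),
                            cfg.cutpoint_counts_per_min) if sel_win.any() else pd.Series(dtype=float)
    if intervals is not None:
        sel_nb = _interval_selector(series, intervals)
        mvpa_nb = mvpa_minutes(series.subset(sel_nb), mask.subset(sel_nb),
                               cfg.cutpoint_counts_per_min) if sel_nb.any() else pd.Series(dtype=float)
    else:
        mvpa_nb = None

    out = []
    for day in wear_by_day.index:
        wear_min = float(wear_by_day.loc[day])
        out.append(DailySummary(
            date=day.date(),
            wear_minutes=wear_min,
            valid=wear_min >= 60.0 * cfg.min_valid_hours,
            mvpa_minutes=float(mvpa_all.get(day, 0.0)),
            mvpa_minutes_windowed=float(mvpa_win.get(day, 0.0)),
            mvpa_minutes_neighborhood=(None if mvpa_nb is None
                                       else float(mvpa_nb.get(day, 0.0))),
        ))
    return out


def mean_daily_mvpa(
    summaries: Iterable[DailySummary],
    which: str = "mvpa_minutes",
    min_valid_days: int = 1,
) -> Optional[float]:
    """Mean MVPA minutes/day over valid days only.

    Returns ``None`` when fewer than ``min_valid_days`` valid days exist:
    the participant is excluded, not scored zero.
    """
    values = [getattr(s, which) for s in summaries if s.valid]
    values = [v for v in values if v is not None]
    if len(values) < min_valid_days:
        return None
    return float(np.mean(values))


# ---------------------------------------------------------------------------
# CSV I/O: long format, one row per epoch.


def write_epoch_csv(series_map: dict[str, EpochSeries], path: str | Path) -> Path:
    path = Path(path)
    frames = []
    for pid in series_map:
        s = series_map[pid]
        frames.append(pd.DataFrame({
            "participant_id": pid,
            "timestamp": s.timestamps.strftime("%Y-%m-%dT%H:%M:%S"),
            "epoch_length": s.epoch_length,
            "counts": s.counts,
        }))
    df = (pd.concat(frames, ignore_index=True) if frames
          else pd.DataFrame(columns=["participant_id", "timestamp", "epoch_length", "counts"]))
    df.to_csv(path, index=False)
    return path


def read_epoch_csv(path: str | Path) -> dict[str, EpochSeries]:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    out: dict[str, EpochSeries] = {}
    for pid, grp in df.groupby("participant_id", sort=False):
        grp = grp.sort_values("timestamp")
        epoch_lengths = grp["epoch_length"].unique()
        if len(epoch_lengths) != 1:
            raise ValueError(f"participant {pid}: mixed epoch lengths {epoch_lengths}")
        out[str(pid)] = EpochSeries(
            participant_id=str(pid),
            epoch_length=int(epoch_lengths[0]),
            timestamps=pd.DatetimeIndex(grp["timestamp"]),
            counts=grp["counts"].to_numpy(),
        )
    return out


def write_intervals_csv(intervals_map: dict[str, LocationIntervals], path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for pid, iv in intervals_map.items():
        for a, b in iv.intervals:
            rows.append({"participant_id": pid,
                         "start": a.strftime("%Y-%m-%dT%H:%M:%S"),
                         "end": b.strftime("%Y-%m-%dT%H:%M:%S")})
    pd.DataFrame(rows, columns=["participant_id", "start", "end"]).to_csv(path, index=False)
    return path


def read_intervals_csv(path: str | Path) -> dict[str, LocationIntervals]:
    df = pd.read_csv(path, parse_dates=["start", "end"])
    out: dict[str, LocationIntervals] = {}
    for pid, grp in df.groupby("participant_id", sort=False):
        out[str(pid)] = LocationIntervals(
            participant_id=str(pid),
            intervals=list(zip(grp["start"], grp["end"])),
        )
    return out
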