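"""Epoch schedule, activity scoring and wear detection for wrist-worn traces.

The watch divides the monitored day (08:00-17:00) into four 2-hour periods and
one final 1-hour period.  Raw tri-axial acceleration (in g) is reduced to one
*activity score* (AS) per epoch — an arbitrary-unit measure of overall body
movement meaningful only relatively, day to day — together with a
movement-based estimate of whether the watch was worn.

The AS is computed as the rectified, gravity-subtracted signal vector
magnitude with a small dead-band, integrated over the epoch:

    AS = sum_i  m_i * dt_i,   m_i = |sqrt(ax^2+ay^2+az^2) - 1|  if >= dead_band else 0

which is non-negative, additive over a partition of the window, zero for a
stationary trace in any orientation, and insensitive to the direction of the
constant gravity component.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date as Date
from datetime import datetime, time
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "AccelSample",
    "EpochWindow",
    "EpochRecord",
    "ScheduleConfig",
    "ScoringConfig",
    "WearConfig",
    "DEFAULT_PERIODS",
    "build_epochs",
    "compute_activity_score",
    "detect_worn",
]


class AccelSample(NamedTuple):
    """One raw accelerometer sample: time in seconds, axes in g."""

    t: float
    ax: float
    ay: float
    az: float


#: Default daily schedule: four 2-h periods and one 1-h period, 08:00-17:00.
DEFAULT_PERIODS: tuple[tuple[time, time], ...] = (
    (time(8, 0), time(10, 0)),
    (time(10, 0), time(12, 0)),
    (time(12, 0), time(14, 0)),
    (time(14, 0), time(16, 0)),
    (time(16, 0), time(17, 0)),
)


@dataclass(frozen=True)
class ScheduleConfig:
    """Daily epoch layout; windows must be disjoint and contiguous."""

    periods: tuple[tuple[time, time], ...] = DEFAULT_PERIODS

    def validate(self) -> None:
        if not self.periods:
            raise ValueError("schedule must define at least one period")
        for start, end in self.periods:
            if start >= end:
                raise ValueError(f"empty or inverted window {start}-{end}")
        for (_, prev_end), (next_start, _) in zip(self.periods, self.periods[1:]):
            if next_start < prev_end:
                raise ValueError("schedule windows overlap")
            if next_start > prev_end:
                raise ValueError("schedule windows leave a gap in the day")


@dataclass(frozen=True)
class EpochWindow:
    """Half-open daily window [start, end) on a calendar date."""

    date: Date
    period_index: int  # 1-based
    start: time
    end: time

    @property
    def start_dt(self) -> datetime:
        return datetime.combine(self.date, self.start)

    @property
    def end_dt(self) -> datetime:
        return datetime.combine(self.date, self.end)

    @property
    def duration_s(self) -> float:
        return (self.end_dt - self.start_dt).total_seconds()

    def contains(self, t_seconds: float) -> bool:
        """Whether a trace timestamp (seconds since the date's midnight) falls in the window."""
        start_s = self.start.hour * 3600 + self.start.minute * 60 + self.start.second
        end_s = self.end.hour * 3600 + self.end.minute * 60 + self.end.second
        return start_s <= t_seconds < end_s


@dataclass
class EpochRecord:
    """One patient-day-period activity record — the atomic analytic unit."""

    patient_id: str
    date: Date
    period_index: int
    activity_score: float
    worn: bool
    worn_fraction: float

    def __post_init__(self) -> None:
        if self.activity_score < 0:
            raise ValueError("activity_score must be non-negative")
        if not 0.0 <= self.worn_fraction <= 1.0:
            raise ValueError("worn_fraction must lie in [0, 1]")


def build_epochs(date: Date, schedule: ScheduleConfig | None = None) -> list[EpochWindow]:
    """Return the day's epoch windows (default: five, spanning 08:00-17:00).

    Windows are half-open, pairwise disjoint and jointly cover the monitored
    day, so every daytime instant maps to exactly one period index.
    """
    schedule = schedule or ScheduleConfig()
    schedule.validate()
    return [
        EpochWindow(date=date, period_index=i + 1, start=start, end=end)
        for i, (start, end) in enumerate(schedule.periods)
    ]


@dataclass(frozen=True)
class ScoringConfig:
    """Activity-score parameters.

    dead_band : movement magnitudes below this (g) are treated as sensor noise
        and contribute nothing.  Default 0.05 g.
    gravity : magnitude of the static component subtracted before rectification
        (g).  Default 1.
    """

    dead_band: float = 0.05
    gravity: float = 1.0


class ScoreResult(NamedTuple):
    score: float
    no_data: bool

    def __float__(self) -> float:  # allows use where a plain AS is expected
        return self.score


def _window_mask(t: np.ndarray, window: EpochWindow) -> np.ndarray:
    start_s = window.start.hour * 3600 + window.start.minute * 60
    end_s = window.end.hour * 3600 + window.end.minute * 60
    return (t >= start_s) & (t < end_s)


def _as_arrays(trace: Sequence[AccelSample]) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray([(s[0], s[1], s[2], s[3]) for s in trace], dtype=float)
    if arr.size == 0:
        return np.empty(0), np.empty((0, 3))
    t = arr[:, 0]
    if not np.all(np.isfinite(arr)):
        raise ValueError("trace contains non-finite values")
    if np.any(np.diff(t) <= 0):
        raise ValueError("trace timestamps must be strictly increasing")
    return t, arr[:, 1:]


def _sample_dt(t: np.ndarray) -> float:
    """Sampling interval, taken as the median inter-sample gap."""
    if t.size < 2:
        return 1.0
    dt = float(np.median(np.diff(t)))
    if dt <= 0:
        raise ValueError("sampling interval must be positive")
    return dt


def compute_activity_score(
    trace: Sequence[AccelSample],
    window: EpochWindow,
    config: ScoringConfig | None = None,
) -> ScoreResult:
    """Integrate rectified, gravity-subtracted movement over a window.

    Returns the AS for samples whose timestamp (seconds since the window
    date's midnight) falls inside the half-open window.  An empty selection
    yields score 0 with ``no_data=True``.
    """
    config = config or ScoringConfig()
    t, xyz = _as_arrays(trace)
    if t.size == 0:
        return ScoreResult(0.0, True)
    dt = _sample_dt(t)
    mask = _window_mask(t, window)
    if not mask.any():
        return ScoreResult(0.0, True)
    vm = np.linalg.norm(xyz[mask], axis=1)
    m = np.abs(vm - config.gravity)
    m[m < config.dead_band] = 0.0
    return ScoreResult(float(np.sum(m) * dt), False)


@dataclass(frozen=True)
class WearConfig:
    """Wear-detection parameters.

    The window is tiled into ``sub_window_s`` stretches; a stretch counts as
    active when the variance of the vector magnitude of its samples exceeds
    ``variance_threshold``.  The watch is deemed worn when at least
    ``min_fraction`` of stretches are active — deliberately conservative, so
    time worn is under- rather than over-estimated.
    """

    sub_window_s: float = 60.0
    variance_threshold: float = 1e-4  # g^2
    min_fraction: float = 0.25


def detect_worn(
    trace: Sequence[AccelSample],
    window: EpochWindow,
    config: WearConfig | None = None,
) -> tuple[bool, float]:
    """Movement-based wear estimate: (worn, fraction of active sub-windows)."""
    config = config or WearConfig()
    t, xyz = _as_arrays(trace)
    start_s = window.start.hour * 3600 + window.start.minute * 60
    n_sub = max(1, math.ceil(window.duration_s / config.sub_window_s))
    if t.size == 0:
        return (False, 0.0)
    mask = _window_mask(t, window)
    if not mask.any():
        return (False, 0.0)
    t_w = t[mask]
    vm = np.linalg.norm(xyz[mask], axis=1)
    idx = np.minimum(((t_w - start_s) // config.sub_window_s).astype(int), n_sub - 1)
    active = 0
    for k in np.unique(idx):
        seg = vm[idx == k]
        if seg.size >= 2 and float(np.var(seg)) >= config.variance_threshold:
            active += 1
    fraction = active / n_sub
    return (fraction >= config.min_fraction, fraction)
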