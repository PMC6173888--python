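"""Adaptive goal setting and the four-bar feedback display.

Each weekday after the baseline day, the watch sets a per-period goal equal to
a 5% increase on the activity recorded in the comparable epoch the preceding
weekday (Friday feeds Monday).  In feedback mode, progress through a period is
shown on a four-level bar: level 1 (red, default) below one third of the goal,
level 2 (orange) from one third, level 3 (yellow) from two thirds, level 4
(green) at or above the full goal.  Control mode shows the clock icon only —
its output stream carries no bar information.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import date as Date
from datetime import timedelta
from typing import Mapping, Sequence

__all__ = [
    "Mode",
    "GoalState",
    "FeedbackState",
    "FeedbackEvent",
    "GOAL_INCREASE",
    "comparable_previous_day",
    "set_goal",
    "bar_state",
    "FeedbackController",
    "run_intervention_day",
]

#: Daily goal multiplier: a 5% increase on the comparable previous-day epoch.
GOAL_INCREASE = 1.05


class Mode(str, enum.Enum):
    FEEDBACK = "feedback"
    CONTROL = "control"


class GoalSource(str, enum.Enum):
    """Provenance of the goal used for a period (for gap flagging)."""

    PREVIOUS_DAY = "previous_day"
    LAST_RECORDED = "last_recorded"   # comparable day missing; most recent same-period score
    BASELINE = "baseline"             # no later recording; baseline score
    DEFAULT = "default"               # no baseline either; configured default
    NONE = "none"                     # baseline day: no goal yet


@dataclass
class GoalState:
    """Per-patient, per-period goal bookkeeping."""

    patient_id: str
    period_index: int
    baseline_score: float | None = None
    current_goal: float | None = None
    last_observed: float | None = None
    goal_source: GoalSource = GoalSource.NONE

    def __post_init__(self) -> None:
        if self.current_goal is not None and self.current_goal < 0:
            raise ValueError("current_goal must be non-negative")


@dataclass(frozen=True)
class FeedbackState:
    """Display state at one instant: period icon, and a bar only in feedback mode."""

    mode: Mode
    period_icon: int
    bar_level: int | None = None

    def __post_init__(self) -> None:
        if self.mode is Mode.CONTROL and self.bar_level is not None:
            raise ValueError("control mode displays the clock icon only")
        if self.bar_level is not None and not 1 <= self.bar_level <= 4:
            raise ValueError("bar_level must be in 1..4")


@dataclass(frozen=True)
class FeedbackEvent:
    """A timestamped display state within a period."""

    patient_id: str
    date: Date
    period_index: int
    timestamp: float  # seconds since midnight
    state: FeedbackState
    goal_source: GoalSource = GoalSource.PREVIOUS_DAY


def comparable_previous_day(date: Date) -> Date:
    """The preceding watch weekday: Friday for a Monday, else the previous day.

    The intervention runs Monday to Friday; weekend dates are rejected.
    """
    wd = date.weekday()
    if wd >= 5:
        raise ValueError(f"{date} falls on a weekend; the intervention runs Monday-Friday")
    return date - timedelta(days=3 if wd == 0 else 1)


def set_goal(prev_epoch_score: float) -> float:
    """Goal = 1.05 x the comparable previous-day epoch score."""
    if prev_epoch_score < 0:
        raise ValueError("epoch score must be non-negative")
    return GOAL_INCREASE * prev_epoch_score


def bar_state(cumulative_score: float, goal: float) -> int:
    """Bar level 1-4 for cumulative within-period AS against the period goal.

    Thresholds sit at one third, two thirds and the full goal (inclusive at
    each boundary); a zero goal is already met, so it displays level 4.
    """
    if cumulative_score < 0 or goal < 0:
        raise ValueError("scores and goals must be non-negative")
    if cumulative_score >= goal:
        return 4
    # goal > 0 from here on
    if cumulative_score >= 2.0 * goal / 3.0:
        return 3
    if cumulative_score >= goal / 3.0:
        return 2
    return 1


@dataclass
class FeedbackController:
    """Stateful per-patient driver of the goal rule across intervention days.

    Tracks per-period baselines, the most recent recorded score per period and
    the current goals; ``process_day`` replays one day's within-period
    cumulative activity and emits the display timeline.
    """

    patient_id: str
    mode: Mode
    n_periods: int = 5
    default_goal: float = 0.0
    goals: dict[int, GoalState] = field(default_factory=dict)
    _baseline_date: Date | None = None

    def __post_init__(self) -> None:
        self.mode = Mode(self.mode)
        for p in range(1, self.n_periods + 1):
            self.goals.setdefault(p, GoalState(self.patient_id, p))

    @property
    def baseline_recorded(self) -> bool:
        return self._baseline_date is not None

    def _goal_for(self, period: int) -> tuple[float, GoalSource]:
        gs = self.goals[period]
        if gs.goal_source is GoalSource.NONE:
            return self.default_goal, GoalSource.DEFAULT
        assert gs.current_goal is not None
        return gs.current_goal, gs.goal_source

    def process_day(
        self,
        date: Date,
        period_samples: Mapping[int, Sequence[tuple[float, float]]],
        period_totals: Mapping[int, float] | None = None,
    ) -> list[FeedbackEvent]:
        """Replay one intervention day and update goals for the next day.

        ``period_samples`` maps period index to (timestamp-seconds,
        incremental AS) pairs; the display state is recomputed at every
        ingested sample.  ``period_totals`` optionally supplies recorded
        end-of-period scores for periods with no sample stream (e.g. when
        replaying pre-aggregated epoch records).  Periods absent from both are
        treated as not recorded and leave the goal chain untouched.

        On the first processed day (the baseline day) no feedback is emitted
        in any mode; goals for day 2 are initialised to 1.05 x the baseline
        scores.
        """
        if date.weekday() >= 5:
            raise ValueError("intervention days run Monday-Friday")
        is_baseline = self._baseline_date is None
        events: list[FeedbackEvent] = []
        totals: dict[int, float] = dict(period_totals or {})

        for period in sorted(period_samples):
            samples = period_samples[period]
            cum = 0.0
            goal, source = self._goal_for(period)
            for ts, increment in samples:
                if increment < 0:
                    raise ValueError("incremental activity must be non-negative")
                cum += increment
                if is_baseline or self.mode is Mode.CONTROL:
                    state = FeedbackState(self.mode, period_icon=period, bar_level=None)
                else:
                    state = FeedbackState(
                        self.mode, period_icon=period, bar_level=bar_state(cum, goal)
                    )
                events.append(
                    FeedbackEvent(self.patient_id, date, period, ts, state, source)
                )
            totals.setdefault(period, cum)

        self._update_goals(date, totals, is_baseline)
        return events

    def _update_goals(self, date: Date, totals: Mapping[int, float], is_baseline: bool) -> None:
        if is_baseline:
            self._baseline_date = date
        for period in range(1, self.n_periods + 1):
            gs = self.goals[period]
            if period in totals:
                score = totals[period]
                if is_baseline or gs.baseline_score is None:
                    gs.baseline_score = score
                gs.last_observed = score
                gs.current_goal = set_goal(score)
                gs.goal_source = GoalSource.PREVIOUS_DAY
            else:
                # Missing comparable epoch: fall back to the most recent
                # recorded same-period score, then the baseline, else default.
                if gs.last_observed is not None:
                    gs.current_goal = set_goal(gs.last_observed)
                    gs.goal_source = GoalSource.LAST_RECORDED
                elif gs.baseline_score is not None:
                    gs.current_goal = set_goal(gs.baseline_score)
                    gs.goal_source = GoalSource.BASELINE
                else:
                    gs.current_goal = None
                    gs.goal_source = GoalSource.NONE


def run_intervention_day(
    controller: FeedbackController,
    date: Date,
    period_samples: Mapping[int, Sequence[tuple[float, float]]],
    period_totals: Mapping[int, float] | None = None,
) -> tuple[list[FeedbackEvent], dict[int, GoalState]]:
    """Functional wrapper: replay one day, return (timeline, updated goals)."""
    events = controller.process_day(date, period_samples, period_totals)
    return events, controller.goals
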