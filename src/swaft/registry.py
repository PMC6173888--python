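"""Eligibility screening, concealed 1:1 randomisation and registry bookkeeping.

The trial ran in two phases on a single rehabilitation ward: a non-randomised
observation phase (no feedback for anyone), then a parallel pilot RCT in which
patients were randomised 1:1 to daily activity feedback or no feedback using a
pre-generated concealed sequence consumed in registration order.

Screening is a pure conjunction of criteria: age 40-75, stroke onset less than
four months ago (operationalised as < 122 days, configurable), first
rehabilitation admission, able to walk 10 m pre-stroke, sufficient cognition,
able to follow a two-stage command, sufficient vision, and capacity to
consent.  A candidate failing only the two-stage command criterion is
re-screened at a 3-day follow-up rather than excluded outright.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import date as Date
from typing import Sequence

import numpy as np

__all__ = [
    "Candidate",
    "PatientRecord",
    "Group",
    "Phase",
    "ScreeningOutcome",
    "ScreeningResult",
    "ONSET_LIMIT_DAYS",
    "screen_eligibility",
    "randomise",
    "AllocationSequence",
    "TrialRegistry",
]

#: "Less than 4 months after stroke onset", counted in days.
ONSET_LIMIT_DAYS = 122

AGE_MIN, AGE_MAX = 40, 75


class Group(str, enum.Enum):
    OBSERVATION = "observation"
    FEEDBACK = "feedback"
    NO_FEEDBACK = "no_feedback"


class Phase(str, enum.Enum):
    OBSERVATION = "observation"
    RCT = "rct"


@dataclass(frozen=True)
class Candidate:
    id: str
    age: float | None = None
    days_since_stroke: float | None = None
    first_rehab_admission: bool | None = None
    could_walk_10m_prestroke: bool | None = None
    two_stage_command: bool | None = None
    sufficient_cognition: bool | None = None
    sufficient_vision: bool | None = None
    can_consent: bool | None = None
    screen_date: Date | None = None


class ScreeningOutcome(str, enum.Enum):
    ELIGIBLE = "eligible"
    INELIGIBLE = "ineligible"
    RECHECK_DAY3 = "recheck_day3"


@dataclass(frozen=True)
class ScreeningResult:
    outcome: ScreeningOutcome
    reasons: tuple[str, ...] = ()

    def __bool__(self) -> bool:
        return self.outcome is ScreeningOutcome.ELIGIBLE


def _criteria(onset_limit_days: int):
    return (
        ("age", lambda c: AGE_MIN <= c.age <= AGE_MAX, "age outside 40-75 years"),
        (
            "days_since_stroke",
            lambda c: c.days_since_stroke < onset_limit_days,
            "more than 4 months after stroke onset",
        ),
        ("first_rehab_admission", lambda c: c.first_rehab_admission, "not first rehabilitation admission"),
        ("could_walk_10m_prestroke", lambda c: c.could_walk_10m_prestroke, "could not walk 10 m pre-stroke"),
        ("sufficient_cognition", lambda c: c.sufficient_cognition, "insufficient cognition"),
        ("two_stage_command", lambda c: c.two_stage_command, "cannot follow two-stage command"),
        ("sufficient_vision", lambda c: c.sufficient_vision, "insufficient vision"),
        ("can_consent", lambda c: c.can_consent, "no capacity to consent"),
    )


def screen_eligibility(candidate: Candidate, onset_limit_days: int = ONSET_LIMIT_DAYS) -> ScreeningResult:
    """Apply the inclusion criteria as a conjunction.

    A candidate failing only the two-stage command criterion is flagged for a
    3-day re-screen; any other failure (or a missing field) is ineligible.
    """
    criteria = _criteria(onset_limit_days)
    missing = [name for name, _, _ in criteria if getattr(candidate, name) is None]
    if missing:
        return ScreeningResult(
            ScreeningOutcome.INELIGIBLE, ("incomplete screen: missing " + ", ".join(missing),)
        )
    failures = [reason for name, check, reason in criteria if not check(candidate)]
    if not failures:
        return ScreeningResult(ScreeningOutcome.ELIGIBLE)
    if failures == ["cannot follow two-stage command"]:
        return ScreeningResult(ScreeningOutcome.RECHECK_DAY3, tuple(failures))
    return ScreeningResult(ScreeningOutcome.INELIGIBLE, tuple(failures))


class AllocationSequence:
    """A pre-generated concealed randomisation sequence, consumed in order.

    Simple (Bernoulli) randomisation is the default, matching a spreadsheet
    random sequence and the 14/16 imbalance such sequences produce at n=30;
    permuted blocks are available as an option.  Deterministic given the seed,
    and regenerating from the seed yields identical assignments regardless of
    when patients registered — the concealment property.
    """

    def __init__(self, seed: int, method: str = "simple", block_size: int = 4):
        if method not in ("simple", "block"):
            raise ValueError("method must be 'simple' or 'block'")
        if method == "block" and (block_size <= 0 or block_size % 2):
            raise ValueError("block_size must be a positive even integer")
        self.seed = seed
        self.method = method
        self.block_size = block_size
        self._rng = np.random.default_rng(seed)
        self._sequence: list[Group] = []
        self._cursor = 0

    def _extend(self) -> None:
        if self.method == "simple":
            draws = self._rng.integers(0, 2, size=64)
            self._sequence.extend(
                Group.FEEDBACK if d else Group.NO_FEEDBACK for d in draws
            )
        else:
            half = self.block_size // 2
            block = np.array([0] * half + [1] * half)
            self._rng.shuffle(block)
            self._sequence.extend(
                Group.FEEDBACK if d else Group.NO_FEEDBACK for d in block
            )

    def draw(self) -> Group:
        while self._cursor >= len(self._sequence):
            self._extend()
        g = self._sequence[self._cursor]
        self._cursor += 1
        return g


def randomise(
    ids: Sequence[str], seed: int, method: str = "simple", block_size: int = 4
) -> dict[str, Group]:
    """Allocate ids 1:1 to feedback / no-feedback from a concealed sequence."""
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate patient ids in randomisation list")
    seq = AllocationSequence(seed, method=method, block_size=block_size)
    return {pid: seq.draw() for pid in ids}


@dataclass
class PatientRecord:
    id: str
    phase: Phase
    group: Group
    stroke_date: Date | None = None
    admission_date: Date | None = None
    registration_date: Date | None = None
    intervention_start: Date | None = None
    discharge_date: Date | None = None
    affected_side: str | None = None
    age: float | None = None
    sex: str | None = None
    valid: bool = True
    protocol_deviations: tuple[str, ...] = ()
    #: completion flags keyed by (timepoint, measure)
    assessments: dict[tuple[str, str], bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        dates = [self.stroke_date, self.admission_date, self.registration_date, self.intervention_start]
        known = [d for d in dates if d is not None]
        if any(a > b for a, b in zip(known, known[1:])):
            raise ValueError(
                "dates must satisfy stroke <= admission <= registration <= intervention start"
            )


class TrialRegistry:
    """Registry of screened-and-registered patients across both phases."""

    def __init__(self, allocation: AllocationSequence | None = None):
        self.allocation = allocation
        self.records: dict[str, PatientRecord] = {}

    def register_patient(
        self,
        candidate: Candidate,
        phase: Phase | str,
        *,
        force: bool = False,
        deviation_note: str | None = None,
        **record_fields,
    ) -> PatientRecord:
        """Register an eligible candidate; observation phase skips randomisation.

        Registering an ineligible candidate raises unless ``force=True``, in
        which case the record is created but flagged invalid with the
        deviation recorded — mirroring an accidental registration that must be
        excludable post hoc.
        """
        phase = Phase(phase)
        if candidate.id in self.records:
            raise ValueError(f"patient {candidate.id} already registered")
        result = screen_eligibility(candidate)
        valid = bool(result)
        deviations: tuple[str, ...] = ()
        if not valid:
            if not force:
                raise ValueError(
                    f"candidate {candidate.id} is not eligible: {', '.join(result.reasons)}"
                )
            deviations = result.reasons + ((deviation_note,) if deviation_note else ())
        elif deviation_note:
            deviations = (deviation_note,)

        if phase is Phase.OBSERVATION:
            group = Group.OBSERVATION
        else:
            if self.allocation is None:
                raise ValueError("RCT registration requires an allocation sequence")
            group = self.allocation.draw()

        record = PatientRecord(
            id=candidate.id,
            phase=phase,
            group=group,
            age=candidate.age,
            valid=valid,
            protocol_deviations=deviations,
            **record_fields,
        )
        self.records[candidate.id] = record
        return record

    @property
    def valid_records(self) -> list[PatientRecord]:
        return [r for r in self.records.values() if r.valid]
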