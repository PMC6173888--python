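"""Synthetic trial generator: patients, allocation, epoch activity, dropout.

Emulates the structure of a single-ward, two-phase smartwatch feasibility
trial: an observation phase followed by a 1:1 pilot RCT.  Admitted patients
are screened, a fraction consent, and recruits wear the watch on weekdays for
up to 15 watch days within 21 elapsed days or until discharge if sooner.

Activity follows a per-patient lognormal level multiplied by a daily trend,
an arm effect (a multiplicative uplift on post-baseline activity in the
feedback arm) and per-epoch lognormal noise — reproducing the heavy
inter-patient variability such cohorts show.  Wear is Bernoulli per period;
weekend recordings appear with their own probability; dropout is
missing-at-random given arm and day.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date as Date
from datetime import timedelta
from typing import Sequence

import numpy as np
import pandas as pd

from .analytics import (
    ANALYSIS_PERIODS,
    FOLLOWUP_MEASURES,
    PERFORMANCE_MEASURES,
    SELF_REPORT_MEASURES,
)
from .device import AccelSample, EpochWindow, ScoringConfig, WearConfig, build_epochs
from .registry import Group, Phase

__all__ = ["SimConfig", "simulate_cohort", "simulate_accel_trace"]

#: Relative weight of each period's activity (period 5 is half as long).
PERIOD_WEIGHTS = {1: 1.0, 2: 1.0, 3: 1.0, 4: 1.0, 5: 0.5}


@dataclass(frozen=True)
class SimConfig:
    """Study-condition knobs; defaults mirror the trial they emulate.

    The flow defaults (470 admitted, ~11% recruited, 40% of recruits in the
    observation phase, 22% post-baseline dropout, 62% follow-up contact) and
    the intervention envelope (up to 15 watch days within 21 elapsed days,
    Monday-Friday) reproduce the observed feasibility pattern; the activity
    model is a per-patient lognormal with a median around 120 AS/day and wide
    spread, matching the magnitude range such watches report.
    """

    seed: int = 0
    n_admitted: int = 470
    eligibility_prob: float = 0.20
    consent_prob: float = 0.55
    observation_fraction: float = 0.40  # phase mix among recruits
    start_date: Date = Date(2015, 9, 22)
    accrual_weeks: int = 30
    mean_los_days: float = 24.0  # admission-to-discharge length of stay
    los_dispersion: float = 0.45  # lognormal sigma of length of stay
    max_watch_days: int = 15
    max_elapsed_days: int = 21
    baseline_activity_log_mean: float = math.log(120.0)
    baseline_activity_log_sd: float = 0.8
    epoch_noise_log_sd: float = 0.45
    daily_trend: float = 1.0  # multiplicative per-day drift
    feedback_effect: float = 0.15  # post-baseline uplift, feedback arm only
    wear_prob: float = 0.95  # per period; ~0.81 all-four-period daily adherence
    weekend_record_prob: float = 0.25
    dropout_prob_discharge: float = 0.22
    contact_prob_followup: float = 0.62
    assessment_measure_prob: float = 0.9  # per-measure completion when assessed

    def validate(self) -> None:
        probs = {
            "eligibility_prob": self.eligibility_prob,
            "consent_prob": self.consent_prob,
            "observation_fraction": self.observation_fraction,
            "wear_prob": self.wear_prob,
            "weekend_record_prob": self.weekend_record_prob,
            "dropout_prob_discharge": self.dropout_prob_discharge,
            "contact_prob_followup": self.contact_prob_followup,
            "assessment_measure_prob": self.assessment_measure_prob,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if self.los_dispersion <= 0:
            raise ValueError("los_dispersion must be positive")
        if self.n_admitted < 0:
            raise ValueError("n_admitted must be non-negative")


def _next_weekday(d: Date) -> Date:
    while d.weekday() >= 5:
        d += timedelta(days=1)
    return d


def simulate_cohort(
    cfg: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (registry, epoch records, assessment records, watch log).

    Reproducible given ``cfg.seed``; all four frames use the same CSV
    dialects as the real-data readers, so the simulator doubles as the
    fixture generator for every analytic.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    registry_rows: list[dict] = []
    epoch_rows: list[dict] = []
    assess_rows: list[dict] = []
    log_rows: list[dict] = []

    n_recruited = 0
    for k in range(cfg.n_admitted):
        admitted = cfg.start_date + timedelta(
            days=int(rng.integers(0, cfg.accrual_weeks * 7))
        )
        eligible = rng.random() < cfg.eligibility_prob
        consented = eligible and (rng.random() < cfg.consent_prob)
        if not consented:
            continue
        n_recruited += 1
        pid = f"P{1000 + n_recruited}"
        phase = (
            Phase.OBSERVATION
            if rng.random() < cfg.observation_fraction
            else Phase.RCT
        )
        if phase is Phase.OBSERVATION:
            group = Group.OBSERVATION
        else:
            group = Group.FEEDBACK if rng.random() < 0.5 else Group.NO_FEEDBACK

        registration = admitted + timedelta(days=int(rng.integers(1, 10)))
        start = _next_weekday(registration + timedelta(days=1))
        los = int(round(float(rng.lognormal(
            math.log(cfg.mean_los_days), cfg.los_dispersion
        ))))
        discharge = admitted + timedelta(days=max(los, 2))

        level = float(rng.lognormal(cfg.baseline_activity_log_mean, cfg.baseline_activity_log_sd))
        uplift = 1.0 + (cfg.feedback_effect if group is Group.FEEDBACK else 0.0)

        watch_days = 0
        day = start
        last_day = start
        while (
            watch_days < cfg.max_watch_days
            and (day - start).days < cfg.max_elapsed_days
            and day <= discharge
        ):
            is_weekday = day.weekday() < 5
            record_today = is_weekday or (rng.random() < cfg.weekend_record_prob)
            if record_today:
                day_factor = cfg.daily_trend ** watch_days
                effect = uplift if watch_days >= 1 else 1.0
                any_worn = False
                for period, weight in PERIOD_WEIGHTS.items():
                    if rng.random() >= cfg.wear_prob:
                        continue
                    noise = float(rng.lognormal(0.0, cfg.epoch_noise_log_sd))
                    score = level * weight / 4.5 * day_factor * effect * noise
                    epoch_rows.append({
                        "patient_id": pid, "date": day, "period": period,
                        "activity_score": round(score, 3),
                        "worn": True, "worn_fraction": 1.0,
                    })
                    any_worn = True
                if any_worn:
                    log_rows.append({
                        "watch_id": f"W{(n_recruited % 12) + 1:02d}",
                        "patient_id": pid, "date": day, "action": "distributed",
                        "file_name": "",
                    })
                    log_rows.append({
                        "watch_id": f"W{(n_recruited % 12) + 1:02d}",
                        "patient_id": pid, "date": day, "action": "downloaded",
                        "file_name": f"{pid}_{day.isoformat()}.csv",
                    })
            if is_weekday and record_today:
                watch_days += 1
                last_day = day
            day += timedelta(days=1)

        dropped = rng.random() < cfg.dropout_prob_discharge
        contacted = (not dropped) and (rng.random() < cfg.contact_prob_followup)

        registry_rows.append({
            "id": pid, "phase": phase.value, "group": group.value,
            "age": int(rng.integers(40, 76)),
            "sex": "male" if rng.random() < 0.7 else "female",
            "affected_side": "left" if rng.random() < 0.6 else "right",
            "stroke_date": admitted - timedelta(days=int(rng.integers(5, 120))),
            "admission_date": admitted,
            "registration_date": registration,
            "intervention_start": start,
            "discharge_date": discharge,
        })

        timepoints = [("baseline", True), ("discharge", not dropped), ("followup_3m", contacted)]
        for tp, assessed in timepoints:
            if tp == "followup_3m":
                measures = FOLLOWUP_MEASURES
            else:
                measures = PERFORMANCE_MEASURES + SELF_REPORT_MEASURES
            for m in measures:
                done = assessed and (rng.random() < cfg.assessment_measure_prob)
                assess_rows.append({
                    "patient_id": pid, "timepoint": tp, "measure": m,
                    "completed": done,
                })

    registry = pd.DataFrame(registry_rows, columns=[
        "id", "phase", "group", "age", "sex", "affected_side", "stroke_date",
        "admission_date", "registration_date", "intervention_start", "discharge_date",
    ])
    epochs = pd.DataFrame(epoch_rows, columns=[
        "patient_id", "date", "period", "activity_score", "worn", "worn_fraction",
    ])
    assessments = pd.DataFrame(assess_rows, columns=[
        "patient_id", "timepoint", "measure", "completed",
    ])
    watch_log = pd.DataFrame(log_rows, columns=[
        "watch_id", "patient_id", "date", "action", "file_name",
    ])
    return registry, epochs, assessments, watch_log


def simulate_accel_trace(
    level: float,
    window: EpochWindow,
    worn_pattern: Sequence[tuple[float, float]] | None = None,
    seed: int = 0,
    sample_rate_hz: float = 5.0,
    scoring: ScoringConfig | None = None,
    wear: WearConfig | None = None,
) -> list[AccelSample]:
    """Synthesize a tri-axial trace whose activity score matches ``level``.

    ``worn_pattern`` lists half-open (start_s, end_s) stretches — in seconds
    since midnight — during which the watch is on the wrist; outside them the
    trace is perfectly stationary (zero variance).  Movement is injected as
    rectangular bursts of known amplitude spread evenly over the worn
    stretches, so the integral of the documented score formula lands on
    ``level`` to within the burst-quantisation error (well inside 5%).
    A zero level yields a fully stationary trace.
    """
    if level < 0:
        raise ValueError("level must be non-negative")
    scoring = scoring or ScoringConfig()
    wear = wear or WearConfig()

    start_s = window.start.hour * 3600 + window.start.minute * 60
    end_s = window.end.hour * 3600 + window.end.minute * 60
    dt = 1.0 / sample_rate_hz
    t = np.arange(start_s, end_s, dt)
    n = t.size
    az = np.ones(n)  # resting flat: gravity on z

    if worn_pattern is None:
        worn_pattern = [(start_s, end_s)]
    worn_mask = np.zeros(n, dtype=bool)
    for s0, s1 in worn_pattern:
        worn_mask |= (t >= s0) & (t < s1)

    if level > 0 and worn_mask.any():
        worn_idx = np.flatnonzero(worn_mask)
        # Amplitude chosen comfortably above the dead-band; burst count sets the score.
        amp = max(4.0 * scoring.dead_band, 0.25)
        n_bursts = max(1, int(round(level / (amp * dt))))
        if n_bursts > worn_idx.size:
            n_bursts = worn_idx.size
            amp = level / (n_bursts * dt)
        chosen = worn_idx[np.linspace(0, worn_idx.size - 1, n_bursts).astype(int)]
        chosen = np.unique(chosen)
        # Re-balance amplitude for the exact burst count after deduplication;
        # bursts point away from gravity so the rectified deviation equals amp.
        amp = max(level / (chosen.size * dt), scoring.dead_band)
        az[chosen] += amp

    return [AccelSample(float(tt), 0.0, 0.0, float(a)) for tt, a in zip(t, az)]
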