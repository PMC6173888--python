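"""Feasibility analytics: flow rates, adherence, exceedance, activity summaries.

All metrics operate on two tidy frames:

* epoch records — one row per (patient, date, period) with ``activity_score``,
  ``worn`` and ``worn_fraction`` columns;
* a registry — one row per patient with ``id``, ``group``,
  ``intervention_start`` and (optionally) ``discharge_date``.

Daily activity totals use periods 1-4 only (08:00-16:00); the final 1-hour
period is excluded because its duration varies with battery life.  A
post-baseline day *exceeds baseline* when its total strictly exceeds the
total on intervention day 1.  "Expected" days are the weekdays from a
patient's first watch day to their last trial day; "actual" days are the days
with recorded data, which weekend recording can push above the expected
count.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as Date
from datetime import timedelta
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FlowCounts",
    "DailyTotal",
    "ANALYSIS_PERIODS",
    "PERFORMANCE_MEASURES",
    "SELF_REPORT_MEASURES",
    "FOLLOWUP_MEASURES",
    "adherence_rate",
    "exceedance_rate",
    "daily_total",
    "daily_totals",
    "exceedance",
    "exceedance_table",
    "adherence_table",
    "flow_rates",
    "completion_table",
    "activity_summary",
    "delta_metrics",
    "weekday_count",
]

#: Periods entering daily totals: 1-4, i.e. 08:00-16:00.
ANALYSIS_PERIODS = (1, 2, 3, 4)

PERFORMANCE_MEASURES = ("grip_left", "grip_right", "walk_10m", "moca", "barthel")
SELF_REPORT_MEASURES = ("fss", "vaf_s", "eq5d5l", "rmi", "whodas")
FOLLOWUP_MEASURES = ("rmi", "whodas", "eq5d5l")


# ---------------------------------------------------------------------------
# Flow counts and rates


@dataclass(frozen=True)
class FlowCounts:
    """Participant flow through the trial (both phases pooled)."""

    admitted: int
    recruited: int
    valid: int
    completed_discharge: int
    completed_followup: int
    dropouts_post_baseline: int = 0

    def __post_init__(self) -> None:
        if min(self.admitted, self.recruited, self.valid, self.completed_discharge,
               self.completed_followup, self.dropouts_post_baseline) < 0:
            raise ValueError("flow counts must be non-negative")
        if not (self.completed_followup <= self.completed_discharge <= self.valid <= self.recruited <= self.admitted):
            raise ValueError(
                "flow counts must satisfy followup <= discharge <= valid <= recruited <= admitted"
            )


def _pct(numerator: float, denominator: float) -> int:
    """Integer percent, round-half-up; 0 when the denominator is 0."""
    if denominator == 0:
        return 0
    return int(np.floor(100.0 * numerator / denominator + 0.5))


def adherence_rate(days_worn: int, base_days: int, decimals: int = 1) -> float:
    """Days worn divided by a denominator of days, as percent (1 dp default).

    The denominator is either the expected weekday count or the recorded-day
    count; published tables mix both bases, so the base is the caller's choice.
    """
    if base_days == 0:
        return 0.0
    return round(100.0 * days_worn / base_days, decimals)


def exceedance_rate(days_exceeding: int, base_days: int, decimals: int = 1) -> float:
    """Days exceeding baseline divided by expected or actual days, as percent."""
    return adherence_rate(days_exceeding, base_days, decimals)


def flow_rates(fc: FlowCounts) -> dict[str, int]:
    """Recruitment and retention percentages, as integer percent.

    recruitment            recruited / admitted
    retention_discharge    discharge-complete / valid
    retention_followup     follow-up-complete / valid
    followup_among_discharged  follow-up-complete / discharge-complete
    """
    return {
        "recruitment": _pct(fc.recruited, fc.admitted),
        "retention_discharge": _pct(fc.completed_discharge, fc.valid),
        "retention_followup": _pct(fc.completed_followup, fc.valid),
        "followup_among_discharged": _pct(fc.completed_followup, fc.completed_discharge),
    }


# ---------------------------------------------------------------------------
# Daily totals and exceedance


class DailyTotal(NamedTuple):
    total: float
    n_periods: int  # analysis periods (1-4) present
    missing: bool   # no analysis-period record at all
    partial: bool   # some but not all analysis periods present


def daily_total(day_records: pd.DataFrame | Mapping[int, float]) -> DailyTotal:
    """Total AS for one patient-day over periods 1-4; period 5 is excluded."""
    if isinstance(day_records, pd.DataFrame):
        scores = dict(zip(day_records["period"], day_records["activity_score"]))
    else:
        scores = dict(day_records)
    present = [p for p in ANALYSIS_PERIODS if p in scores]
    total = float(sum(scores[p] for p in present))
    n = len(present)
    return DailyTotal(total, n, missing=n == 0, partial=0 < n < len(ANALYSIS_PERIODS))


def daily_totals(records: pd.DataFrame) -> pd.DataFrame:
    """Per patient-day totals over periods 1-4, with completeness flags."""
    sub = records[records["period"].isin(ANALYSIS_PERIODS)]
    grouped = sub.groupby(["patient_id", "date"], sort=True).agg(
        total=("activity_score", "sum"), n_periods=("period", "nunique")
    )
    out = grouped.reset_index()
    out["partial"] = out["n_periods"] < len(ANALYSIS_PERIODS)
    return out


def exceedance(totals: Sequence[float]) -> tuple[int, int]:
    """(days exceeding baseline, post-baseline days) for one patient.

    ``totals`` is the chronologically ordered sequence of recorded daily
    totals; the first entry is the baseline (intervention day 1).  Exceeding
    is strict, so the baseline day can never count in the numerator.
    """
    totals = list(totals)
    if not totals:
        raise ValueError("patient has no recorded baseline day")
    baseline = totals[0]
    post = totals[1:]
    return sum(t > baseline for t in post), len(post)


def weekday_count(start: Date, end: Date) -> int:
    """Number of Mon-Fri days in [start, end], inclusive."""
    if end < start:
        return 0
    return int(np.busday_count(start, end + timedelta(days=1)))


def _trial_span(registry: pd.DataFrame, records: pd.DataFrame) -> pd.DataFrame:
    """Per-patient (start, end) of the intervention.

    The end is the discharge date when recorded, else the last recorded watch
    day (length of stay estimated from the smartwatch data, as when discharge
    dates are missing).
    """
    last_rec = records.groupby("patient_id")["date"].max()
    reg = registry.set_index("id")
    spans = []
    for pid, row in reg.iterrows():
        start = row["intervention_start"]
        end = row.get("discharge_date")
        if end is None or (isinstance(end, float) and np.isnan(end)) or pd.isna(end):
            end = last_rec.get(pid)
        if pd.isna(start) or end is None or pd.isna(end):
            continue
        spans.append({"patient_id": pid, "group": row["group"],
                      "start": start, "end": max(start, end)})
    return pd.DataFrame(spans, columns=["patient_id", "group", "start", "end"])


def exceedance_table(records: pd.DataFrame, registry: pd.DataFrame) -> pd.DataFrame:
    """Per-group exceedance counts and rates on both denominators.

    Columns: expected_days (weekdays spanned), actual_days (recorded days),
    days_exceeding_baseline, rate_vs_expected, rate_vs_actual (percent, 1 dp).
    Patients with no recorded baseline day are excluded.
    """
    totals = daily_totals(records)
    spans = _trial_span(registry, records)
    rows = []
    for group, span_g in spans.groupby("group", sort=True):
        expected = actual = exceed = 0
        for _, srow in span_g.iterrows():
            pt = totals[totals["patient_id"] == srow["patient_id"]].sort_values("date")
            if pt.empty:
                continue
            expected += weekday_count(srow["start"], srow["end"])
            actual += len(pt)
            n_ex, _ = exceedance(pt["total"].tolist())
            exceed += n_ex
        rows.append({
            "group": group,
            "expected_days": expected,
            "actual_days": actual,
            "days_exceeding_baseline": exceed,
            "rate_vs_expected": exceedance_rate(exceed, expected),
            "rate_vs_actual": exceedance_rate(exceed, actual),
        })
    return pd.DataFrame(rows, columns=[
        "group", "expected_days", "actual_days", "days_exceeding_baseline",
        "rate_vs_expected", "rate_vs_actual",
    ]).set_index("group")


# ---------------------------------------------------------------------------
# Adherence


def adherence_table(records: pd.DataFrame, registry: pd.DataFrame) -> pd.DataFrame:
    """Per-group watch-wearing adherence, Table-5 style.

    A recorded day's category is the number of analysis periods (1-4) worn
    that day; each recorded day falls in exactly one of {4, 3, 2, 1, 0}.
    Percentages are reported on both denominators — expected weekdays and
    recorded days — because the two bases answer different questions (and
    weekend recording can push recorded days above the weekday count,
    yielding rates above 100%).
    """
    spans = _trial_span(registry, records)
    sub = records[records["period"].isin(ANALYSIS_PERIODS)]
    worn_per_day = (
        sub.groupby(["patient_id", "date"])["worn"].sum().rename("n_worn").reset_index()
    )
    recorded_days = (
        records.groupby(["patient_id", "date"]).size().rename("n_rec").reset_index()
    )
    per_day = recorded_days.merge(worn_per_day, on=["patient_id", "date"], how="left")
    per_day["n_worn"] = per_day["n_worn"].fillna(0).astype(int)

    rows = []
    for group, span_g in spans.groupby("group", sort=True):
        pids = set(span_g["patient_id"])
        total_days = int(sum((r["end"] - r["start"]).days + 1 for _, r in span_g.iterrows()))
        expected = int(sum(weekday_count(r["start"], r["end"]) for _, r in span_g.iterrows()))
        days_g = per_day[per_day["patient_id"].isin(pids)]
        actual = len(days_g)
        cat = days_g["n_worn"].value_counts()
        counts = {k: int(cat.get(k, 0)) for k in (4, 3, 2, 1)}
        ge1 = sum(counts.values())
        row = {
            "group": group,
            "total_days": total_days,
            "expected_days": expected,
            "actual_days": actual,
            "worn_4": counts[4],
            "worn_3": counts[3],
            "worn_2": counts[2],
            "worn_1": counts[1],
            "worn_ge1": ge1,
        }
        for key in ("worn_4", "worn_3", "worn_2", "worn_1", "worn_ge1"):
            row[f"{key}_pct_expected"] = adherence_rate(row[key], expected)
            row[f"{key}_pct_actual"] = adherence_rate(row[key], actual)
        rows.append(row)
    columns = ["group", "total_days", "expected_days", "actual_days",
               "worn_4", "worn_3", "worn_2", "worn_1", "worn_ge1"]
    columns += [f"{k}_pct_{b}" for k in ("worn_4", "worn_3", "worn_2", "worn_1", "worn_ge1")
                for b in ("expected", "actual")]
    return pd.DataFrame(rows, columns=columns).set_index("group")


# ---------------------------------------------------------------------------
# Assessment completion


def completion_table(
    assessments: pd.DataFrame,
    registry: pd.DataFrame,
    measure_sets: Mapping[str, tuple[tuple[str, ...], tuple[str, ...]]] | None = None,
) -> pd.DataFrame:
    """Completion of outcome measures per group, timepoint and measure set.

    ``assessments`` has columns patient_id, timepoint, measure, completed.
    Each measure set maps name -> (timepoints, measures).  For every
    (group, timepoint, set): the number of patients completing *all* measures
    in the set, and the min-max percent of the group completing each
    individual measure (integer percent of group size).
    """
    if measure_sets is None:
        measure_sets = {
            "performance": (("baseline", "discharge"), PERFORMANCE_MEASURES),
            "self_report": (("baseline", "discharge"), SELF_REPORT_MEASURES),
            "followup": (("followup_3m",), FOLLOWUP_MEASURES),
        }
    rows = []
    for group, reg_g in registry.groupby("group", sort=True):
        pids = list(reg_g["id"])
        n_group = len(pids)
        sub = assessments[assessments["patient_id"].isin(pids)]
        for set_name, (timepoints, measures) in measure_sets.items():
            for tp in timepoints:
                tp_sub = sub[(sub["timepoint"] == tp) & (sub["measure"].isin(measures))]
                done = tp_sub[tp_sub["completed"]]
                per_measure_pct = [
                    _pct(done[done["measure"] == m]["patient_id"].nunique(), n_group)
                    for m in measures
                ]
                by_patient = done.groupby("patient_id")["measure"].nunique()
                n_full = int((by_patient == len(measures)).sum())
                rows.append({
                    "group": group,
                    "measure_set": set_name,
                    "timepoint": tp,
                    "n_group": n_group,
                    "n_full": n_full,
                    "range_min_pct": min(per_measure_pct) if per_measure_pct else 0,
                    "range_max_pct": max(per_measure_pct) if per_measure_pct else 0,
                })
    return pd.DataFrame(rows).set_index(["group", "measure_set", "timepoint"])


# ---------------------------------------------------------------------------
# Activity summaries and per-patient deltas


def intervention_day_index(date: Date, start: Date) -> int | None:
    """Weekday index within the intervention (day 1 = first watch day).

    Weekend dates carry no index and return None.
    """
    if date.weekday() >= 5:
        return None
    if date < start:
        return None
    return int(np.busday_count(start, date)) + 1


def activity_summary(
    records: pd.DataFrame,
    registry: pd.DataFrame,
    day_indices: Sequence[int] = (1, 5, 10, 15),
) -> pd.DataFrame:
    """Median <Q1-Q3> [n] of daily total AS per group at selected watch days.

    Quantiles use the inclusive linear-interpolation convention.
    """
    totals = daily_totals(records)
    reg = registry.set_index("id")
    totals = totals[totals["patient_id"].isin(reg.index)]
    starts = reg["intervention_start"]
    groups = reg["group"]
    day_idx = [
        intervention_day_index(d, starts.loc[pid])
        for pid, d in zip(totals["patient_id"], totals["date"])
    ]
    totals = totals.assign(day_index=day_idx, group=groups.loc[totals["patient_id"]].values)
    totals = totals.dropna(subset=["day_index"])
    rows = []
    for (group, di), sub in totals.groupby(["group", "day_index"], sort=True):
        if int(di) not in day_indices:
            continue
        vals = sub["total"].to_numpy()
        q1, med, q3 = np.percentile(vals, [25, 50, 75], method="linear")
        rows.append({
            "group": group, "day_index": int(di),
            "median": float(med), "q1": float(q1), "q3": float(q3), "n": len(vals),
        })
    return pd.DataFrame(rows, columns=["group", "day_index", "median", "q1", "q3", "n"]).set_index(
        ["group", "day_index"]
    )


def delta_metrics(patient_records: pd.DataFrame, intervention_start: Date) -> pd.DataFrame:
    """Per-period AS deltas for one patient: from baseline and from previous day.

    Returns a frame indexed by (period, day_index) with columns ``as_score``,
    ``delta_baseline`` (AS - BAS) and ``delta_previous`` (AS - comparable
    previous weekday's AS); missing days propagate as NaN.
    """
    sub = patient_records[patient_records["period"].isin(ANALYSIS_PERIODS)].copy()
    sub["day_index"] = [
        intervention_day_index(d, intervention_start) for d in sub["date"]
    ]
    sub = sub.dropna(subset=["day_index"])
    sub["day_index"] = sub["day_index"].astype(int)
    max_day = int(sub["day_index"].max()) if len(sub) else 0
    frames = []
    for period in ANALYSIS_PERIODS:
        series = (
            sub[sub["period"] == period]
            .set_index("day_index")["activity_score"]
            .reindex(range(1, max_day + 1))
        )
        bas = series.get(1, np.nan)
        frames.append(pd.DataFrame({
            "period": period,
            "day_index": series.index,
            "as_score": series.values,
            "delta_baseline": series.values - bas,
            "delta_previous": series.values - series.shift(1).values,
        }))
    if not frames:
        return pd.DataFrame(
            columns=["period", "day_index", "as_score", "delta_baseline", "delta_previous"]
        ).set_index(["period", "day_index"])
    return pd.concat(frames, ignore_index=True).set_index(["period", "day_index"])
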