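"""CSV dialects, watch-log handling and file-level quality control.

No on-watch binary format exists; a set of documented UTF-8 CSV dialects
(ISO-8601 dates, local clock times) is the canonical interchange format:

* epoch records   — ``patient_id,date,period,activity_score,worn,worn_fraction``
* raw traces      — ``t,ax,ay,az`` (epoch-seconds or ISO-8601 timestamps; g)
* registry        — ``id,phase,group,age,sex,affected_side,stroke_date,``
                    ``admission_date,registration_date,intervention_start,discharge_date``
* assessments     — ``patient_id,timepoint,measure,completed``
* watch log       — ``watch_id,patient_id,date,action,file_name``

Readers are tolerant: unknown extra columns are preserved with a warning; a
missing required column raises a structured error naming it.  ``write`` then
``read`` is the identity on valid files.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from datetime import date as Date
from datetime import datetime
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MissingColumnError",
    "WatchLogEntry",
    "QCReport",
    "read_epochs", "write_epochs",
    "read_trace", "write_trace",
    "read_registry", "write_registry",
    "read_assessments", "write_assessments",
    "read_watch_log", "write_watch_log",
    "qc_files",
]


class MissingColumnError(ValueError):
    """A required header column is absent from an input file."""

    def __init__(self, column: str, path: str | Path):
        self.column = column
        self.path = str(path)
        super().__init__(f"{path}: missing required column '{column}'")


def _read(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in required:
        if col not in df.columns:
            raise MissingColumnError(col, path)
    extra = [c for c in df.columns if c not in required]
    if extra:
        warnings.warn(f"{path}: preserving unknown columns {extra}", stacklevel=3)
    return df


def _parse_date(value) -> Date | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    if isinstance(value, Date) and not isinstance(value, datetime):
        return value
    return datetime.fromisoformat(str(value)).date()


def _date_col(df: pd.DataFrame, col: str) -> None:
    if col in df.columns:
        df[col] = [_parse_date(v) for v in df[col]]


EPOCH_COLUMNS = ["patient_id", "date", "period", "activity_score", "worn", "worn_fraction"]
TRACE_COLUMNS = ["t", "ax", "ay", "az"]
REGISTRY_COLUMNS = [
    "id", "phase", "group", "age", "sex", "affected_side", "stroke_date",
    "admission_date", "registration_date", "intervention_start", "discharge_date",
]
ASSESSMENT_COLUMNS = ["patient_id", "timepoint", "measure", "completed"]
WATCH_LOG_COLUMNS = ["watch_id", "patient_id", "date", "action", "file_name"]


def read_epochs(path: str | Path) -> pd.DataFrame:
    df = _read(path, EPOCH_COLUMNS)
    _date_col(df, "date")
    df["period"] = df["period"].astype(int)
    df["worn"] = df["worn"].astype(bool)
    return df


def write_epochs(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_trace(path: str | Path) -> pd.DataFrame:
    """Raw trace; ISO-8601 timestamps are converted to seconds since midnight."""
    df = _read(path, TRACE_COLUMNS)
    try:
        df["t"] = df["t"].astype(float)
    except (TypeError, ValueError):
        ts = [datetime.fromisoformat(str(v)) for v in df["t"]]
        df["t"] = [
            (v - v.replace(hour=0, minute=0, second=0, microsecond=0)).total_seconds()
            for v in ts
        ]
    return df


def write_trace(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_registry(path: str | Path) -> pd.DataFrame:
    df = _read(path, REGISTRY_COLUMNS)
    for col in ("stroke_date", "admission_date", "registration_date",
                "intervention_start", "discharge_date"):
        _date_col(df, col)
    return df


def write_registry(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_assessments(path: str | Path) -> pd.DataFrame:
    df = _read(path, ASSESSMENT_COLUMNS)
    df["completed"] = df["completed"].astype(bool)
    return df


def write_assessments(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_watch_log(path: str | Path) -> pd.DataFrame:
    df = _read(path, WATCH_LOG_COLUMNS)
    _date_col(df, "date")
    df["file_name"] = df["file_name"].fillna("")
    return df


def write_watch_log(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# File-level quality control


@dataclass(frozen=True)
class WatchLogEntry:
    watch_id: str
    patient_id: str
    date: Date
    action: str  # distributed | downloaded | recharged
    file_name: str = ""


@dataclass
class QCReport:
    """Outcome of a download-folder audit.

    duplicate_groups: sets of files carrying an identical payload for the
    same (patient, date) — the daily-download failure mode.
    mislabelled: files whose embedded patient id is not in the registry.
    unconsolidated: patients with data but no single final file spanning
    their whole intervention.
    unparseable: files that could not be read (never fatal).
    """

    duplicate_groups: list[tuple[str, ...]] = field(default_factory=list)
    mislabelled: list[str] = field(default_factory=list)
    unconsolidated: list[str] = field(default_factory=list)
    unparseable: list[str] = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return not (self.duplicate_groups or self.mislabelled
                    or self.unconsolidated or self.unparseable)


def qc_files(paths: Iterable[str | Path], registry: pd.DataFrame) -> QCReport:
    """Audit a set of per-patient epoch CSV files against the registry.

    Duplicates are detected by hashing each file's per-(patient, date)
    payload; a consolidated patient has one file covering every date that
    patient has data for (the end-of-intervention full download).
    """
    report = QCReport()
    known_ids = set(registry["id"])
    payload_hash: dict[tuple[str, Date, str], list[str]] = {}
    file_dates: dict[str, tuple[set[str], tuple[Date, Date]]] = {}
    patient_dates: dict[str, set[Date]] = {}

    for path in paths:
        path = Path(path)
        try:
            df = read_epochs(path)
        except Exception:
            report.unparseable.append(path.name)
            continue
        if df.empty:
            report.unparseable.append(path.name)
            continue
        pids = set(df["patient_id"].astype(str))
        for pid in sorted(pids - known_ids):
            report.mislabelled.append(path.name)
            break
        for (pid, date), day_df in df.groupby(["patient_id", "date"]):
            pid = str(pid)
            payload = day_df[EPOCH_COLUMNS].sort_values("period").to_csv(index=False)
            digest = hashlib.sha256(payload.encode()).hexdigest()
            payload_hash.setdefault((pid, date, digest), []).append(path.name)
            patient_dates.setdefault(pid, set()).add(date)
        file_dates[path.name] = (
            pids, (df["date"].min(), df["date"].max())
        )

    groups = {tuple(sorted(files)) for files in payload_hash.values() if len(files) > 1}
    report.duplicate_groups.extend(sorted(groups))

    for pid in sorted(patient_dates):
        if pid not in known_ids:
            continue
        dates = patient_dates[pid]
        # A file spanning [min, max] of the patient's dates counts as the
        # final whole-intervention download.
        consolidated = any(
            pid in pids and lo <= min(dates) and hi >= max(dates)
            for name, (pids, (lo, hi)) in file_dates.items()
        )
        if not consolidated:
            report.unconsolidated.append(pid)
    return report
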