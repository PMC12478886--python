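"""Read, validate, filter, and write person-day time-diary microdata.

The canonical table has one row per diary day with columns

    age, year, cohort_year (optional), gender, minutes_alone, weight,
    day_of_week, holiday

``cohort_year`` must satisfy the Lexis identity ``cohort_year = year - age``;
if absent it is derived. Rows violating any record invariant (identity,
outcome outside [0, 1440], non-positive or missing weight) are rejected and
reported, never silently fixed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, field_validator, model_validator

from .errors import SchemaError

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "age",
    "year",
    "gender",
    "minutes_alone",
    "weight",
    "day_of_week",
    "holiday",
)
OPTIONAL_COLUMNS = ("cohort_year",)

DAY_LEVELS = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")
GENDER_LEVELS = ("female", "male")

_DAY_ALIASES = {d.lower(): d for d in DAY_LEVELS}
_DAY_ALIASES.update(
    {
        "monday": "Mon",
        "tuesday": "Tue",
        "wednesday": "Wed",
        "thursday": "Thu",
        "friday": "Fri",
        "saturday": "Sat",
        "sunday": "Sun",
    }
)

_TRUE = {"true", "1", "yes", "y", "t"}
_FALSE = {"false", "0", "no", "n", "f"}

MINUTES_PER_DAY = 1440.0


@dataclass
class ValidationReport:
    """Row-level outcome of microdata validation."""

    n_rows: int = 0
    n_accepted: int = 0
    rejections: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejections)

    def summary(self) -> str:
        return (
            f"{self.n_accepted}/{self.n_rows} rows accepted, "
            f"{self.n_rejected} rejected"
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_rows": self.n_rows,
            "n_accepted": self.n_accepted,
            "n_rejected": self.n_rejected,
            "rejections": [
                {"row": int(i), "reason": r} for i, r in self.rejections
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))


class FilterSpec(BaseModel):
    """Analysis-sample filter: closed intervals plus optional strata.

    Defaults reproduce the primary analysis window (ages 15-79 inclusive,
    diary years 2003-2022 inclusive). ``day_subset`` supports the
    weekday/weekend sensitivity analysis, ``year_range=(2003, 2019)`` the
    pre-pandemic one.
    """

    age_range: tuple[int, int] = (15, 79)
    year_range: tuple[int, int] = (2003, 2022)
    day_subset: Optional[tuple[str, ...]] = None
    gender: Optional[str] = None

    @field_validator("age_range", "year_range")
    @classmethod
    def _interval_nonempty(cls, v: tuple[int, int]) -> tuple[int, int]:
        if v[0] > v[1]:
            raise ValueError(f"empty interval {v}")
        return v

    @field_validator("day_subset")
    @classmethod
    def _days_valid(cls, v):
        if v is None:
            return v
        if len(v) == 0:
            raise ValueError("day_subset must be non-empty when present")
        bad = [d for d in v if d not in DAY_LEVELS]
        if bad:
            raise ValueError(f"unknown day-of-week levels {bad}")
        return tuple(v)

    @field_validator("gender")
    @classmethod
    def _gender_valid(cls, v):
        if v is not None and v not in GENDER_LEVELS:
            raise ValueError(f"gender must be one of {GENDER_LEVELS}")
        return v


def _normalize_day(value) -> Optional[str]:
    key = str(value).strip().lower()
    return _DAY_ALIASES.get(key)


def _normalize_bool(value) -> Optional[bool]:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    key = str(value).strip().lower()
    if key in _TRUE:
        return True
    if key in _FALSE:
        return False
    return None


def validate_microdata(df: pd.DataFrame) -> tuple[pd.DataFrame, ValidationReport]:
    """Validate a raw microdata frame against the record invariants.

    Returns the accepted rows (canonical dtypes, original row order) and a
    report listing every rejection with its 0-based input row index.
    """
    df = df.copy()
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    report = ValidationReport(n_rows=len(df))
    reasons = pd.Series([None] * len(df), index=df.index, dtype=object)

    def flag(mask: pd.Series, reason: str) -> None:
        new = mask & reasons.isna()
        reasons[new] = reason

    age = pd.to_numeric(df["age"], errors="coerce")
    year = pd.to_numeric(df["year"], errors="coerce")
    minutes = pd.to_numeric(df["minutes_alone"], errors="coerce")
    weight = pd.to_numeric(df["weight"], errors="coerce")

    flag(age.isna() | (age != age.round()), "age missing or non-integer")
    flag(year.isna() | (year != year.round()), "year missing or non-integer")
    flag(minutes.isna(), "minutes_alone missing or non-numeric")
    flag(
        minutes.notna() & ((minutes < 0) | (minutes > MINUTES_PER_DAY)),
        "minutes_alone outside [0, 1440]",
    )
    flag(weight.isna(), "weight missing or non-numeric")
    flag(weight.notna() & (weight <= 0), "non-positive weight")

    gender = df["gender"].astype(str).str.strip().str.lower()
    flag(~gender.isin(GENDER_LEVELS), "unknown gender level")

    day = df["day_of_week"].map(_normalize_day)
    flag(day.isna(), "unknown day_of_week level")

    holiday = df["holiday"].map(_normalize_bool)
    flag(holiday.isna(), "holiday not interpretable as boolean")

    derived_cohort = year - age
    if "cohort_year" in df.columns:
        cohort = pd.to_numeric(df["cohort_year"], errors="coerce")
        flag(cohort.isna(), "cohort_year missing or non-numeric")
        flag(
            cohort.notna() & (cohort != derived_cohort),
            "cohort identity violated (cohort_year != year - age)",
        )
    else:
        cohort = derived_cohort

    bad = reasons.notna()
    for idx in df.index[bad]:
        report.rejections.append((int(idx), str(reasons[idx])))

    keep = ~bad
    clean = pd.DataFrame(
        {
            "age": age[keep].astype(int),
            "year": year[keep].astype(int),
            "cohort_year": cohort[keep].astype(int),
            "gender": gender[keep],
            "minutes_alone": minutes[keep].astype(float),
            "weight": weight[keep].astype(float),
            "day_of_week": day[keep],
            "holiday": holiday[keep].astype(bool),
        },
        index=df.index[keep],
    )
    report.n_accepted = len(clean)
    logger.info("microdata validation: %s", report.summary())
    return clean, report


def read_microdata(
    path: str | Path,
    delimiter: str = ",",
    report_path: str | Path | None = None,
) -> tuple[pd.DataFrame, ValidationReport]:
    """Read a delimited microdata file and validate every row.

    Parameters
    ----------
    path : file path
        Delimited text file with a header row (case-insensitive names).
    delimiter : str
        Field separator; pass ``"\\t"`` for tab-separated extracts.
    report_path : optional path
        If given, the validation report is also written as a JSON sidecar.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep=delimiter)
    table, report = validate_microdata(raw)
    if report_path is not None:
        report.to_json(report_path)
    return table, report


def write_microdata(table: pd.DataFrame, path: str | Path, delimiter: str = ",") -> None:
    """Write a validated table back to delimited text (round-trip safe)."""
    cols = [c for c in (*REQUIRED_COLUMNS, *OPTIONAL_COLUMNS) if c in table.columns]
    ordered = ["age", "year", "cohort_year", "gender", "minutes_alone",
               "weight", "day_of_week", "holiday"]
    cols = [c for c in ordered if c in table.columns]
    table[cols].to_csv(path, sep=delimiter, index=False)


def filter_records(table: pd.DataFrame, spec: FilterSpec) -> pd.DataFrame:
    """Apply the analysis-sample filter; idempotent; closed intervals."""
    mask = (
        table["age"].between(*spec.age_range)
        & table["year"].between(*spec.year_range)
    )
    if spec.day_subset is not None:
        mask &= table["day_of_week"].isin(spec.day_subset)
    if spec.gender is not None:
        mask &= table["gender"] == spec.gender
    out = table[mask]
    logger.info("filter: retained %d of %d records", len(out), len(table))
    if len(out) == 0:
        logger.warning("filter produced an empty table")
    return out
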