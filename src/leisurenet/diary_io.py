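"""Diary ingestion, inclusion/exclusion filtering, SWB grouping and
2-mode incidence construction.

The canonical diary file is a long-format CSV with one row per
(person, day type, activity): see ``simulate.DIARY_COLUMNS``. Subjective
well-being (SWB, 1-7) and health status (1-5) are scored so that *higher
is worse*; the study design keeps only the two extreme joint strata:

* ``high_swb``: SWB 1-4 **and** health 1-2,
* ``low_swb``:  SWB 5-7 **and** health 3-5,

every other score combination is excluded, which makes the two groups
disjoint by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .simulate import DIARY_COLUMNS

__all__ = [
    "SchemaError",
    "DiaryReadResult",
    "FilterReport",
    "IncidenceMatrix",
    "read_diary",
    "write_diary",
    "classify_swb",
    "assign_swb_group",
    "apply_inclusion_filters",
    "build_incidence",
]

HIGH, LOW, EXCLUDED = "high_swb", "low_swb", "excluded"

_NUMERIC = ("age", "swb_score", "health_score", "leisure_satisfaction", "minutes")
_MANDATORY = ("person_id", "day_type", "activity_code")


class SchemaError(ValueError):
    """The diary file header does not match the canonical schema."""


@dataclass
class DiaryReadResult:
    """Typed records plus a report of rows rejected during parsing."""

    records: pd.DataFrame
    rejects: pd.DataFrame  # original row values + a ``reject_reason`` column

    def __iter__(self):  # allow records, rejects = read_diary(...)
        return iter((self.records, self.rejects))


def read_diary(path: str | Path) -> DiaryReadResult:
    """Read a canonical diary CSV.

    Malformed rows (non-numeric minutes or scores, negative minutes,
    unknown day type, missing mandatory field) are collected into the
    rejects report rather than raised on or silently dropped.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in DIARY_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"diary file {path} is missing column(s): {', '.join(missing)}")
    raw = raw[list(DIARY_COLUMNS)]

    reasons = pd.Series("", index=raw.index, dtype=object)

    def flag(mask: pd.Series, reason: str) -> None:
        add = mask & (reasons == "")
        reasons[add] = reason

    for col in _MANDATORY:
        flag(raw[col].str.strip() == "", f"missing {col}")
    flag(~raw["day_type"].isin(["weekday", "weekend"]) & (raw["day_type"] != ""),
         "unknown day_type")

    numeric = {}
    for col in _NUMERIC:
        values = pd.to_numeric(raw[col].replace("", np.nan), errors="coerce")
        numeric[col] = values
        flag(values.isna() & (raw[col].str.strip() != ""), f"non-numeric {col}")
    flag(numeric["minutes"] < 0, "negative minutes")
    flag(numeric["swb_score"].notna()
         & ~numeric["swb_score"].between(1, 7), "swb_score outside 1-7")
    flag(numeric["health_score"].notna()
         & ~numeric["health_score"].between(1, 5), "health_score outside 1-5")

    bad = reasons != ""
    rejects = raw[bad].copy()
    rejects["reject_reason"] = reasons[bad]

    records = raw[~bad].copy()
    for col in _NUMERIC:
        records[col] = numeric[col][~bad]
    for col in ("age", "minutes"):
        records[col] = records[col].astype("Int64")
    for col in ("swb_score", "health_score", "leisure_satisfaction"):
        records[col] = records[col].astype("Float64")
    return DiaryReadResult(records.reset_index(drop=True), rejects.reset_index(drop=True))


def write_diary(records: pd.DataFrame, path: str | Path) -> None:
    """Write records as the canonical diary CSV."""
    records[list(DIARY_COLUMNS)].to_csv(path, index=False)


def classify_swb(swb_score: float | None, health_score: float | None) -> str:
    """Classify one respondent's joint (SWB, health) scores.

    Returns ``high_swb``, ``low_swb`` or ``excluded``; missing scores are
    excluded.
    """
    if swb_score is None or health_score is None:
        return EXCLUDED
    if pd.isna(swb_score) or pd.isna(health_score):
        return EXCLUDED
    if 1 <= swb_score <= 4 and 1 <= health_score <= 2:
        return HIGH
    if 5 <= swb_score <= 7 and 3 <= health_score <= 5:
        return LOW
    return EXCLUDED


def assign_swb_group(records: pd.DataFrame) -> pd.Series:
    """Vectorised :func:`classify_swb` over a record table."""
    swb = pd.to_numeric(records["swb_score"], errors="coerce")
    health = pd.to_numeric(records["health_score"], errors="coerce")
    out = pd.Series(EXCLUDED, index=records.index, dtype=object)
    out[swb.between(1, 4) & health.between(1, 2)] = HIGH
    out[swb.between(5, 7) & health.between(3, 5)] = LOW
    return out.rename("swb_group")


@dataclass
class FilterReport:
    """Per-rule removal counts from :func:`apply_inclusion_filters`."""

    n_input: int = 0
    n_output: int = 0
    removed_age: int = 0
    removed_duplicate: int = 0
    removed_missing: int = 0

    @property
    def n_removed(self) -> int:
        return self.removed_age + self.removed_duplicate + self.removed_missing

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(self.__dict__, indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def apply_inclusion_filters(records: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the study's inclusion/exclusion rules.

    Keeps diarists aged 10-19 inclusive, drops rows with a missing
    mandatory field or score, and removes exact duplicate
    (person_id, day_type, activity_code) rows keeping the first.
    Filters never raise; removals are tallied per rule in the report.
    """
    report = FilterReport(n_input=len(records))
    df = records.copy()

    mandatory = list(_MANDATORY) + ["age", "swb_score", "health_score", "minutes"]
    missing = df[mandatory].isna().any(axis=1)
    for col in _MANDATORY:
        missing |= df[col].astype(str).str.strip().isin(["", "nan", "<NA>"])
    report.removed_missing = int(missing.sum())
    df = df[~missing]

    age = pd.to_numeric(df["age"], errors="coerce")
    bad_age = ~age.between(10, 19)
    report.removed_age = int(bad_age.sum())
    df = df[~bad_age]

    dup = df.duplicated(subset=["person_id", "day_type", "activity_code"], keep="first")
    report.removed_duplicate = int(dup.sum())
    df = df[~dup]

    report.n_output = len(df)
    return df.reset_index(drop=True), report


@dataclass
class IncidenceMatrix:
    """Persons x activities 2-mode structure for one (group, day type).

    ``binary[i, j]`` is 1 iff person i performed activity j at least once
    on that day type; ``weights[i, j]`` is the summed minutes. Activities
    nobody performed are dropped from the column set, and persons with no
    records for the day type simply never appear as rows.
    """

    persons: list[str]
    activities: list[str]
    binary: np.ndarray
    weights: np.ndarray
    group_label: str = ""
    day_type: str = ""
    empty: bool = field(default=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.binary.shape

    def participant_counts(self) -> np.ndarray:
        """Number of distinct participants per activity column."""
        return self.binary.sum(axis=0)


def build_incidence(records: pd.DataFrame, group_label: str, day_type: str,
                    activities: Iterable[str] | None = None) -> IncidenceMatrix:
    """Build the 2-mode person x activity incidence matrix.

    ``records`` should already be filtered; rows are selected by the
    ``swb_group`` column if present (else all rows are used) and by
    ``day_type``. Passing ``activities`` fixes the candidate column
    universe (columns with zero participants are still dropped).
    """
    df = records
    if "swb_group" in df.columns:
        df = df[df["swb_group"] == group_label]
    elif "swb_score" in df.columns:
        df = df[assign_swb_group(df) == group_label]
    df = df[df["day_type"] == day_type]

    if len(df) == 0:
        return IncidenceMatrix([], [], np.zeros((0, 0)), np.zeros((0, 0)),
                               group_label, day_type, empty=True)

    minutes = pd.to_numeric(df["minutes"], errors="coerce").fillna(0.0).astype(float)
    table = (
        pd.DataFrame({"person_id": df["person_id"],
                      "activity_code": df["activity_code"],
                      "minutes": minutes.to_numpy()})
        .pivot_table(index="person_id", columns="activity_code",
                     values="minutes", aggfunc="sum", fill_value=0.0)
    )
    if activities is not None:
        keep = [a for a in activities if a in table.columns]
        table = table[keep]
    table = table.loc[:, table.sum(axis=0) > 0]  # drop zero-participant columns
    table = table.loc[table.sum(axis=1) > 0]     # and all-zero person rows

    weights = table.to_numpy(dtype=float)
    return IncidenceMatrix(
        persons=[str(p) for p in table.index],
        activities=[str(a) for a in table.columns],
        binary=(weights > 0).astype(float),
        weights=weights,
        group_label=group_label,
        day_type=day_type,
        empty=table.size == 0,
    )
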