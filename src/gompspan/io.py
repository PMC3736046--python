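"""Survival-table data model and file I/O.

The analyzed unit is a per-animal record: subject id, group label, entry age
(months, the age at which observation starts), event age (months, death or
censoring age) and an event flag (True = death observed, False =
right-censored).  Records are grouped into cohorts sharing a group label and
a single entry age.  All ages are in months throughout the package; there is
no unit conversion anywhere.

Tables are plain delimited text (CSV by default, TSV via ``delimiter``) with
the header ``subject_id,group,entry_age,event_age,event``.  Summary reports
are JSON and round-trip exactly (numeric fields at full float precision).
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .metrics import LifespanSummary

__all__ = [
    "LifespanRecord",
    "Cohort",
    "TableFormatError",
    "TableValidationError",
    "read_lifespan_table",
    "write_lifespan_table",
    "write_summary",
    "read_summary",
]

COLUMNS = ("subject_id", "group", "entry_age", "event_age", "event")

_TRUE = {"true", "t", "1", "yes", "y"}
_FALSE = {"false", "f", "0", "no", "n"}


class TableFormatError(ValueError):
    """The file is not a parsable survival table (missing columns, empty)."""


class TableValidationError(ValueError):
    """One or more rows violate record invariants; message cites row numbers."""


@dataclass(frozen=True)
class LifespanRecord:
    """One animal: entry age, event age (months), event status, group."""

    subject_id: str
    group: str
    entry_age: float
    event_age: float
    event: bool

    def __post_init__(self) -> None:
        for name in ("entry_age", "event_age"):
            value = getattr(self, name)
            if not (isinstance(value, (int, float)) and math.isfinite(value)):
                raise ValueError(f"{name} must be finite, got {value!r}")
            if value < 0:
                raise ValueError(f"{name} must be non-negative, got {value!r}")
        if self.event_age <= self.entry_age:
            raise ValueError(
                f"event_age ({self.event_age}) must exceed entry_age "
                f"({self.entry_age}) for subject {self.subject_id!r}"
            )


@dataclass(frozen=True, eq=False)
class Cohort:
    """All records of one group, sharing a single entry age."""

    group: str
    records: tuple[LifespanRecord, ...]
    entry_age: float

    def __post_init__(self) -> None:
        if len(self.records) == 0:
            raise ValueError(f"cohort {self.group!r} is empty")
        ids = set()
        for rec in self.records:
            if rec.group != self.group:
                raise ValueError(
                    f"record {rec.subject_id!r} has group {rec.group!r}, "
                    f"expected {self.group!r}"
                )
            if rec.entry_age != self.entry_age:
                raise ValueError(
                    f"record {rec.subject_id!r} has entry_age {rec.entry_age}, "
                    f"expected {self.entry_age}"
                )
            if rec.subject_id in ids:
                raise ValueError(
                    f"duplicate subject_id {rec.subject_id!r} in group {self.group!r}"
                )
            ids.add(rec.subject_id)

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        return (
            self.group == other.group
            and self.entry_age == other.entry_age
            and sorted(self.records, key=lambda r: r.subject_id)
            == sorted(other.records, key=lambda r: r.subject_id)
        )

    @property
    def event_ages(self) -> np.ndarray:
        return np.array([r.event_age for r in self.records], dtype=float)

    @property
    def events(self) -> np.ndarray:
        return np.array([r.event for r in self.records], dtype=bool)


def _parse_event(value, row: int) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise ValueError(f"row {row}: cannot parse event flag {value!r}")


def read_lifespan_table(path: str | os.PathLike, delimiter: str = ",") -> dict[str, "Cohort"]:
    """Read a delimited survival table into cohorts keyed by group label.

    Rows are grouped by their ``group`` column, in order of first appearance;
    invariant-violating rows raise :class:`TableValidationError` naming the
    offending data row (1-based, header excluded).
    """
    try:
        # round_trip parsing keeps ages at full precision (read(write(x)) == x)
        df = pd.read_csv(
            path,
            sep=delimiter,
            dtype={"subject_id": str, "group": str},
            float_precision="round_trip",
        )
    except pd.errors.EmptyDataError:
        raise TableFormatError(f"empty input file: {path}") from None
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"missing column(s) {missing} in {path}")
    if len(df) == 0:
        raise TableFormatError(f"no data rows in {path}")

    problems: list[str] = []
    grouped: dict[str, list[LifespanRecord]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            rec = LifespanRecord(
                subject_id=str(row.subject_id),
                group=str(row.group),
                entry_age=float(row.entry_age),
                event_age=float(row.event_age),
                event=_parse_event(row.event, i),
            )
        except (ValueError, TypeError) as exc:
            problems.append(f"row {i}: {exc}")
            continue
        grouped.setdefault(rec.group, []).append(rec)
    if problems:
        raise TableValidationError("; ".join(problems))

    cohorts: dict[str, Cohort] = {}
    for group, records in grouped.items():
        entry_ages = {r.entry_age for r in records}
        if len(entry_ages) > 1:
            raise TableValidationError(
                f"group {group!r} has multiple entry ages {sorted(entry_ages)}"
            )
        cohorts[group] = Cohort(group=group, records=tuple(records), entry_age=records[0].entry_age)
    return cohorts


def write_lifespan_table(
    cohorts: Mapping[str, "Cohort"], path: str | os.PathLike, delimiter: str = ","
) -> None:
    """Write cohorts back to the standard delimited table format."""
    rows = [
        {
            "subject_id": r.subject_id,
            "group": r.group,
            "entry_age": repr(float(r.entry_age)),
            "event_age": repr(float(r.event_age)),
            "event": r.event,
        }
        for cohort in cohorts.values()
        for r in cohort.records
    ]
    pd.DataFrame(rows, columns=list(COLUMNS)).to_csv(path, sep=delimiter, index=False)


def write_summary(summary: "LifespanSummary", path: str | os.PathLike) -> None:
    """Serialize a lifespan summary to JSON; re-reading reproduces all
    numeric fields exactly (floats survive the repr round-trip)."""
    payload: dict = {
        "start_age": summary.start_age,
        "control": summary.control,
        "treated": summary.treated,
        "t_half": dict(summary.t_half),
        "residual": dict(summary.residual),
        "gain_months": summary.gain_months,
        "percent_increase_residual": summary.percent_increase_residual,
        "percent_increase_overall": summary.percent_increase_overall,
    }
    if summary.params is not None:
        payload["params"] = {
            g: {"P1": p.P1, "P2": p.P2, "P3": p.P3} for g, p in summary.params.items()
        }
    if summary.ci is not None:
        payload["ci"] = {k: [lo, hi] for k, (lo, hi) in summary.ci.items()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def read_summary(path: str | os.PathLike) -> "LifespanSummary":
    """Inverse of :func:`write_summary`."""
    from .gompertz import GompertzParams
    from .metrics import LifespanSummary

    with open(path) as fh:
        payload = json.load(fh)
    params = None
    if "params" in payload:
        params = {
            g: GompertzParams(d["P1"], d["P2"], d["P3"])
            for g, d in payload["params"].items()
        }
    ci = None
    if "ci" in payload:
        ci = {k: (lo, hi) for k, (lo, hi) in payload["ci"].items()}
    return LifespanSummary(
        start_age=payload["start_age"],
        control=payload["control"],
        treated=payload["treated"],
        t_half=payload["t_half"],
        residual=payload["residual"],
        gain_months=payload["gain_months"],
        percent_increase_residual=payload["percent_increase_residual"],
        percent_increase_overall=payload["percent_increase_overall"],
        ci=ci,
        params=params,
    )
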