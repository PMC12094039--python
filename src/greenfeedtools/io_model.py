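"""Domain types and file I/O for GreenFeed exports.

The GreenFeed system (C-Lock Inc.) produces two kinds of per-animal event
tables that this package consumes:

* **visit records** — one row per preprocessed chamber visit, carrying the
  usable measurement duration and per-gas production rates (CH4, CO2, O2,
  H2, all in g/d);
* **feedtimes** — one row per bait-pellet drop event (animal, unit,
  timestamp, number of drops).

Export dialects vary between installations, so every reader takes a
``column_map`` overriding the default column names.  Field data are dirty:
malformed rows are dropped and counted in an :class:`IngestReport`, never
raised, so that monitoring reports still render mid-trial.

Identifier handling: raw IDs are canonicalized (whitespace stripped,
leading zeros removed from all-digit IDs) and optionally mapped through a
:class:`Roster` of (RFID, farm ID) pairs.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GASES",
    "VisitRecord",
    "FeedEvent",
    "Roster",
    "StudyWindow",
    "IngestReport",
    "InvalidIDError",
    "ColumnMappingError",
    "canonical_id",
    "read_visits",
    "read_feedtimes",
    "read_roster",
    "write_visits",
    "write_feedtimes",
    "write_table",
    "DEFAULT_VISIT_COLUMNS",
    "DEFAULT_FEED_COLUMNS",
]

logger = logging.getLogger(__name__)

#: Gas names measured by the system, in canonical order.
GASES = ("CH4", "CO2", "O2", "H2")

#: Slack (minutes) allowed when checking that the usable duration fits
#: inside the visit interval.
DURATION_TOLERANCE_MIN = 1e-6


class InvalidIDError(ValueError):
    """Raised for empty/whitespace-only animal identifiers."""


class ColumnMappingError(ValueError):
    """Raised when a mandatory column is absent from an input file."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StudyWindow:
    """Inclusive date range of a trial; length in days is end - start + 1."""

    start_date: dt.date
    end_date: dt.date

    def __post_init__(self) -> None:
        if self.end_date < self.start_date:
            raise ValueError("end_date must not precede start_date")

    @property
    def n_days(self) -> int:
        return (self.end_date - self.start_date).days + 1

    def dates(self) -> list[dt.date]:
        return [self.start_date + dt.timedelta(days=i) for i in range(self.n_days)]

    def week_index(self, date: dt.date) -> int:
        """Consecutive 7-day study week of ``date``; week 1 starts at start_date."""
        return (date - self.start_date).days // 7 + 1

    def __contains__(self, date: dt.date) -> bool:
        return self.start_date <= date <= self.end_date


@dataclass
class VisitRecord:
    """One preprocessed GreenFeed visit.

    ``gas`` maps gas name -> production rate in g/d; a gas absent from the
    map had no usable value for this visit (an exported 0 or blank is
    treated as missing — valid gas fluxes from a live animal are never
    exactly zero).
    """

    animal_id: str
    unit_id: str
    start_time: dt.datetime
    end_time: dt.datetime
    good_duration_min: float
    gas: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.end_time < self.start_time:
            raise ValueError("end_time precedes start_time")
        span_min = (self.end_time - self.start_time).total_seconds() / 60.0
        if self.good_duration_min < 0:
            raise ValueError("good_duration_min is negative")
        if self.good_duration_min > span_min + DURATION_TOLERANCE_MIN:
            raise ValueError("good_duration_min exceeds visit interval")
        for g, v in self.gas.items():
            if g not in GASES:
                raise ValueError(f"unknown gas {g!r}")
            if not math.isfinite(v) or v == 0:
                raise ValueError(f"gas {g} value {v!r} is not a finite nonzero number")

    @property
    def date(self) -> dt.date:
        """Calendar date of the visit in local trial time (date of start_time)."""
        return self.start_time.date()


@dataclass
class FeedEvent:
    """One bait-drop event from a feedtimes file."""

    animal_id: str
    unit_id: str
    time: dt.datetime
    drops: int

    def validate(self) -> None:
        if self.drops < 0 or int(self.drops) != self.drops:
            raise ValueError("drops must be a non-negative integer")

    @property
    def date(self) -> dt.date:
        return self.time.date()


class Roster:
    """Mapping of RFID (as exported) to farm animal ID.

    Both sides are canonicalized on construction.  Canonical RFIDs must be
    unique; a farm ID that also appears as an RFID must map to itself,
    otherwise :func:`canonical_id` would not be idempotent.
    """

    def __init__(self, entries: Iterable[tuple[str, str]]):
        self.entries = [(str(r), str(f)) for r, f in entries]
        mapping: dict[str, str] = {}
        for rfid, farm in self.entries:
            key = canonical_id(rfid)
            val = canonical_id(farm)
            if key in mapping and mapping[key] != val:
                raise ValueError(f"duplicate RFID {key!r} in roster")
            mapping[key] = val
        for key, val in mapping.items():
            if val in mapping and mapping[val] != val:
                raise ValueError(
                    f"roster maps farm ID {val!r} onward to {mapping[val]!r}; "
                    "chained mappings are not allowed"
                )
        self._map = mapping

    def lookup(self, canonical: str) -> str:
        return self._map.get(canonical, canonical)

    def animal_ids(self) -> list[str]:
        """Sorted canonical farm IDs of all rostered animals."""
        return sorted(set(self._map.values()))

    def __len__(self) -> int:
        return len(self._map)

    def __repr__(self) -> str:
        return f"Roster({len(self._map)} animals)"


def canonical_id(raw: str, roster: Roster | None = None) -> str:
    """Canonicalize an animal identifier.

    Strips surrounding whitespace, removes leading zeros from all-digit
    IDs (``"0000982123"`` -> ``"982123"``), then maps RFID -> farm ID when
    a roster is given; IDs not in the roster pass through.  Idempotent.
    """
    s = str(raw).strip()
    if not s:
        raise InvalidIDError("animal ID is empty")
    if s.isdigit():
        s = s.lstrip("0") or "0"
    if roster is not None:
        s = roster.lookup(s)
    return s


# ---------------------------------------------------------------------------
# Ingestion
# ---------------------------------------------------------------------------


@dataclass
class IngestReport:
    """Row accounting for one file read: rows_kept + rows_dropped = rows_read."""

    path: str = ""
    rows_read: int = 0
    rows_kept: int = 0
    dropped: dict[str, int] = field(default_factory=dict)

    @property
    def rows_dropped(self) -> int:
        return sum(self.dropped.values())

    def drop(self, reason: str) -> None:
        self.dropped[reason] = self.dropped.get(reason, 0) + 1


#: Default visit-file dialect (config-overridable; exports vary in the wild).
DEFAULT_VISIT_COLUMNS: dict[str, str] = {
    "animal_id": "AnimalName",
    "unit_id": "FeederID",
    "start_time": "StartTime",
    "end_time": "EndTime",
    "good_duration": "GoodDataDuration",
    "CH4": "CH4GramsPerDay",
    "CO2": "CO2GramsPerDay",
    "O2": "O2GramsPerDay",
    "H2": "H2GramsPerDay",
}

#: Default feedtimes dialect.
DEFAULT_FEED_COLUMNS: dict[str, str] = {
    "animal_id": "AnimalName",
    "unit_id": "FeederID",
    "time": "Time",
    "drops": "Drops",
}

DEFAULT_ROSTER_COLUMNS: dict[str, str] = {"rfid": "RFID", "farm_id": "FarmName"}


def _resolve_columns(
    df: pd.DataFrame, defaults: Mapping[str, str], column_map: Mapping[str, str] | None
) -> dict[str, str]:
    cols = dict(defaults)
    if column_map:
        cols.update(column_map)
    for logical, name in cols.items():
        if logical in GASES:
            continue  # gas columns are optional per dialect
        if name not in df.columns:
            raise ColumnMappingError(
                f"mandatory column {name!r} (for {logical!r}) not found; "
                f"available: {list(df.columns)}"
            )
    return cols


def _read_raw(path: str | Path) -> pd.DataFrame | None:
    """Read a CSV as strings; None for a zero-byte file."""
    try:
        return pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        logger.warning("file %s is empty (no header)", path)
        return None


def parse_duration_min(value: str) -> float | None:
    """Parse a usable-duration cell: 'HH:MM:SS' text or decimal minutes."""
    s = str(value).strip()
    if not s:
        return None
    if ":" in s:
        parts = s.split(":")
        if len(parts) != 3:
            return None
        try:
            h, m, sec = (float(p) for p in parts)
        except ValueError:
            return None
        return h * 60.0 + m + sec / 60.0
    try:
        v = float(s)
    except ValueError:
        return None
    return v if math.isfinite(v) else None


def _parse_timestamp(value: str) -> dt.datetime | None:
    ts = pd.to_datetime(str(value).strip(), errors="coerce")
    if pd.isna(ts):
        return None
    return ts.to_pydatetime()


def read_visits(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    roster: Roster | None = None,
) -> tuple[list[VisitRecord], IngestReport]:
    """Read a visit-record CSV into :class:`VisitRecord` objects.

    Rows with unparseable IDs, timestamps, inconsistent intervals or
    durations are dropped and tallied by reason in the returned
    :class:`IngestReport`.  Gas cells that are blank, non-numeric, zero or
    non-finite are treated as missing for that gas only.
    """
    report = IngestReport(path=str(path))
    df = _read_raw(path)
    if df is None:
        return [], report
    cols = _resolve_columns(df, DEFAULT_VISIT_COLUMNS, column_map)
    report.rows_read = len(df)
    if df.empty:
        logger.warning("visit file %s has a header but no data rows", path)
        return [], report

    records: list[VisitRecord] = []
    for row in df.itertuples(index=False):
        row_d = dict(zip(df.columns, row))
        try:
            animal = canonical_id(row_d[cols["animal_id"]], roster)
        except InvalidIDError:
            report.drop("animal_id")
            continue
        start = _parse_timestamp(row_d[cols["start_time"]])
        end = _parse_timestamp(row_d[cols["end_time"]])
        if start is None or end is None:
            report.drop("timestamp")
            continue
        if end < start:
            report.drop("interval")
            continue
        dur = parse_duration_min(row_d[cols["good_duration"]])
        span_min = (end - start).total_seconds() / 60.0
        if dur is None or dur < 0 or dur > span_min + DURATION_TOLERANCE_MIN:
            report.drop("duration")
            continue
        gas: dict[str, float] = {}
        for g in GASES:
            name = cols.get(g)
            if name is None or name not in row_d:
                continue
            cell = str(row_d[name]).strip()
            if not cell:
                continue
            try:
                v = float(cell)
            except ValueError:
                continue
            if math.isfinite(v) and v != 0:
                gas[g] = v
        records.append(
            VisitRecord(
                animal_id=animal,
                unit_id=str(row_d[cols["unit_id"]]).strip(),
                start_time=start,
                end_time=end,
                good_duration_min=dur,
                gas=gas,
            )
        )
        report.rows_kept += 1
    if report.rows_dropped:
        logger.info(
            "read %s: kept %d/%d rows (dropped %s)",
            path,
            report.rows_kept,
            report.rows_read,
            report.dropped,
        )
    return records, report


def read_feedtimes(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    roster: Roster | None = None,
) -> tuple[list[FeedEvent], IngestReport]:
    """Read a feedtimes CSV into :class:`FeedEvent` objects (see read_visits)."""
    report = IngestReport(path=str(path))
    df = _read_raw(path)
    if df is None:
        return [], report
    cols = _resolve_columns(df, DEFAULT_FEED_COLUMNS, column_map)
    report.rows_read = len(df)
    if df.empty:
        logger.warning("feedtimes file %s has a header but no data rows", path)
        return [], report

    events: list[FeedEvent] = []
    for row in df.itertuples(index=False):
        row_d = dict(zip(df.columns, row))
        try:
            animal = canonical_id(row_d[cols["animal_id"]], roster)
        except InvalidIDError:
            report.drop("animal_id")
            continue
        time = _parse_timestamp(row_d[cols["time"]])
        if time is None:
            report.drop("timestamp")
            continue
        try:
            drops = int(str(row_d[cols["drops"]]).strip())
        except ValueError:
            report.drop("drops")
            continue
        if drops < 0:
            report.drop("drops")
            continue
        events.append(
            FeedEvent(
                animal_id=animal,
                unit_id=str(row_d[cols["unit_id"]]).strip(),
                time=time,
                drops=drops,
            )
        )
        report.rows_kept += 1
    return events, report


def read_roster(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> Roster:
    """Read an RFID -> farm-ID roster CSV."""
    df = _read_raw(path)
    if df is None:
        return Roster([])
    cols = dict(DEFAULT_ROSTER_COLUMNS)
    if column_map:
        cols.update(column_map)
    for logical, name in cols.items():
        if name not in df.columns:
            raise ColumnMappingError(f"mandatory roster column {name!r} not found")
    return Roster(
        (str(r), str(f))
        for r, f in zip(df[cols["rfid"]], df[cols["farm_id"]])
        if str(r).strip() and str(f).strip()
    )


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

_TS_FMT = "%Y-%m-%d %H:%M:%S"


def write_visits(records: Sequence[VisitRecord], path: str | Path) -> None:
    """Write visit records in the default dialect; round-trips via read_visits."""
    rows = []
    for r in records:
        row = {
            "AnimalName": r.animal_id,
            "FeederID": r.unit_id,
            "StartTime": r.start_time.strftime(_TS_FMT),
            "EndTime": r.end_time.strftime(_TS_FMT),
            "GoodDataDuration": r.good_duration_min,
        }
        for g in GASES:
            row[DEFAULT_VISIT_COLUMNS[g]] = r.gas.get(g, np.nan)
        rows.append(row)
    pd.DataFrame(rows, columns=list(DEFAULT_VISIT_COLUMNS.values())).to_csv(
        path, index=False
    )


def write_feedtimes(events: Sequence[FeedEvent], path: str | Path) -> None:
    rows = [
        {
            "AnimalName": e.animal_id,
            "FeederID": e.unit_id,
            "Time": e.time.strftime(_TS_FMT),
            "Drops": e.drops,
        }
        for e in events
    ]
    pd.DataFrame(rows, columns=list(DEFAULT_FEED_COLUMNS.values())).to_csv(
        path, index=False
    )


def _as_frame(rows) -> pd.DataFrame:
    if isinstance(rows, pd.DataFrame):
        return rows
    rows = list(rows)
    if rows and dataclasses.is_dataclass(rows[0]):
        return pd.DataFrame([dataclasses.asdict(r) for r in rows])
    return pd.DataFrame(rows)


def write_table(rows, path: str | Path, format: str | None = None) -> None:
    """Write a homogeneous row set as CSV or XLSX (inferred from suffix)."""
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower() or "csv"
    df = _as_frame(rows)
    if fmt == "csv":
        df.to_csv(path, index=False)
    elif fmt == "xlsx":
        df.to_excel(path, index=False, engine="openpyxl")
    else:
        raise ValueError(f"unsupported table format {fmt!r}")
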