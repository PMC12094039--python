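"""Visitation monitoring from feed-drop events or visit records.

Early in a trial, animals must be confirmed to be using the unit(s); an
animal that never triggers feed drops needs retraining.  A *visit* is one
head-in-unit episode: consecutive drop events for the same animal (and
unit) separated by no more than a gap threshold belong to one visit.
Feedtimes are the preferred input here because they capture visits too
short to survive preprocessing into a valid record; preprocessed visit
records are accepted too (each record is one visit by construction).
"""

from __future__ import annotations

import datetime as dt
from typing import Sequence

import pandas as pd

from .io_model import FeedEvent, Roster, StudyWindow, VisitRecord

__all__ = ["DEFAULT_GAP_SECONDS", "group_visits", "visits_per_animal", "nonvisitors"]

#: Default maximum within-visit gap between consecutive drop events.
DEFAULT_GAP_SECONDS = 300.0


def group_visits(
    events: Sequence[FeedEvent], gap_seconds: float = DEFAULT_GAP_SECONDS
) -> list[list[FeedEvent]]:
    """Group drop events into visits by inter-event gap.

    Events are grouped per (animal, unit), ordered by time; a gap greater
    than ``gap_seconds`` starts a new visit.  Output order: by animal,
    unit, then visit start time.  Invariant to input ordering.
    """
    by_key: dict[tuple[str, str], list[FeedEvent]] = {}
    for e in events:
        by_key.setdefault((e.animal_id, e.unit_id), []).append(e)
    visits: list[list[FeedEvent]] = []
    for key in sorted(by_key):
        chain = sorted(by_key[key], key=lambda e: e.time)
        current = [chain[0]]
        for e in chain[1:]:
            if (e.time - current[-1].time).total_seconds() > gap_seconds:
                visits.append(current)
                current = [e]
            else:
                current.append(e)
        visits.append(current)
    return visits


def _visit_rows(data, gap_seconds: float) -> list[tuple[str, dt.date, str]]:
    """(animal, date, unit) per visit, for either input kind."""
    if not data:
        return []
    if isinstance(data[0], VisitRecord):
        return [(r.animal_id, r.date, r.unit_id) for r in data]
    return [
        (v[0].animal_id, v[0].date, v[0].unit_id)
        for v in group_visits(data, gap_seconds)
    ]


def visits_per_animal(
    data: Sequence[FeedEvent] | Sequence[VisitRecord],
    study: StudyWindow | None = None,
    gap_seconds: float = DEFAULT_GAP_SECONDS,
) -> pd.DataFrame:
    """Per-animal, per-day, per-unit visit counts.

    ``data`` is either feed-drop events (gap-grouped into visits, dated by
    the first drop) or preprocessed visit records (one visit each).
    Returns a tidy frame with columns animal_id, date, unit_id, n_visits,
    sorted for deterministic output.
    """
    rows = _visit_rows(list(data), gap_seconds)
    df = pd.DataFrame(rows, columns=["animal_id", "date", "unit_id"])
    if df.empty:
        return pd.DataFrame(columns=["animal_id", "date", "unit_id", "n_visits"])
    if study is not None:
        df = df[(df["date"] >= study.start_date) & (df["date"] <= study.end_date)]
    out = (
        df.groupby(["animal_id", "date", "unit_id"], sort=True)
        .size()
        .rename("n_visits")
        .reset_index()
    )
    return out


def nonvisitors(
    data: Sequence[FeedEvent] | Sequence[VisitRecord],
    roster: Roster,
    window_days: int | None = None,
    gap_seconds: float = DEFAULT_GAP_SECONDS,
) -> list[str]:
    """Rostered animals with zero visits in the trailing monitoring window.

    The window covers the last ``window_days`` calendar days ending at the
    most recent activity in ``data`` (all of it when ``window_days`` is
    None).  Returns sorted canonical IDs.
    """
    if roster is None or len(roster) == 0:
        raise ValueError("nonvisitors requires a non-empty roster")
    rows = _visit_rows(list(data), gap_seconds)
    if rows and window_days is not None:
        last = max(date for _, date, _ in rows)
        cutoff = last - dt.timedelta(days=window_days - 1)
        rows = [r for r in rows if r[1] >= cutoff]
    seen = {a for a, _, _ in rows}
    return sorted(set(roster.animal_ids()) - seen)
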