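"""Daily bait-pellet intake per animal from feed-drop events.

Each feed event carries a drop count; intake is simply
``drops x grams_per_drop``, summed per animal and calendar date across
all units.  ``grams_per_drop`` is a mandatory user parameter — pellet cup
masses vary by feed and unit calibration, and a silent default would
corrupt intakes.  The ``n_visits`` column uses the same gap-based visit
grouping as the visitation module; intake totals never depend on it.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Sequence

from .io_model import FeedEvent, Roster, StudyWindow
from .visits import DEFAULT_GAP_SECONDS, group_visits

__all__ = ["IntakeRow", "pellet_intakes"]


@dataclass
class IntakeRow:
    """One animal-day of pellet intake; intake_g = n_drops * grams_per_drop."""

    animal_id: str
    date: dt.date
    n_visits: int
    n_drops: int
    intake_g: float


def pellet_intakes(
    events: Sequence[FeedEvent],
    grams_per_drop: float,
    study: StudyWindow | None = None,
    roster: Roster | None = None,
    gap_seconds: float = DEFAULT_GAP_SECONDS,
) -> list[IntakeRow]:
    """Daily pellet intake per animal, merged across all units.

    Drops are summed by each event's own calendar date, so
    ``sum(intake_g) == grams_per_drop * sum(drops)`` holds exactly;
    visits are dated by their first drop event.  Rostered animals with no
    events get zero-filled rows for every study date (requires ``study``).
    """
    if grams_per_drop <= 0:
        raise ValueError("grams_per_drop must be positive")
    events = list(events)
    if study is not None:
        events = [e for e in events if e.date in study]

    drops: dict[tuple[str, dt.date], int] = {}
    for e in events:
        key = (e.animal_id, e.date)
        drops[key] = drops.get(key, 0) + e.drops
    visit_counts: dict[tuple[str, dt.date], int] = {}
    for visit in group_visits(events, gap_seconds):
        key = (visit[0].animal_id, visit[0].date)
        visit_counts[key] = visit_counts.get(key, 0) + 1

    keys = set(drops)
    if roster is not None and study is not None:
        seen = {a for a, _ in keys}
        for a in roster.animal_ids():
            if a not in seen:
                keys.update((a, d) for d in study.dates())
    return [
        IntakeRow(
            animal_id=a,
            date=d,
            n_visits=visit_counts.get((a, d), 0),
            n_drops=drops.get((a, d), 0),
            intake_g=drops.get((a, d), 0) * grams_per_drop,
        )
        for a, d in sorted(keys)
    ]
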