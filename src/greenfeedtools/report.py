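"""Descriptive visitation and gas-production summaries, rendered to Markdown.

Mirrors the daily/final monitoring report a farm team reads during a
trial: how many animals are using the unit (and which rostered animals
are not), how many records arrive per day and per animal, when in the day
animals visit (four 6-hour behavioural windows), and how gas production
is distributed per animal and across the day.  All numbers in the
rendered document come straight from the functions below — the template
re-derives nothing.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_model import GASES, Roster, StudyWindow, VisitRecord
from .processing import summarize_gas

__all__ = [
    "TIME_WINDOWS",
    "TimeWindowCounts",
    "AnimalActivity",
    "time_window_counts",
    "records_per_day",
    "animal_activity",
    "diurnal_profile",
    "render_report",
]

#: Behavioural time-of-day windows (labels and half-open hour ranges);
#: W1 wraps midnight.
TIME_WINDOWS = (
    ("W1 22:00-04:00", 22, 4),
    ("W2 04:00-10:00", 4, 10),
    ("W3 10:00-16:00", 10, 16),
    ("W4 16:00-22:00", 16, 22),
)


@dataclass
class TimeWindowCounts:
    """Record counts per time window; sums to the number of input records."""

    counts: tuple[int, int, int, int]

    @property
    def total(self) -> int:
        return sum(self.counts)


@dataclass
class AnimalActivity:
    animal_id: str
    n_records: int
    records_per_day: float
    n_records_with_gas: dict[str, int]


def _window_of(t: dt.datetime) -> int:
    h = t.hour
    if 4 <= h < 10:
        return 1
    if 10 <= h < 16:
        return 2
    if 16 <= h < 22:
        return 3
    return 0  # [22:00, 04:00), wrapping midnight


def time_window_counts(records: Iterable[VisitRecord]) -> TimeWindowCounts:
    """Assign each record to exactly one window by its start hour."""
    counts = [0, 0, 0, 0]
    for r in records:
        counts[_window_of(r.start_time)] += 1
    return TimeWindowCounts(counts=tuple(counts))


def records_per_day(
    records: Sequence[VisitRecord], study: StudyWindow | None = None
) -> pd.DataFrame:
    """Records per calendar date, with per-gas data counts, zero-filled.

    The date range is the study window when given, otherwise the span of
    the records themselves.  Columns: n_records and n_with_<gas>.
    """
    cols = ["n_records", *[f"n_with_{g}" for g in GASES]]
    if study is not None:
        dates = study.dates()
    elif records:
        d0 = min(r.date for r in records)
        d1 = max(r.date for r in records)
        dates = StudyWindow(d0, d1).dates()
    else:
        dates = []
    out = pd.DataFrame(0, index=pd.Index(dates, name="date"), columns=cols)
    for r in records:
        if r.date not in out.index:
            continue
        out.loc[r.date, "n_records"] += 1
        for g in r.gas:
            out.loc[r.date, f"n_with_{g}"] += 1
    return out.reset_index()


def animal_activity(
    records: Sequence[VisitRecord],
    study: StudyWindow,
    roster: Roster | None = None,
) -> list[AnimalActivity]:
    """Per-animal record counts and records/day over the study length.

    ``records_per_day`` divides by the study length in days (an animal
    with 184 records over a 46-day study has 4.0 records/day).  Rostered
    animals with no records appear with zeros.
    """
    study_days = study.n_days
    ids = sorted(
        {r.animal_id for r in records}
        | (set(roster.animal_ids()) if roster is not None else set())
    )
    by_id: dict[str, list[VisitRecord]] = {a: [] for a in ids}
    for r in records:
        by_id[r.animal_id].append(r)
    return [
        AnimalActivity(
            animal_id=a,
            n_records=len(rs),
            records_per_day=len(rs) / study_days,
            n_records_with_gas={g: sum(1 for r in rs if g in r.gas) for g in GASES},
        )
        for a, rs in by_id.items()
    ]


def diurnal_profile(
    records: Sequence[VisitRecord],
    gases: Sequence[str] = GASES,
    bin_minutes: int = 60,
) -> pd.DataFrame:
    """Unweighted per-gas means by time-of-day bin, with no filtering.

    One row per bin of the day (``bin_minutes`` must divide 1440); per gas
    the count and plain mean of non-missing values.  Empty bins carry
    n = 0 and a missing mean.
    """
    if 1440 % bin_minutes != 0:
        raise ValueError("bin_minutes must divide 1440")
    n_bins = 1440 // bin_minutes
    starts = [
        f"{(b * bin_minutes) // 60:02d}:{(b * bin_minutes) % 60:02d}"
        for b in range(n_bins)
    ]
    out = pd.DataFrame({"bin_start": starts})
    sums = {g: np.zeros(n_bins) for g in gases}
    ns = {g: np.zeros(n_bins, dtype=int) for g in gases}
    for r in records:
        b = (r.start_time.hour * 60 + r.start_time.minute) // bin_minutes
        for g in gases:
            if g in r.gas:
                sums[g][b] += r.gas[g]
                ns[g][b] += 1
    for g in gases:
        out[f"n_{g}"] = ns[g]
        with np.errstate(invalid="ignore"):
            out[f"mean_{g}"] = np.where(ns[g] > 0, sums[g] / np.maximum(ns[g], 1), np.nan)
    return out


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _md_table(header: Sequence[str], rows: Sequence[Sequence[str]]) -> str:
    lines = [
        "| " + " | ".join(header) + " |",
        "|" + "|".join(["---"] * len(header)) + "|",
    ]
    for row in rows:
        lines.append("| " + " | ".join(str(c) for c in row) + " |")
    return "\n".join(lines)


def _fmt(v: float, nd: int = 1) -> str:
    return f"{v:.{nd}f}"


def _five_number(vals: Sequence[float]) -> tuple[float, float, float, float, float]:
    """Boxplot five-number summary with 1.5*IQR whiskers."""
    a = np.asarray(vals, dtype=float)
    q1, med, q3 = np.percentile(a, [25, 50, 75])
    iqr = q3 - q1
    lo = a[a >= q1 - 1.5 * iqr].min()
    hi = a[a <= q3 + 1.5 * iqr].max()
    return lo, q1, med, q3, hi


def _normalize_gases(plot_opt) -> list[str]:
    if plot_opt == "all" or plot_opt is None:
        return list(GASES)
    gases = [plot_opt] if isinstance(plot_opt, str) else list(plot_opt)
    for g in gases:
        if g not in GASES:
            raise ValueError(f"unknown gas {g!r}; choose from {GASES} or 'all'")
    return [g for g in GASES if g in gases]


def render_report(
    records: Sequence[VisitRecord],
    study: StudyWindow,
    roster: Roster | None = None,
    plot_opt="all",
    mode: str = "daily",
    out_dir: str | Path | None = None,
) -> tuple[str, list[Path]]:
    """Render the monitoring report as Markdown (plus PNG figures).

    ``mode='daily'`` gives the mid-trial check; ``mode='final'`` adds the
    unfiltered diurnal gas profile.  Only gases in ``plot_opt`` appear.
    Returns the document and the figure paths (figures are only written
    when ``out_dir`` is given).  Rendering is deterministic.
    """
    if mode not in ("daily", "final"):
        raise ValueError("mode must be 'daily' or 'final'")
    gases = _normalize_gases(plot_opt)
    records = list(records)
    activity = animal_activity(records, study, roster)
    per_day = records_per_day(records, study)
    windows = time_window_counts(records)
    seen = {r.animal_id for r in records}
    nonvisiting = (
        sorted(set(roster.animal_ids()) - seen) if roster is not None else []
    )

    title = "GreenFeed Final Report" if mode == "final" else "GreenFeed Daily Report"
    L: list[str] = [f"# {title}", ""]
    L.append(
        f"Study window: {study.start_date.isoformat()} to "
        f"{study.end_date.isoformat()} ({study.n_days} days)"
    )
    L.append(f"Total visit records: {len(records)}")
    L.append("")

    L.append("## Animals")
    L.append("")
    L.append(f"Animals with records: {len(seen)}")
    if roster is not None:
        L.append(f"Animals on roster: {len(roster.animal_ids())}")
        L.append(
            "Rostered animals with no records: "
            + (", ".join(nonvisiting) if nonvisiting else "none")
        )
    L.append("")

    L.append("## Records per day")
    L.append("")
    header = ["date", "records"] + [f"with {g}" for g in gases]
    rows = [
        [str(r.date), str(int(r.n_records))]
        + [str(int(getattr(r, f"n_with_{g}"))) for g in gases]
        for r in per_day.itertuples(index=False)
    ]
    L.append(_md_table(header, rows))
    L.append("")

    L.append("## Records per animal")
    L.append("")
    header = ["animal", "records", "records/day"] + [f"with {g}" for g in gases]
    rows = [
        [a.animal_id, str(a.n_records), _fmt(a.records_per_day, 2)]
        + [str(a.n_records_with_gas[g]) for g in gases]
        for a in activity
    ]
    L.append(_md_table(header, rows))
    L.append("")

    L.append("## Visits by time of day")
    L.append("")
    L.append(
        _md_table(
            [label for label, _, _ in TIME_WINDOWS],
            [[str(c) for c in windows.counts]],
        )
    )
    L.append("")

    by_animal: dict[str, list[VisitRecord]] = {}
    for r in records:
        by_animal.setdefault(r.animal_id, []).append(r)
    for g in gases:
        L.append(f"## {g} production per animal (g/d)")
        L.append("")
        all_vals = [r.gas[g] for r in records if g in r.gas]
        if all_vals:
            s = summarize_gas(all_vals, g)
            L.append(
                f"All records: n={s.n}, mean={_fmt(s.mean)}, sd={_fmt(s.sd)}, "
                f"CV={_fmt(s.cv)}%, range {_fmt(s.min)} to {_fmt(s.max)}"
            )
        else:
            L.append("All records: no data")
        L.append("")
        rows = []
        for a in sorted(by_animal):
            vals = [r.gas[g] for r in by_animal[a] if g in r.gas]
            if not vals:
                rows.append([a, "0", "-", "-", "-", "-", "-"])
                continue
            lo, q1, med, q3, hi = _five_number(vals)
            rows.append(
                [a, str(len(vals)), _fmt(lo), _fmt(q1), _fmt(med), _fmt(q3), _fmt(hi)]
            )
        L.append(
            _md_table(
                ["animal", "n", "whisker lo", "Q1", "median", "Q3", "whisker hi"],
                rows,
            )
        )
        L.append("")

    profile = None
    if mode == "final":
        profile = diurnal_profile(records, gases)
        L.append("## Gas production across the day (all records, unfiltered)")
        L.append("")
        header = ["time"] + [h for g in gases for h in (f"n {g}", f"mean {g}")]
        rows = []
        for r in profile.itertuples(index=False):
            row = [r.bin_start]
            for g in gases:
                n = int(getattr(r, f"n_{g}"))
                m = getattr(r, f"mean_{g}")
                row += [str(n), "-" if pd.isna(m) else _fmt(m)]
            rows.append(row)
        L.append(_md_table(header, rows))
        L.append("")

    doc = "\n".join(L)
    figures: list[Path] = []
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.md").write_text(doc)
        figures = _render_figures(records, activity, windows, profile, gases, out)
    return doc, figures


def _render_figures(records, activity, windows, profile, gases, out: Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figures: list[Path] = []

    fig, ax = plt.subplots(figsize=(8, 3.5))
    ids = [a.animal_id for a in activity]
    ax.bar(ids, [a.n_records for a in activity], color="#4878a8")
    ax.set_ylabel("visit records")
    ax.tick_params(axis="x", rotation=90, labelsize=6)
    fig.tight_layout()
    p = out / "fig_records_per_animal.png"
    fig.savefig(p, dpi=100)
    plt.close(fig)
    figures.append(p)

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.bar([label.split()[0] for label, _, _ in TIME_WINDOWS], windows.counts,
           color="#70a070")
    ax.set_ylabel("visit records")
    fig.tight_layout()
    p = out / "fig_time_windows.png"
    fig.savefig(p, dpi=100)
    plt.close(fig)
    figures.append(p)

    by_animal: dict[str, list[float]] = {}
    for g in gases:
        by_animal.clear()
        for r in records:
            if g in r.gas:
                by_animal.setdefault(r.animal_id, []).append(r.gas[g])
        if not by_animal:
            continue
        fig, ax = plt.subplots(figsize=(8, 3.5))
        keys = sorted(by_animal)
        ax.boxplot([by_animal[k] for k in keys], tick_labels=keys, whis=1.5,
                   showfliers=False)
        ax.set_ylabel(f"{g} (g/d)")
        ax.tick_params(axis="x", rotation=90, labelsize=6)
        fig.tight_layout()
        p = out / f"fig_{g}_per_animal.png"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        figures.append(p)

    if profile is not None:
        fig, ax = plt.subplots(figsize=(7, 3.5))
        x = range(len(profile))
        for g in gases:
            ax.plot(x, profile[f"mean_{g}"], marker="o", ms=3, label=g)
        ax.set_xticks(list(x)[::2])
        ax.set_xticklabels(profile["bin_start"][::2], rotation=45, fontsize=7)
        ax.set_ylabel("mean production (g/d)")
        ax.legend(fontsize=7)
        fig.tight_layout()
        p = out / "fig_diurnal_profile.png"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        figures.append(p)

    return figures
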