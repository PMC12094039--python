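"""Record filtering and duration-weighted aggregation of gas phenotypes.

The pipeline turns raw spot-sampled visit records into per-animal daily
and weekly emission phenotypes, in four stages run in a fixed order:

1. **minimum-duration filter** — keep visits whose usable measurement time
   is at least ``min_time`` minutes (inclusive; valid measurements require
   >= 2 min of head-in-chamber time, so ``min_time >= 2``);
2. **outlier removal** — per gas, values outside mean +/- k*SD (default
   k = 3) over all remaining records are masked, in a single global pass
   (statistics are not recomputed after masking); a record left with no
   gas values is dropped;
3. **daily averages** — per animal and calendar date, the
   duration-weighted mean of each gas over records where that gas is
   present, emitted only for animal-days with at least ``param1`` records;
4. **weekly averages** — per animal and consecutive 7-day study week, the
   minute-weighted mean of the daily means (weight = the day's total
   retained visit minutes), emitted only for animal-weeks with at least
   ``param2`` distinct days with records.

``param1``, ``param2`` and ``min_time`` are the record-sufficiency knobs;
:func:`param_grid` evaluates retention and phenotype means over a grid of
them and :func:`grid_correlation` quantifies how retention responds.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_model import GASES, StudyWindow, VisitRecord

__all__ = [
    "ProcessParams",
    "DailyAverage",
    "WeeklyAverage",
    "GasSummary",
    "GridRow",
    "ProcessResult",
    "filter_min_time",
    "remove_gas_outliers",
    "daily_averages",
    "weekly_averages",
    "process",
    "summarize_gas",
    "param_grid",
    "grid_correlation",
    "visits_to_frame",
]

MIN_VALID_DURATION_MIN = 2.0


@dataclass(frozen=True)
class ProcessParams:
    """Record-sufficiency thresholds for the processing pipeline."""

    param1: int = 2  # min records per animal-day
    param2: int = 4  # min days with records per animal-week
    min_time: float = 2.0  # min usable visit duration, minutes
    outlier_k: float = 3.0

    def __post_init__(self) -> None:
        if self.min_time < MIN_VALID_DURATION_MIN:
            raise ValueError(
                "min_time must be at least 2 min (shorter visits do not yield "
                "a valid measurement)"
            )
        if self.param1 < 1 or self.param2 < 1:
            raise ValueError("param1 and param2 must be >= 1")
        if self.outlier_k <= 0:
            raise ValueError("outlier_k must be positive")


@dataclass
class DailyAverage:
    animal_id: str
    date: dt.date
    n_records: int
    total_minutes: float
    gas_mean: dict[str, float] = field(default_factory=dict)


@dataclass
class WeeklyAverage:
    animal_id: str
    week_index: int
    n_days: int
    n_records: int
    total_minutes: float
    gas_mean: dict[str, float] = field(default_factory=dict)


@dataclass
class GasSummary:
    """Descriptive summary of one gas: n, mean, SD, CV%, min, max."""

    gas: str
    n: int
    mean: float
    sd: float
    cv: float
    min: float
    max: float


@dataclass
class GridRow:
    """One cell of the param1 x param2 x min_time sensitivity sweep."""

    param1: int
    param2: int
    min_time: float
    n_daily_records: int
    n_animals_daily: int
    daily_mean: float | None
    daily_sd: float | None
    n_weekly_records: int
    n_animals_weekly: int
    weekly_mean: float | None
    weekly_sd: float | None


@dataclass
class ProcessResult:
    daily: list[DailyAverage]
    weekly: list[WeeklyAverage]
    counts: dict[str, int]


# ---------------------------------------------------------------------------
# Frame plumbing — the public operations work on record lists; internally
# the aggregation runs on a tidy DataFrame (one row per visit, one column
# per gas, NaN = missing).
# ---------------------------------------------------------------------------


def visits_to_frame(records: Iterable[VisitRecord]) -> pd.DataFrame:
    rows = [
        {
            "animal_id": r.animal_id,
            "unit_id": r.unit_id,
            "start_time": r.start_time,
            "date": r.start_time.date(),
            "good_duration_min": r.good_duration_min,
            **{g: r.gas.get(g, np.nan) for g in GASES},
        }
        for r in records
    ]
    cols = ["animal_id", "unit_id", "start_time", "date", "good_duration_min", *GASES]
    return pd.DataFrame(rows, columns=cols)


def _mask_outliers_frame(df: pd.DataFrame, outlier_k: float) -> pd.DataFrame:
    """Mask per-gas outliers (single pass) and drop all-missing rows."""
    df = df.copy()
    for g in GASES:
        vals = df[g].dropna()
        if len(vals) < 2:
            continue  # SD undefined: no masking for this gas
        mean = vals.mean()
        sd = vals.std(ddof=1)
        bad = (df[g] - mean).abs() > outlier_k * sd
        df.loc[bad, g] = np.nan
    keep = df[list(GASES)].notna().any(axis=1)
    return df[keep]


def _daily_frame(df: pd.DataFrame, param1: int) -> pd.DataFrame:
    if df.empty:
        return pd.DataFrame(
            columns=["animal_id", "date", "n_records", "total_minutes", *GASES]
        )
    keys = [df["animal_id"], df["date"]]
    out = df.groupby(["animal_id", "date"], sort=True).agg(
        n_records=("animal_id", "size"),
        total_minutes=("good_duration_min", "sum"),
    )
    w = df["good_duration_min"]
    for g in GASES:
        v = df[g]
        part = pd.DataFrame({"wv": v * w, "w": w.where(v.notna())})
        sums = part.groupby(keys).sum(min_count=1)
        out[g] = sums["wv"] / sums["w"]
    out = out[out["n_records"] >= param1]
    return out.reset_index()


def _weekly_frame(
    daily: pd.DataFrame, param2: int, study: StudyWindow
) -> pd.DataFrame:
    cols = [
        "animal_id", "week_index", "n_days", "n_records", "total_minutes", *GASES,
    ]
    if daily.empty:
        return pd.DataFrame(columns=cols)
    daily = daily.copy()
    daily["week_index"] = daily["date"].map(study.week_index)
    keys = [daily["animal_id"], daily["week_index"]]
    out = daily.groupby(["animal_id", "week_index"], sort=True).agg(
        n_days=("date", "nunique"),
        n_records=("n_records", "sum"),
        total_minutes=("total_minutes", "sum"),
    )
    w = daily["total_minutes"]
    for g in GASES:
        v = daily[g]
        part = pd.DataFrame({"wv": v * w, "w": w.where(v.notna())})
        sums = part.groupby(keys).sum(min_count=1)
        out[g] = sums["wv"] / sums["w"]
    out = out[out["n_days"] >= param2]
    return out.reset_index()


def _frame_to_daily(df: pd.DataFrame) -> list[DailyAverage]:
    return [
        DailyAverage(
            animal_id=row.animal_id,
            date=row.date,
            n_records=int(row.n_records),
            total_minutes=float(row.total_minutes),
            gas_mean={
                g: float(getattr(row, g))
                for g in GASES
                if not pd.isna(getattr(row, g))
            },
        )
        for row in df.itertuples(index=False)
    ]


def _frame_to_weekly(df: pd.DataFrame) -> list[WeeklyAverage]:
    return [
        WeeklyAverage(
            animal_id=row.animal_id,
            week_index=int(row.week_index),
            n_days=int(row.n_days),
            n_records=int(row.n_records),
            total_minutes=float(row.total_minutes),
            gas_mean={
                g: float(getattr(row, g))
                for g in GASES
                if not pd.isna(getattr(row, g))
            },
        )
        for row in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def filter_min_time(
    records: Sequence[VisitRecord], min_time: float
) -> list[VisitRecord]:
    """Keep records whose usable duration is >= ``min_time`` minutes (inclusive)."""
    return [r for r in records if r.good_duration_min >= min_time]


def remove_gas_outliers(
    records: Sequence[VisitRecord], outlier_k: float = 3.0
) -> list[VisitRecord]:
    """Mask per-gas values outside mean +/- k*SD; drop all-missing records.

    Statistics are computed once, globally per gas, over all non-missing
    values; a record can lose one gas and keep another.  With fewer than
    two values the SD is undefined and nothing is masked for that gas.
    """
    stats: dict[str, tuple[float, float]] = {}
    for g in GASES:
        vals = [r.gas[g] for r in records if g in r.gas]
        if len(vals) < 2:
            continue
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1))
        stats[g] = (mean, sd)
    out: list[VisitRecord] = []
    for r in records:
        gas = {
            g: v
            for g, v in r.gas.items()
            if g not in stats
            or abs(v - stats[g][0]) <= outlier_k * stats[g][1]
        }
        if gas:
            out.append(
                VisitRecord(
                    animal_id=r.animal_id,
                    unit_id=r.unit_id,
                    start_time=r.start_time,
                    end_time=r.end_time,
                    good_duration_min=r.good_duration_min,
                    gas=gas,
                )
            )
    return out


def daily_averages(
    records: Sequence[VisitRecord], param1: int
) -> list[DailyAverage]:
    """Duration-weighted daily means per animal and calendar date.

    Per gas, the weight is the record's usable minutes and only records
    with that gas present contribute; the animal-day is emitted only when
    it holds at least ``param1`` records.  A gas with no valid values in
    the group is missing from ``gas_mean``, never 0.
    """
    return _frame_to_daily(_daily_frame(visits_to_frame(records), param1))


def weekly_averages(
    daily: Sequence[DailyAverage], param2: int, study: StudyWindow
) -> list[WeeklyAverage]:
    """Minute-weighted weekly means of the daily means.

    Weeks are consecutive 7-day blocks anchored at the study start date
    (``week_index = (date - start) // 7 + 1``), so a 46-day trial has 7
    study weeks.  Each day's weight is its total retained visit minutes;
    the animal-week is emitted only with >= ``param2`` distinct days.
    """
    rows = [
        {
            "animal_id": d.animal_id,
            "date": d.date,
            "n_records": d.n_records,
            "total_minutes": d.total_minutes,
            **{g: d.gas_mean.get(g, np.nan) for g in GASES},
        }
        for d in daily
    ]
    df = pd.DataFrame(
        rows, columns=["animal_id", "date", "n_records", "total_minutes", *GASES]
    )
    return _frame_to_weekly(_weekly_frame(df, param2, study))


def process(
    records: Sequence[VisitRecord],
    params: ProcessParams,
    study: StudyWindow,
) -> ProcessResult:
    """Run the full pipeline; also tallies record counts at each stage."""
    counts = {"records_in": len(records)}
    kept = filter_min_time(records, params.min_time)
    counts["after_min_time"] = len(kept)
    kept = remove_gas_outliers(kept, params.outlier_k)
    counts["after_outlier_removal"] = len(kept)
    daily = daily_averages(kept, params.param1)
    counts["daily_rows"] = len(daily)
    weekly = weekly_averages(daily, params.param2, study)
    counts["weekly_rows"] = len(weekly)
    return ProcessResult(daily=daily, weekly=weekly, counts=counts)


def summarize_gas(values: Sequence[float], gas: str = "CH4") -> GasSummary:
    """n, mean, sample SD, CV% and range of a set of gas values.

    A single value has undefined sample SD; it is reported as 0 (not
    missing) so report tables stay total.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("summarize_gas requires at least one value")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    cv = 100.0 * sd / mean if mean > 0 else 0.0
    return GasSummary(
        gas=gas,
        n=int(vals.size),
        mean=mean,
        sd=sd,
        cv=cv,
        min=float(vals.min()),
        max=float(vals.max()),
    )


def param_grid(
    records: Sequence[VisitRecord],
    param1_set: Sequence[int],
    param2_set: Sequence[int],
    min_time_set: Sequence[float],
    study: StudyWindow,
    gas: str = "CH4",
    outlier_k: float = 3.0,
) -> list[GridRow]:
    """Retention and phenotype means over the full parameter grid.

    For each (param1, param2, min_time) combination: the number of daily
    rows, animals with at least one daily row, the mean +/- SD of the
    daily ``gas`` phenotype across daily rows, and the weekly analogues.
    Cells with no weekly rows report missing means.
    """
    if not (len(param1_set) and len(param2_set) and len(min_time_set)):
        raise ValueError("parameter sets must be non-empty")
    base = visits_to_frame(records)
    rows: list[GridRow] = []
    for min_time in min_time_set:
        if min_time < MIN_VALID_DURATION_MIN:
            raise ValueError("min_time must be at least 2 min")
        masked = _mask_outliers_frame(
            base[base["good_duration_min"] >= min_time], outlier_k
        )
        for p1 in param1_set:
            daily = _daily_frame(masked, p1)
            d_vals = daily[gas].dropna() if not daily.empty else pd.Series(dtype=float)
            d_mean = float(d_vals.mean()) if len(d_vals) else None
            d_sd = (
                float(d_vals.std(ddof=1))
                if len(d_vals) > 1
                else (0.0 if len(d_vals) == 1 else None)
            )
            for p2 in param2_set:
                weekly = _weekly_frame(daily, p2, study)
                w_vals = (
                    weekly[gas].dropna() if not weekly.empty else pd.Series(dtype=float)
                )
                w_mean = float(w_vals.mean()) if len(w_vals) else None
                w_sd = (
                    float(w_vals.std(ddof=1))
                    if len(w_vals) > 1
                    else (0.0 if len(w_vals) == 1 else None)
                )
                rows.append(
                    GridRow(
                        param1=int(p1),
                        param2=int(p2),
                        min_time=float(min_time),
                        n_daily_records=int(len(daily)),
                        n_animals_daily=(
                            int(daily["animal_id"].nunique()) if not daily.empty else 0
                        ),
                        daily_mean=d_mean,
                        daily_sd=d_sd,
                        n_weekly_records=int(len(weekly)),
                        n_animals_weekly=(
                            int(weekly["animal_id"].nunique())
                            if not weekly.empty
                            else 0
                        ),
                        weekly_mean=w_mean,
                        weekly_sd=w_sd,
                    )
                )
    return rows


def grid_correlation(
    grid: Sequence[GridRow], x: str, y: str
) -> float | None:
    """Pearson correlation of grid column ``y`` against parameter ``x``.

    Rows with a missing/non-finite ``y`` are excluded; with fewer than 3
    usable rows or zero variance on either axis the correlation is
    undefined and None is returned.
    """
    xs, ys = [], []
    for row in grid:
        yv = getattr(row, y)
        if yv is None or not math.isfinite(float(yv)):
            continue
        xs.append(float(getattr(row, x)))
        ys.append(float(yv))
    if len(xs) < 3:
        return None
    if np.std(xs) == 0 or np.std(ys) == 0:
        return None
    return float(sps.pearsonr(xs, ys).statistic)
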