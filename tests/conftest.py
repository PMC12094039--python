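import dataclasses
import datetime as dt

import pytest

from greenfeedtools import StudyWindow, VisitRecord, default_config, simulate_trial


@pytest.fixture(scope="session")
def paper_cfg():
    """Default paper_like profile: 32 animals, 46 days, one unit."""
    return default_config("paper_like", seed=0)


@pytest.fixture(scope="session")
def paper_trial(paper_cfg):
    """One simulated trial under the paper_like profile."""
    return simulate_trial(paper_cfg)


@pytest.fixture(scope="session")
def big_trial(paper_cfg):
    """~50k records: many animals so record-level moments are estimable."""
    cfg = dataclasses.replace(
        paper_cfg, n_animals=300, n_days=30, visit_rate_per_day=5.6, seed=7
    )
    return simulate_trial(cfg)


def make_record(
    animal="A1",
    unit="GF1",
    start="2024-01-15 08:00:00",
    duration_min=3.0,
    gas=None,
):
    """Hand-build a valid VisitRecord for targeted unit tests."""
    t0 = dt.datetime.fromisoformat(start)
    return VisitRecord(
        animal_id=animal,
        unit_id=unit,
        start_time=t0,
        end_time=t0 + dt.timedelta(minutes=duration_min + 1),
        good_duration_min=duration_min,
        gas=dict(gas or {}),
    )


@pytest.fixture
def week_window():
    return StudyWindow(dt.date(2024, 1, 15), dt.date(2024, 1, 21))
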