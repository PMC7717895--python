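"""Shared fixtures: fixture regions, toy event streams, small simulations."""

from __future__ import annotations

from datetime import datetime, timezone

import pandas as pd
import pytest

from geomobility.ingest import GeoEvent, Provenance
from geomobility.regions import RegionSet
from geomobility.simulate import SimConfig, default_fixture_regions, simulate_checkins


def ts(s: str) -> datetime:
    return datetime.fromisoformat(s).replace(tzinfo=timezone.utc)


def ev(user: str, when: str, lat: float, lon: float) -> GeoEvent:
    return GeoEvent(user, ts(when), lat, lon, Provenance.EXACT)


def events_frame(events) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.user_id, e.timestamp, e.lat, e.lon) for e in events],
        columns=["user_id", "timestamp", "lat", "lon"],
    )


@pytest.fixture(scope="session")
def fixture_regions() -> RegionSet:
    return default_fixture_regions()


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated collection shared across tests (seeded)."""
    cfg = SimConfig(n_users=60, seed=424242)
    lines, truth = simulate_checkins(cfg)
    return cfg, lines, truth


@pytest.fixture
def toy_filter_stream():
    """Hand-countable stream for the sparse-data filters.

    Users: A has 5 events in week 2020-03-02 and 2 in week 2020-03-09;
    B has 2 events total; C has 3 events in one week; D has 4 + 3 events
    in two weeks; E has 1 event. Surviving the >=3-overall filter:
    A, C, D (3 users). Surviving user-weeks: A/03-02, C/03-02, D/03-09,
    D/03-16 (4 records).
    """
    base_lat, base_lon = 39.0, -76.6
    events = []
    # A: 5 in week of 2020-03-02, 2 in week of 2020-03-09
    for i in range(5):
        events.append(ev("A", f"2020-03-0{2 + i}T12:00:00", base_lat + 0.01 * i, base_lon))
    events.append(ev("A", "2020-03-09T12:00:00", base_lat, base_lon))
    events.append(ev("A", "2020-03-10T12:00:00", base_lat, base_lon))
    # B: 2 events total
    events.append(ev("B", "2020-03-03T09:00:00", base_lat, base_lon))
    events.append(ev("B", "2020-03-04T09:00:00", base_lat, base_lon))
    # C: exactly 3 in one week
    for i in range(3):
        events.append(ev("C", f"2020-03-0{3 + i}T10:00:00", base_lat, base_lon + 0.02 * i))
    # D: 4 in week of 2020-03-09, 3 in week of 2020-03-16
    for i in range(4):
        events.append(ev("D", f"2020-03-{9 + i:02d}T11:00:00", base_lat - 0.01 * i, base_lon))
    for i in range(3):
        events.append(ev("D", f"2020-03-{16 + i:02d}T11:00:00", base_lat, base_lon - 0.01 * i))
    # E: singleton
    events.append(ev("E", "2020-03-05T08:00:00", base_lat, base_lon))
    return events_frame(events)
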