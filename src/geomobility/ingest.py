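"""Reading Twitter-like JSONL event streams and resolving locations.

Each newline-delimited JSON record mirrors the public Twitter object
subset: ``user.id``, ``created_at`` (ISO-8601 UTC), an optional
``coordinates.coordinates`` pair in GeoJSON ``[lon, lat]`` order, and an
optional ``place`` object (id, place_type, name, country_code,
bounding_box). Exact coordinates always take precedence over the place;
a place resolves to the midpoint of its bounding box, subject to
analysis-level rules: state-level analyses drop point-of-interest and
neighborhood places (their state is not recoverable from the metadata),
while city-level analyses keep a POI/neighborhood only when the city name
occurs in the place name or the place id is explicitly whitelisted (used
to merge the five New York City boroughs into the city).
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from enum import Enum
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional

logger = logging.getLogger(__name__)

PLACE_TYPES = frozenset({"poi", "neighborhood", "city", "admin", "country"})


class Provenance(str, Enum):
    EXACT = "exact"
    PLACE_CENTER = "place_center"


class Level(str, Enum):
    NATIONAL = "national"
    STATE = "state"
    CITY = "city"


@dataclass(frozen=True)
class PlaceInfo:
    """Named location attached to an event, with its bounding box."""

    place_id: str
    place_type: str
    name: str
    country: str
    bounding_box: tuple[tuple[float, float], ...]  # (lon, lat) corners

    def __post_init__(self):
        if self.place_type not in PLACE_TYPES:
            raise ValueError(f"unknown place_type {self.place_type!r}")


@dataclass(frozen=True)
class RawEvent:
    """One parsed stream record before location resolution."""

    user_id: str
    timestamp: datetime
    coordinates: Optional[tuple[float, float]] = None  # (lon, lat)
    place: Optional[PlaceInfo] = None


@dataclass(frozen=True)
class GeoEvent:
    """A record resolved to a single point."""

    user_id: str
    timestamp: datetime
    lat: float
    lon: float
    provenance: Provenance

    def __post_init__(self):
        if not (-90.0 <= self.lat <= 90.0 and -180.0 <= self.lon <= 180.0):
            raise ValueError(f"invalid coordinates ({self.lat}, {self.lon})")


@dataclass
class AnalysisLevel:
    """Geographic level of the analysis plus city-matching configuration."""

    level: Level = Level.NATIONAL
    city_name: Optional[str] = None
    extra_place_ids: frozenset[str] = frozenset()
    country: Optional[str] = None  # keep only places from this country code

    def __post_init__(self):
        self.level = Level(self.level)
        if self.level is Level.CITY and not self.city_name:
            raise ValueError("city-level analysis requires city_name")


@dataclass
class StreamStats:
    """Counters accumulated while parsing a stream."""

    lines: int = 0
    parsed: int = 0
    skipped_malformed: int = 0
    skipped_no_location: int = 0


def _parse_timestamp(value: str) -> datetime:
    ts = datetime.fromisoformat(value.replace("Z", "+00:00"))
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return ts.astimezone(timezone.utc)


def _parse_place(obj: dict) -> PlaceInfo:
    bb = obj["bounding_box"]
    coords = bb["coordinates"] if isinstance(bb, dict) else bb
    if isinstance(coords[0][0], (list, tuple)):  # GeoJSON polygon nesting
        coords = coords[0]
    corners = tuple((float(lon), float(lat)) for lon, lat in coords)
    return PlaceInfo(
        place_id=str(obj["id"]),
        place_type=str(obj["place_type"]),
        name=str(obj.get("name", "")),
        country=str(obj.get("country_code", obj.get("country", ""))),
        bounding_box=corners,
    )


def _parse_line(line: str) -> Optional[RawEvent]:
    obj = json.loads(line)
    user = obj.get("user", {})
    user_id = str(user["id"]) if isinstance(user, dict) else str(user)
    ts = _parse_timestamp(obj["created_at"])
    coords = None
    raw_coords = obj.get("coordinates")
    if raw_coords:
        pair = raw_coords["coordinates"] if isinstance(raw_coords, dict) else raw_coords
        coords = (float(pair[0]), float(pair[1]))
    place = _parse_place(obj["place"]) if obj.get("place") else None
    if coords is None and place is None:
        return None
    return RawEvent(user_id=user_id, timestamp=ts, coordinates=coords, place=place)


def parse_event_stream(
    source: str | Path | IO[str],
    stats: Optional[StreamStats] = None,
) -> Iterator[RawEvent]:
    """Lazily yield :class:`RawEvent` per parseable JSONL line.

    Malformed lines and lines with neither coordinates nor place are
    counted in ``stats`` and skipped; the stream is never fully loaded
    into memory. An unreadable path raises the underlying OSError.
    """
    if stats is None:
        stats = StreamStats()

    def _iter(fh: Iterable[str]) -> Iterator[RawEvent]:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            stats.lines += 1
            try:
                event = _parse_line(line)
            except (json.JSONDecodeError, KeyError, ValueError, TypeError, IndexError):
                stats.skipped_malformed += 1
                continue
            if event is None:
                stats.skipped_no_location += 1
                continue
            stats.parsed += 1
            yield event
        logger.info(
            "parsed %d events (%d malformed, %d without location)",
            stats.parsed, stats.skipped_malformed, stats.skipped_no_location,
        )

    if hasattr(source, "read"):
        return _iter(source)

    def _from_path() -> Iterator[RawEvent]:
        with open(source, "r", encoding="utf-8") as fh:
            yield from _iter(fh)

    return _from_path()


def place_center(bounding_box) -> tuple[float, float]:
    """Midpoint ``(lat, lon)`` of a bounding box's lon/lat extents.

    Degenerate (point) boxes return that point. Boxes spanning the
    antimeridian are rejected.
    """
    lons = [c[0] for c in bounding_box]
    lats = [c[1] for c in bounding_box]
    if max(lons) - min(lons) > 180.0:
        raise ValueError("bounding box spans the antimeridian")
    return ((min(lats) + max(lats)) / 2.0, (min(lons) + max(lons)) / 2.0)


@dataclass(frozen=True)
class Excluded:
    """Sentinel for an event excluded during resolution, with a reason."""

    reason: str


def resolve_location(event: RawEvent, level: AnalysisLevel) -> GeoEvent | Excluded:
    """Resolve one event to a point or exclude it.

    Exact coordinates always win (``provenance=exact``, bit-identical to
    the input). Otherwise the place's box center is used, subject to the
    level rules described in the module docstring and an optional country
    filter.
    """
    if event.coordinates is not None:
        lon, lat = event.coordinates
        return GeoEvent(event.user_id, event.timestamp, lat, lon, Provenance.EXACT)
    place = event.place
    if place is None:
        return Excluded("no geolocation fields")
    if level.country is not None and place.country and place.country != level.country:
        return Excluded(f"country {place.country!r} filtered")
    if place.place_type in ("poi", "neighborhood"):
        if level.level is Level.STATE:
            return Excluded(f"{place.place_type} place at state level")
        if level.level is Level.CITY:
            name_match = level.city_name.lower() in place.name.lower()
            if not name_match and place.place_id not in level.extra_place_ids:
                return Excluded(f"{place.place_type} place not matching city")
    lat, lon = place_center(place.bounding_box)
    return GeoEvent(event.user_id, event.timestamp, lat, lon, Provenance.PLACE_CENTER)


def resolve_stream(
    events: Iterable[RawEvent],
    level: AnalysisLevel,
    counters: Optional[dict] = None,
) -> Iterator[GeoEvent]:
    """Resolve a stream of events, dropping exclusions.

    ``counters``, if given, accumulates ``resolved``, ``excluded`` and
    per-reason exclusion counts.
    """
    for event in events:
        out = resolve_location(event, level)
        if isinstance(out, GeoEvent):
            if counters is not None:
                counters["resolved"] = counters.get("resolved", 0) + 1
            yield out
        elif counters is not None:
            counters["excluded"] = counters.get("excluded", 0) + 1
            counters[out.reason] = counters.get(out.reason, 0) + 1


RESOLVED_COLUMNS = ["user_id", "timestamp", "lat", "lon", "provenance"]


def write_resolved_csv(events: Iterable[GeoEvent], path: str | Path) -> int:
    """Write resolved events as CSV; returns the number of rows written."""
    n = 0
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(RESOLVED_COLUMNS)
        for ev in events:
            writer.writerow(
                [ev.user_id, ev.timestamp.isoformat(), repr(ev.lat), repr(ev.lon), ev.provenance.value]
            )
            n += 1
    return n


def read_resolved_csv(path: str | Path) -> Iterator[GeoEvent]:
    """Read back a resolved-events CSV written by :func:`write_resolved_csv`."""
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            yield GeoEvent(
                user_id=row["user_id"],
                timestamp=_parse_timestamp(row["timestamp"]),
                lat=float(row["lat"]),
                lon=float(row["lon"]),
                provenance=Provenance(row["provenance"]),
            )
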