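"""Region assignment: users mapped to areas from their all-time centroid.

Regions are polygons (GeoJSON FeatureCollection, lon/lat order) and a
user belongs to the first region containing their all-time centroid.
Assignment happens once per user for the whole study — a user who moves
is attributed to a single region throughout. Boundary points count as
inside; a point on a shared edge goes to the lexicographically smallest
region_id so assignment stays deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from shapely.geometry import Point, shape
from shapely.prepared import prep
from shapely.validation import explain_validity

UNASSIGNED = None


@dataclass
class RegionSet:
    """Ordered set of named region polygons at one analysis level."""

    regions: list  # (region_id, name, shapely geometry), sorted by region_id
    level: str = "state"

    @classmethod
    def from_geojson(cls, source: str | Path | dict, level: str = "state") -> "RegionSet":
        """Load a FeatureCollection with ``region_id``/``name`` properties.

        Invalid polygons are a fatal load-time error, never a query-time
        one.
        """
        if isinstance(source, (str, Path)):
            with open(source, "r", encoding="utf-8") as fh:
                obj = json.load(fh)
        else:
            obj = source
        regions = []
        seen = set()
        for feat in obj["features"]:
            props = feat.get("properties", {})
            rid = str(props.get("region_id", props.get("id", "")))
            if not rid:
                raise ValueError("feature missing region_id property")
            if rid in seen:
                raise ValueError(f"duplicate region_id {rid!r}")
            seen.add(rid)
            geom = shape(feat["geometry"])
            if not geom.is_valid:
                raise ValueError(
                    f"invalid geometry for region {rid!r}: {explain_validity(geom)}"
                )
            regions.append((rid, str(props.get("name", rid)), geom))
        regions.sort(key=lambda r: r[0])
        return cls(regions=regions, level=level)

    def region_ids(self) -> list[str]:
        return [rid for rid, _, _ in self.regions]


def assign_region(centroid: tuple[float, float], regions: RegionSet):
    """Region id containing a ``(lat, lon)`` centroid, or ``UNASSIGNED``.

    Containment includes the boundary; ties on shared edges resolve to
    the lexicographically smallest region_id because regions are scanned
    in sorted order.
    """
    lat, lon = centroid
    pt = Point(lon, lat)
    for rid, _, geom in regions.regions:
        if geom.covers(pt):
            return rid
    return UNASSIGNED


def assign_users(users, regions: RegionSet) -> dict:
    """Map every user to a region from their all-time centroid.

    ``users`` is the ``users`` frame from
    :func:`~geomobility.mobility.build_user_weeks`. Users whose centroid
    falls outside every region are omitted from the returned dict.
    """
    prepared = [(rid, prep(geom)) for rid, _, geom in regions.regions]
    out = {}
    for row in users.itertuples(index=False):
        pt = Point(row.centroid_lon, row.centroid_lat)
        for rid, pgeom in prepared:
            # prepared intersects == covers for points (boundary inclusive)
            if pgeom.intersects(pt):
                out[row.user_id] = rid
                break
    return out
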