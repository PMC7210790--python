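"""Great-circle and local planar geometry primitives.

All other modules build on this one: spherical (haversine) distances for
crow-flies travel, point-in-polygon tests for assigning locations to health
trusts, and segment/disk intersection for enforcing no-fly zones on drone
flight paths.

Coordinates are WGS84 decimal degrees.  Distances are kilometres on a
sphere; the default radius is 6356 km (the polar radius), overridable via
:class:`EarthModel`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from shapely.geometry import Point as _ShapelyPoint
from shapely.geometry import Polygon as _ShapelyPolygon

__all__ = [
    "GeoPoint",
    "EarthModel",
    "Disk",
    "haversine_km",
    "point_in_polygon",
    "segment_intersects_disk",
    "nearest_facility",
]


@dataclass(frozen=True)
class GeoPoint:
    """A latitude/longitude pair in decimal degrees (WGS84)."""

    lat_deg: float
    lon_deg: float

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lat_deg <= 90.0):
            raise ValueError(f"latitude out of range [-90, 90]: {self.lat_deg}")
        if not (-180.0 <= self.lon_deg <= 180.0):
            raise ValueError(f"longitude out of range [-180, 180]: {self.lon_deg}")


@dataclass(frozen=True)
class EarthModel:
    """Spherical earth model.  Default radius 6356 km (polar radius)."""

    radius_km: float = 6356.0

    def __post_init__(self) -> None:
        if self.radius_km <= 0:
            raise ValueError("earth radius must be positive")


#: Module-wide default earth model.
WGS84_SPHERE = EarthModel()


@dataclass(frozen=True)
class Disk:
    """A circular zone on the ground: centre plus radius in km.

    Used for no-fly zones (default 5 km radius around restricted sites)
    and for residential areas within a trust.
    """

    center: GeoPoint
    radius_km: float

    def __post_init__(self) -> None:
        if self.radius_km <= 0:
            raise ValueError("disk radius must be positive")


def haversine_km(a: GeoPoint, b: GeoPoint, earth: EarthModel = WGS84_SPHERE) -> float:
    """Great-circle distance between two points, in km.

    d = 2 r arcsin( sqrt( sin^2(dphi/2) + cos(phi1) cos(phi2) sin^2(dlam/2) ) )

    Symmetric, non-negative and bounded by pi*r (the antipodal distance).
    """
    phi1 = math.radians(a.lat_deg)
    phi2 = math.radians(b.lat_deg)
    dphi = phi2 - phi1
    dlam = math.radians(b.lon_deg) - math.radians(a.lon_deg)
    h = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2.0) ** 2
    # clamp against rounding so asin never sees > 1
    h = min(1.0, max(0.0, h))
    return 2.0 * earth.radius_km * math.asin(math.sqrt(h))


def point_in_polygon(p: GeoPoint, polygon: Sequence[GeoPoint]) -> bool:
    """True iff ``p`` lies inside or on the boundary of the closed ring.

    The ring may be given open (first vertex not repeated) or closed;
    it must contain at least 3 distinct vertices.  Boundary points count
    as inside.
    """
    ring = [(v.lon_deg, v.lat_deg) for v in polygon]
    if len({(round(x, 12), round(y, 12)) for x, y in ring}) < 3:
        raise ValueError("polygon needs at least 3 distinct vertices")
    poly = _ShapelyPolygon(ring)
    return bool(poly.covers(_ShapelyPoint(p.lon_deg, p.lat_deg)))


def _local_xy(p: GeoPoint, origin: GeoPoint, earth: EarthModel) -> tuple[float, float]:
    """Equirectangular projection of ``p`` into a km plane centred on ``origin``.

    Valid for extents small relative to the earth radius (no-fly radii of a
    few km, drone ranges of ~12 km), which is the regime this model works in.
    """
    kx = earth.radius_km * math.radians(1.0) * math.cos(math.radians(origin.lat_deg))
    ky = earth.radius_km * math.radians(1.0)
    return ((p.lon_deg - origin.lon_deg) * kx, (p.lat_deg - origin.lat_deg) * ky)


def segment_intersects_disk(
    a: GeoPoint, b: GeoPoint, zone: Disk, earth: EarthModel = WGS84_SPHERE
) -> bool:
    """True iff the straight path a->b passes within ``zone.radius_km`` of the
    zone centre, in a local planar projection centred on the zone.

    Endpoints inside the disk count as intersecting, so exclusion rules built
    on this test are conservative.
    """
    ax, ay = _local_xy(a, zone.center, earth)
    bx, by = _local_xy(b, zone.center, earth)
    # distance from origin (zone centre) to segment [A, B]
    dx, dy = bx - ax, by - ay
    seg2 = dx * dx + dy * dy
    if seg2 == 0.0:
        d2 = ax * ax + ay * ay
    else:
        t = max(0.0, min(1.0, -(ax * dx + ay * dy) / seg2))
        cx, cy = ax + t * dx, ay + t * dy
        d2 = cx * cx + cy * cy
    return d2 <= zone.radius_km * zone.radius_km


def nearest_facility(
    p: GeoPoint,
    facilities: Sequence,
    earth: EarthModel = WGS84_SPHERE,
) -> tuple[str, float]:
    """Return ``(facility_id, distance_km)`` of the facility nearest to ``p``.

    Facilities are any objects with ``facility_id`` and ``location``
    attributes.  Ties are broken by the lexicographically lowest id so the
    result is deterministic.
    """
    if not facilities:
        raise ValueError("facility list is empty")
    best_id, best_d = None, math.inf
    for f in facilities:
        d = haversine_km(p, f.location, earth)
        if d < best_d or (d == best_d and (best_id is None or f.facility_id < best_id)):
            best_id, best_d = f.facility_id, d
    return best_id, best_d
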