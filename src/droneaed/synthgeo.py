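"""Synthetic study regions and a parametric road-travel-time model.

The real study consumed proprietary geodata for Northern Ireland: five
Health and Social Care trust boundaries with population densities,
ambulance stations, publicly accessible AEDs, and civic facilities
(police/fire stations, hospitals, GP clinics) serving as candidate drone
bases, plus a commercial travel-time API.  None of that is redistributable,
so this module generates a synthetic region with the same structure —
trust polygons tiling a bounding box, residential areas, facilities of the
three kinds, circular no-fly zones — and replaces API travel times with a
parametric model: crow-flies distance x circuity factor / congestion-adjusted
speed.

Regions round-trip through GeoJSON (trusts, residential centres, no-fly
zones) plus a facilities CSV, so user-supplied real data in the same
schemas can be substituted for the generator.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from shapely.geometry import MultiPoint, Point as _SPoint, Polygon as _SPolygon, box as _sbox
from shapely.ops import voronoi_diagram

from .geo import Disk, EarthModel, GeoPoint, WGS84_SPHERE, haversine_km, point_in_polygon

__all__ = [
    "Trust",
    "Facility",
    "Region",
    "RoadModel",
    "RegionConfig",
    "generate_region",
    "road_time_min",
    "region_to_geojson",
    "region_from_geojson",
    "facilities_to_csv",
    "facilities_from_csv",
]

FACILITY_KINDS = ("ambulance_station", "public_aed", "candidate_base")


@dataclass(frozen=True)
class Trust:
    """One health trust: polygon, population density, habitable areas."""

    trust_id: str
    name: str
    polygon: tuple[GeoPoint, ...]
    population_density: float  # persons per km^2
    residential_centers: tuple[Disk, ...]

    def __post_init__(self) -> None:
        if self.population_density <= 0:
            raise ValueError("population density must be positive")
        if len(self.polygon) < 3:
            raise ValueError("trust polygon needs at least 3 vertices")

    def contains(self, p: GeoPoint) -> bool:
        return point_in_polygon(p, self.polygon)


@dataclass(frozen=True)
class Facility:
    facility_id: str
    kind: str
    location: GeoPoint

    def __post_init__(self) -> None:
        if self.kind not in FACILITY_KINDS:
            raise ValueError(f"unknown facility kind: {self.kind!r}")


@dataclass(frozen=True)
class Region:
    """Trusts + facilities + no-fly zones + earth model: the simulation arena."""

    trusts: tuple[Trust, ...]
    facilities: tuple[Facility, ...]
    no_fly_zones: tuple[Disk, ...] = ()
    earth: EarthModel = WGS84_SPHERE

    def __post_init__(self) -> None:
        if not self.trusts:
            raise ValueError("region needs at least one trust")
        ids = [f.facility_id for f in self.facilities]
        if len(ids) != len(set(ids)):
            raise ValueError("facility ids must be unique")
        if not self.of_kind("candidate_base"):
            raise ValueError("region needs at least one candidate drone base")

    def of_kind(self, kind: str) -> tuple[Facility, ...]:
        return tuple(f for f in self.facilities if f.kind == kind)

    @property
    def ambulance_stations(self) -> tuple[Facility, ...]:
        return self.of_kind("ambulance_station")

    @property
    def public_aeds(self) -> tuple[Facility, ...]:
        return self.of_kind("public_aed")

    @property
    def candidate_bases(self) -> tuple[Facility, ...]:
        return self.of_kind("candidate_base")

    def trust_by_id(self, trust_id: str) -> Trust:
        for t in self.trusts:
            if t.trust_id == trust_id:
                return t
        raise KeyError(trust_id)


# Hour-of-day congestion multipliers (>= 1): free flow overnight, morning and
# evening commuter peaks.  Stand-in for live traffic data; fully configurable.
DEFAULT_HOURLY_MULTIPLIER = (
    1.00, 1.00, 1.00, 1.00, 1.00, 1.05,  # 00-05
    1.15, 1.35, 1.50, 1.30, 1.15, 1.10,  # 06-11
    1.15, 1.15, 1.10, 1.20, 1.35, 1.50,  # 12-17
    1.35, 1.15, 1.05, 1.00, 1.00, 1.00,  # 18-23
)


@dataclass(frozen=True)
class RoadModel:
    """Parametric driving-time model.

    ``circuity`` is the road-to-crow-flies distance ratio (1.3 is a standard
    stylized fact for road networks); ``base_speed_kmh`` is free-flow driving
    speed; ``hourly_multiplier`` divides speed by hour of day to mimic
    congestion.
    """

    circuity: float = 1.3
    base_speed_kmh: float = 50.0
    hourly_multiplier: tuple[float, ...] = DEFAULT_HOURLY_MULTIPLIER

    def __post_init__(self) -> None:
        if self.circuity < 1.0:
            raise ValueError("circuity must be >= 1")
        if self.base_speed_kmh <= 0:
            raise ValueError("base speed must be positive")
        if len(self.hourly_multiplier) != 24 or any(m < 1.0 for m in self.hourly_multiplier):
            raise ValueError("hourly_multiplier needs 24 values, all >= 1")


def road_time_min(
    a: GeoPoint,
    b: GeoPoint,
    hour: int,
    model: RoadModel,
    earth: EarthModel = WGS84_SPHERE,
) -> float:
    """Driving time in minutes between two points at a given hour of day."""
    if not (0 <= int(hour) <= 23) or int(hour) != hour:
        raise ValueError(f"hour must be an integer in 0..23, got {hour!r}")
    d_road = haversine_km(a, b, earth) * model.circuity
    speed = model.base_speed_kmh / model.hourly_multiplier[int(hour)]
    return 60.0 * d_road / speed


# ---------------------------------------------------------------------------
# Region generation
# ---------------------------------------------------------------------------

# Stylized per-trust densities (persons/km^2) loosely shaped like a region
# with one dense urban trust and several sparse rural ones.
DEFAULT_DENSITIES = (2570.0, 164.0, 89.0, 131.0, 178.0)


@dataclass(frozen=True)
class RegionConfig:
    """Parameters of the synthetic-region generator.

    The bounding box defaults to roughly the extent of Northern Ireland.
    Facility counts are desk-scale stand-ins for the real inventories
    (the real study had 242 candidate bases); all are configurable.
    """

    lat_min: float = 54.0
    lat_max: float = 55.3
    lon_min: float = -8.2
    lon_max: float = -5.4
    n_trusts: int = 5
    densities: tuple[float, ...] | None = None  # per-trust; default stylized
    residential_centers_per_trust: int = 8
    residential_radius_km: float = 2.5
    n_ambulance_stations: int = 30
    n_public_aeds: int = 80
    n_candidate_bases: int = 60
    n_no_fly_zones: int = 2
    no_fly_radius_km: float = 5.0
    earth: EarthModel = WGS84_SPHERE

    def __post_init__(self) -> None:
        if self.n_trusts < 1:
            raise ValueError("need at least one trust")
        if self.n_candidate_bases < 1:
            raise ValueError("need at least one candidate base")
        if min(self.n_ambulance_stations, self.n_public_aeds, self.n_no_fly_zones) < 0:
            raise ValueError("facility counts must be >= 0")
        if self.densities is not None and len(self.densities) != self.n_trusts:
            raise ValueError("densities must have one entry per trust")
        if self.residential_centers_per_trust < 1 and (
            self.n_ambulance_stations or self.n_public_aeds or self.n_candidate_bases
        ):
            raise ValueError("facilities require at least one residential centre per trust")
        if self.lat_min >= self.lat_max or self.lon_min >= self.lon_max:
            raise ValueError("degenerate bounding box")


def _trust_densities(cfg: RegionConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.densities is not None:
        return np.asarray(cfg.densities, dtype=float)
    if cfg.n_trusts <= len(DEFAULT_DENSITIES):
        return np.asarray(DEFAULT_DENSITIES[: cfg.n_trusts], dtype=float)
    # beyond the stylized five: sparse rural-like densities
    extra = rng.uniform(60.0, 250.0, size=cfg.n_trusts - len(DEFAULT_DENSITIES))
    return np.concatenate([np.asarray(DEFAULT_DENSITIES), extra])


def _voronoi_trust_polygons(cfg: RegionConfig, rng: np.random.Generator) -> list[_SPolygon]:
    """Partition the bounding box into n_trusts convex-ish cells."""
    bbox = _sbox(cfg.lon_min, cfg.lat_min, cfg.lon_max, cfg.lat_max)
    if cfg.n_trusts == 1:
        return [bbox]
    # seed points kept away from the box edge so every cell is 2-D
    lats = rng.uniform(cfg.lat_min, cfg.lat_max, size=cfg.n_trusts)
    lons = rng.uniform(cfg.lon_min, cfg.lon_max, size=cfg.n_trusts)
    seeds = MultiPoint([(lo, la) for lo, la in zip(lons, lats)])
    cells = voronoi_diagram(seeds, envelope=bbox)
    # map cells back to seed order so output is deterministic
    ordered: list[_SPolygon] = []
    remaining = list(cells.geoms)
    for pt in seeds.geoms:
        for g in remaining:
            if g.covers(pt):
                ordered.append(g.intersection(bbox))
                remaining.remove(g)
                break
    return ordered


def _sample_in_polygon(poly: _SPolygon, rng: np.random.Generator, max_attempts: int = 10_000) -> GeoPoint:
    minx, miny, maxx, maxy = poly.bounds
    for _ in range(max_attempts):
        x = rng.uniform(minx, maxx)
        y = rng.uniform(miny, maxy)
        if poly.covers(_SPoint(x, y)):
            return GeoPoint(lat_deg=y, lon_deg=x)
    raise RuntimeError("could not sample a point inside the polygon")


def generate_region(config: RegionConfig, seed: int) -> Region:
    """Generate a synthetic :class:`Region`; deterministic for a fixed seed.

    Trust polygons are Voronoi cells around random seed points clipped to
    the bounding box.  Residential centres are random disks inside each
    trust.  Facilities are placed with Gaussian jitter around residential
    centres (density-weighted across trusts, mimicking placement of AEDs in
    high-footfall areas), rejected until they fall inside their trust.
    """
    rng = np.random.default_rng(seed)
    densities = _trust_densities(config, rng)
    polys = _voronoi_trust_polygons(config, rng)

    deg_lat_km = config.earth.radius_km * math.radians(1.0)
    trusts: list[Trust] = []
    for i, (poly, dens) in enumerate(zip(polys, densities)):
        centers = []
        for _ in range(config.residential_centers_per_trust):
            c = _sample_in_polygon(poly, rng)
            centers.append(Disk(center=c, radius_km=config.residential_radius_km))
        ring = tuple(
            GeoPoint(lat_deg=y, lon_deg=x) for x, y in poly.exterior.coords
        )
        trusts.append(
            Trust(
                trust_id=f"T{i + 1}",
                name=f"Trust {i + 1}",
                polygon=ring,
                population_density=float(dens),
                residential_centers=tuple(centers),
            )
        )

    weights = densities / densities.sum()
    facilities: list[Facility] = []
    prefixes = {"ambulance_station": "AMB", "public_aed": "AED", "candidate_base": "CB"}
    counts = {
        "ambulance_station": config.n_ambulance_stations,
        "public_aed": config.n_public_aeds,
        "candidate_base": config.n_candidate_bases,
    }
    for kind in FACILITY_KINDS:
        for j in range(counts[kind]):
            ti = int(rng.choice(len(trusts), p=weights))
            trust, poly = trusts[ti], polys[ti]
            center = trust.residential_centers[int(rng.integers(len(trust.residential_centers)))]
            sigma_deg = (center.radius_km / 2.0) / deg_lat_km
            loc = None
            for _ in range(1000):
                lat = center.center.lat_deg + rng.normal(0.0, sigma_deg)
                lon = center.center.lon_deg + rng.normal(
                    0.0, sigma_deg / math.cos(math.radians(center.center.lat_deg))
                )
                if poly.covers(_SPoint(lon, lat)):
                    loc = GeoPoint(lat_deg=lat, lon_deg=lon)
                    break
            if loc is None:  # pathological geometry: fall back to the centre
                loc = center.center
            facilities.append(
                Facility(facility_id=f"{prefixes[kind]}{j + 1:03d}", kind=kind, location=loc)
            )

    zones = []
    for _ in range(config.n_no_fly_zones):
        lat = rng.uniform(config.lat_min, config.lat_max)
        lon = rng.uniform(config.lon_min, config.lon_max)
        zones.append(Disk(center=GeoPoint(lat, lon), radius_km=config.no_fly_radius_km))

    return Region(
        trusts=tuple(trusts),
        facilities=tuple(facilities),
        no_fly_zones=tuple(zones),
        earth=config.earth,
    )


# ---------------------------------------------------------------------------
# Serialization: GeoJSON (trusts, residential centres, no-fly zones) + CSV
# ---------------------------------------------------------------------------

def region_to_geojson(region: Region) -> dict:
    """Region (minus facilities) as a GeoJSON FeatureCollection.

    Coordinate order is GeoJSON standard: [lon, lat].  Facilities travel
    separately as CSV (see :func:`facilities_to_csv`).
    """
    features: list[dict] = []
    for t in region.trusts:
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [[[p.lon_deg, p.lat_deg] for p in t.polygon]],
                },
                "properties": {
                    "feature_kind": "trust",
                    "trust_id": t.trust_id,
                    "name": t.name,
                    "population_density": t.population_density,
                },
            }
        )
        for d in t.residential_centers:
            features.append(
                {
                    "type": "Feature",
                    "geometry": {
                        "type": "Point",
                        "coordinates": [d.center.lon_deg, d.center.lat_deg],
                    },
                    "properties": {
                        "feature_kind": "residential_center",
                        "trust_id": t.trust_id,
                        "radius_km": d.radius_km,
                    },
                }
            )
    for z in region.no_fly_zones:
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Point",
                    "coordinates": [z.center.lon_deg, z.center.lat_deg],
                },
                "properties": {"feature_kind": "no_fly_zone", "radius_km": z.radius_km},
            }
        )
    return {
        "type": "FeatureCollection",
        "properties": {"earth_radius_km": region.earth.radius_km},
        "features": features,
    }


def region_from_geojson(doc: dict, facilities: Sequence[Facility] = ()) -> Region:
    """Rebuild a Region from :func:`region_to_geojson` output plus facilities."""
    earth = EarthModel(radius_km=doc.get("properties", {}).get("earth_radius_km", 6356.0))
    trusts_raw: dict[str, dict] = {}
    res_centers: dict[str, list[Disk]] = {}
    zones: list[Disk] = []
    for feat in doc["features"]:
        props = feat.get("properties", {})
        kind = props.get("feature_kind")
        geom = feat["geometry"]
        if kind == "trust":
            trusts_raw[props["trust_id"]] = {
                "name": props.get("name", props["trust_id"]),
                "ring": tuple(
                    GeoPoint(lat_deg=lat, lon_deg=lon) for lon, lat in geom["coordinates"][0]
                ),
                "density": float(props["population_density"]),
            }
        elif kind == "residential_center":
            lon, lat = geom["coordinates"]
            res_centers.setdefault(props["trust_id"], []).append(
                Disk(center=GeoPoint(lat, lon), radius_km=float(props["radius_km"]))
            )
        elif kind == "no_fly_zone":
            lon, lat = geom["coordinates"]
            zones.append(Disk(center=GeoPoint(lat, lon), radius_km=float(props["radius_km"])))
    trusts = tuple(
        Trust(
            trust_id=tid,
            name=raw["name"],
            polygon=raw["ring"],
            population_density=raw["density"],
            residential_centers=tuple(res_centers.get(tid, [])),
        )
        for tid, raw in trusts_raw.items()
    )
    return Region(trusts=trusts, facilities=tuple(facilities), no_fly_zones=tuple(zones), earth=earth)


def facilities_to_csv(facilities: Sequence[Facility], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["facility_id", "kind", "lat", "lon"])
        for f in facilities:
            w.writerow([f.facility_id, f.kind, repr(f.location.lat_deg), repr(f.location.lon_deg)])


def facilities_from_csv(path: str | Path) -> tuple[Facility, ...]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                Facility(
                    facility_id=row["facility_id"],
                    kind=row["kind"],
                    location=GeoPoint(float(row["lat"]), float(row["lon"])),
                )
            )
    return tuple(out)


def save_region(region: Region, geojson_path: str | Path, facilities_path: str | Path) -> None:
    with open(geojson_path, "w") as fh:
        json.dump(region_to_geojson(region), fh, indent=1)
    facilities_to_csv(region.facilities, facilities_path)


def load_region(geojson_path: str | Path, facilities_path: str | Path) -> Region:
    with open(geojson_path) as fh:
        doc = json.load(fh)
    return region_from_geojson(doc, facilities_from_csv(facilities_path))
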