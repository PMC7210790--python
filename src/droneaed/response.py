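"""Per-incident response times for the three responder types.

For each simulated cardiac arrest the model computes:

* **ambulance** — blue-light driving time from the nearest ambulance
  station (civilian driving time reduced by 25%);
* **public AED** — a bystander driving from the incident to the nearest
  publicly accessible AED and back (no blue-light reduction);
* **drone** — straight-line flight from the nearest active drone base
  whose path avoids every no-fly zone and whose distance is within the
  drone's range (12 km and 100 km/h by default); unavailable otherwise.

The fastest available responder wins; ties prefer the professional
responder (ambulance, then drone, then public AED).  "Unavailable" is the
``None`` sentinel, never an exception, so network fitness degrades
gracefully when no base is in range.

The scalar functions define the semantics; :class:`ResponseEvaluator`
is a vectorised equivalent used by the genetic algorithm, where the same
incident set is re-scored for thousands of candidate networks.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .geo import Disk, EarthModel, GeoPoint, WGS84_SPHERE, haversine_km, segment_intersects_disk
from .incidents import Incident
from .synthgeo import Facility, Region, RoadModel, road_time_min

__all__ = [
    "DroneSpec",
    "ResponseConfig",
    "ResponseRecord",
    "ambulance_time",
    "aed_time",
    "drone_time",
    "respond",
    "respond_all",
    "mean_response",
    "ResponseEvaluator",
    "records_to_csv",
    "records_from_csv",
]

#: Winner labels in tie-break preference order.
TIE_BREAK_ORDER = ("ambulance", "drone", "public_aed")


@dataclass(frozen=True)
class DroneSpec:
    """AED-carrying drone: cruise speed and maximum one-way range."""

    speed_kmh: float = 100.0
    range_km: float = 12.0

    def __post_init__(self) -> None:
        if self.speed_kmh <= 0 or self.range_km <= 0:
            raise ValueError("drone speed and range must be positive")


@dataclass(frozen=True)
class ResponseConfig:
    """Knobs of the response model.

    ``blue_light_factor`` multiplies the civilian ambulance driving time
    (0.75 = the 25% blue-light reduction).  The per-responder overheads
    (dispatch, take-off, AED deployment, ...) default to zero: the model
    scores travel time only.
    """

    blue_light_factor: float = 0.75
    ambulance_overhead_min: float = 0.0
    aed_overhead_min: float = 0.0
    drone_overhead_min: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.blue_light_factor <= 1):
            raise ValueError("blue_light_factor must be in (0, 1]")
        if min(self.ambulance_overhead_min, self.aed_overhead_min, self.drone_overhead_min) < 0:
            raise ValueError("overheads must be >= 0")


@dataclass(frozen=True)
class ResponseRecord:
    incident_id: int
    ambulance_min: Optional[float]
    aed_min: Optional[float]
    drone_min: Optional[float]
    winner: str
    winner_min: float


def _nearest(p: GeoPoint, facilities: Sequence[Facility], earth: EarthModel) -> tuple[Facility, float]:
    best, best_d = None, np.inf
    for f in facilities:
        d = haversine_km(p, f.location, earth)
        if d < best_d or (d == best_d and best is not None and f.facility_id < best.facility_id):
            best, best_d = f, d
    return best, best_d


def ambulance_time(
    incident: Incident,
    stations: Sequence[Facility],
    road: RoadModel,
    earth: EarthModel = WGS84_SPHERE,
    cfg: ResponseConfig = ResponseConfig(),
) -> Optional[float]:
    """Blue-light driving time (min) from the nearest station, or None."""
    if not stations:
        return None
    st, _ = _nearest(incident.location, stations, earth)
    t = road_time_min(st.location, incident.location, incident.hour, road, earth)
    return cfg.blue_light_factor * t + cfg.ambulance_overhead_min


def aed_time(
    incident: Incident,
    aeds: Sequence[Facility],
    road: RoadModel,
    earth: EarthModel = WGS84_SPHERE,
    cfg: ResponseConfig = ResponseConfig(),
) -> Optional[float]:
    """Bystander round-trip driving time (min) to the nearest AED, or None."""
    if not aeds:
        return None
    aed, _ = _nearest(incident.location, aeds, earth)
    out = road_time_min(incident.location, aed.location, incident.hour, road, earth)
    back = road_time_min(aed.location, incident.location, incident.hour, road, earth)
    return out + back + cfg.aed_overhead_min


def drone_time(
    incident: Incident,
    bases: Sequence[Facility],
    spec: DroneSpec,
    zones: Sequence[Disk] = (),
    earth: EarthModel = WGS84_SPHERE,
    cfg: ResponseConfig = ResponseConfig(),
) -> Optional[float]:
    """Flight time (min) from the nearest usable base, or None.

    A base is usable iff its great-circle distance is within ``range_km``
    (inclusive) and the straight path to the incident crosses no no-fly
    zone.  Bases are considered in increasing distance, so a farther base
    serves when the nearest one is blocked.
    """
    if not bases:
        return None
    by_dist = sorted(
        ((haversine_km(incident.location, b.location, earth), b.facility_id, b) for b in bases)
    )
    for d, _, b in by_dist:
        if d > spec.range_km:
            break  # sorted: every later base is also out of range
        if any(segment_intersects_disk(b.location, incident.location, z, earth) for z in zones):
            continue
        return 60.0 * d / spec.speed_kmh + cfg.drone_overhead_min
    return None


def _pick_winner(times: dict[str, Optional[float]]) -> tuple[str, float]:
    available = [(t, TIE_BREAK_ORDER.index(name), name) for name, t in times.items() if t is not None]
    if not available:
        raise RuntimeError("no responder of any kind is available")
    t, _, name = min(available)
    return name, t


def respond(
    incident: Incident,
    region: Region,
    active_bases: Iterable[str] = (),
    road: RoadModel = RoadModel(),
    spec: DroneSpec = DroneSpec(),
    cfg: ResponseConfig = ResponseConfig(),
) -> ResponseRecord:
    """Score one incident and select the fastest available responder.

    ``active_bases`` is a set of candidate-base facility ids (a drone base
    network); empty means the drone layer is absent — the "before"
    scenario.
    """
    active = set(active_bases)
    bases = [b for b in region.candidate_bases if b.facility_id in active]
    amb = ambulance_time(incident, region.ambulance_stations, road, region.earth, cfg)
    aed = aed_time(incident, region.public_aeds, road, region.earth, cfg)
    drn = (
        drone_time(incident, bases, spec, region.no_fly_zones, region.earth, cfg)
        if bases
        else None
    )
    winner, t = _pick_winner({"ambulance": amb, "public_aed": aed, "drone": drn})
    return ResponseRecord(
        incident_id=incident.incident_id,
        ambulance_min=amb,
        aed_min=aed,
        drone_min=drn,
        winner=winner,
        winner_min=t,
    )


def respond_all(
    incidents: Sequence[Incident],
    region: Region,
    active_bases: Iterable[str] = (),
    road: RoadModel = RoadModel(),
    spec: DroneSpec = DroneSpec(),
    cfg: ResponseConfig = ResponseConfig(),
) -> list[ResponseRecord]:
    return [respond(i, region, active_bases, road, spec, cfg) for i in incidents]


def mean_response(
    incidents: Sequence[Incident],
    region: Region,
    active_bases: Iterable[str] = (),
    road: RoadModel = RoadModel(),
    spec: DroneSpec = DroneSpec(),
    cfg: ResponseConfig = ResponseConfig(),
) -> float:
    """Mean winner time (min) over the incident set — the GA fitness."""
    if not incidents:
        raise ValueError("incident list is empty")
    recs = respond_all(incidents, region, active_bases, road, spec, cfg)
    return float(np.mean([r.winner_min for r in recs]))


# ---------------------------------------------------------------------------
# Vectorised evaluator (same semantics, precomputed once per incident set)
# ---------------------------------------------------------------------------

def _haversine_matrix(
    lat1: np.ndarray, lon1: np.ndarray, lat2: np.ndarray, lon2: np.ndarray, radius_km: float
) -> np.ndarray:
    """Pairwise great-circle distances, km; shapes broadcast (n,1) x (1,m)."""
    p1, p2 = np.radians(lat1)[:, None], np.radians(lat2)[None, :]
    dphi = p2 - p1
    dlam = np.radians(lon2)[None, :] - np.radians(lon1)[:, None]
    h = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * radius_km * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


class ResponseEvaluator:
    """Precomputes per-incident ambulance/AED times and the incident x
    candidate-base drone feasibility matrix, so a network's mean response
    time is a single masked-minimum per evaluation.

    Agrees exactly with :func:`respond` (tested property); exists because
    the genetic algorithm re-scores the same incidents for thousands of
    networks.
    """

    def __init__(
        self,
        incidents: Sequence[Incident],
        region: Region,
        road: RoadModel = RoadModel(),
        spec: DroneSpec = DroneSpec(),
        cfg: ResponseConfig = ResponseConfig(),
    ) -> None:
        if not incidents:
            raise ValueError("incident list is empty")
        self.incidents = list(incidents)
        self.region = region
        self.road = road
        self.spec = spec
        self.cfg = cfg

        R = region.earth.radius_km
        ilat = np.array([i.location.lat_deg for i in incidents])
        ilon = np.array([i.location.lon_deg for i in incidents])
        hours = np.array([i.hour for i in incidents])
        mult = np.asarray(road.hourly_multiplier)[hours]
        # minutes of driving per km of crow-flies distance, per incident
        min_per_km = 60.0 * road.circuity * mult / road.base_speed_kmh

        def _min_dist(facs: Sequence[Facility]) -> np.ndarray:
            lat = np.array([f.location.lat_deg for f in facs])
            lon = np.array([f.location.lon_deg for f in facs])
            return _haversine_matrix(ilat, ilon, lat, lon, R).min(axis=1)

        stations = region.ambulance_stations
        aeds = region.public_aeds
        self.ambulance_min = (
            cfg.blue_light_factor * _min_dist(stations) * min_per_km + cfg.ambulance_overhead_min
            if stations
            else None
        )
        self.aed_min = (
            2.0 * _min_dist(aeds) * min_per_km + cfg.aed_overhead_min if aeds else None
        )
        if self.ambulance_min is None and self.aed_min is None:
            raise RuntimeError("region has neither ambulance stations nor public AEDs")

        bases = region.candidate_bases
        self.base_ids = [b.facility_id for b in bases]
        self._base_col = {bid: j for j, bid in enumerate(self.base_ids)}
        blat = np.array([b.location.lat_deg for b in bases])
        blon = np.array([b.location.lon_deg for b in bases])
        D = _haversine_matrix(ilat, ilon, blat, blon, R)  # (n_inc, n_base)
        blocked = np.zeros_like(D, dtype=bool)
        for z in region.no_fly_zones:
            blocked |= self._segment_disk_mask(ilat, ilon, blat, blon, z, R)
        D[(D > spec.range_km) | blocked] = np.inf
        self._drone_dist = D  # inf where base unusable for that incident

    @staticmethod
    def _segment_disk_mask(
        ilat: np.ndarray, ilon: np.ndarray, blat: np.ndarray, blon: np.ndarray,
        zone: Disk, earth_radius_km: float,
    ) -> np.ndarray:
        """Vectorised segment_intersects_disk for all incident-base pairs."""
        kx = earth_radius_km * np.radians(1.0) * np.cos(np.radians(zone.center.lat_deg))
        ky = earth_radius_km * np.radians(1.0)
        ax = (ilon[:, None] - zone.center.lon_deg) * kx
        ay = (ilat[:, None] - zone.center.lat_deg) * ky
        bx = (blon[None, :] - zone.center.lon_deg) * kx
        by = (blat[None, :] - zone.center.lat_deg) * ky
        dx, dy = bx - ax, by - ay
        seg2 = dx * dx + dy * dy
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.clip(np.where(seg2 > 0, -(ax * dx + ay * dy) / np.where(seg2 > 0, seg2, 1.0), 0.0), 0.0, 1.0)
        cx, cy = ax + t * dx, ay + t * dy
        return cx * cx + cy * cy <= zone.radius_km**2

    def drone_minutes(self, base_ids: Iterable[str]) -> np.ndarray:
        """Per-incident drone time for a network; inf where unavailable."""
        cols = [self._base_col[b] for b in base_ids]
        if not cols:
            return np.full(len(self.incidents), np.inf)
        d = self._drone_dist[:, cols].min(axis=1)
        out = 60.0 * d / self.spec.speed_kmh + self.cfg.drone_overhead_min
        out[~np.isfinite(d)] = np.inf
        return out

    def winner_minutes(self, base_ids: Iterable[str] = ()) -> np.ndarray:
        amb = self.ambulance_min if self.ambulance_min is not None else np.inf
        aed = self.aed_min if self.aed_min is not None else np.inf
        return np.minimum(np.minimum(amb, aed), self.drone_minutes(base_ids))

    def mean_response(self, base_ids: Iterable[str] = ()) -> float:
        return float(self.winner_minutes(base_ids).mean())

    def records(self, base_ids: Iterable[str] = ()) -> list[ResponseRecord]:
        """Full per-incident records for a network (winner via tie-break)."""
        amb = self.ambulance_min
        aed = self.aed_min
        drn = self.drone_minutes(base_ids)
        out = []
        for k, inc in enumerate(self.incidents):
            times = {
                "ambulance": None if amb is None else float(amb[k]),
                "public_aed": None if aed is None else float(aed[k]),
                "drone": None if not np.isfinite(drn[k]) else float(drn[k]),
            }
            winner, t = _pick_winner(times)
            out.append(
                ResponseRecord(
                    incident_id=inc.incident_id,
                    ambulance_min=times["ambulance"],
                    aed_min=times["public_aed"],
                    drone_min=times["drone"],
                    winner=winner,
                    winner_min=t,
                )
            )
        return out


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def records_to_csv(records: Sequence[ResponseRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["incident_id", "ambulance_min", "aed_min", "drone_min", "winner", "winner_min"])
        for r in records:
            w.writerow(
                [
                    r.incident_id,
                    "" if r.ambulance_min is None else repr(r.ambulance_min),
                    "" if r.aed_min is None else repr(r.aed_min),
                    "" if r.drone_min is None else repr(r.drone_min),
                    r.winner,
                    repr(r.winner_min),
                ]
            )


def records_from_csv(path: str | Path) -> list[ResponseRecord]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                ResponseRecord(
                    incident_id=int(row["incident_id"]),
                    ambulance_min=float(row["ambulance_min"]) if row["ambulance_min"] else None,
                    aed_min=float(row["aed_min"]) if row["aed_min"] else None,
                    drone_min=float(row["drone_min"]) if row["drone_min"] else None,
                    winner=row["winner"],
                    winner_min=float(row["winner_min"]),
                )
            )
    return out
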