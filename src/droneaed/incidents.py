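"""Probabilistic OHCA incident generation.

Incidents are apportioned across trusts proportionally to population
density (largest-remainder rule), placed by rejection sampling inside the
trust polygon restricted to residential disks (emulating "residential
roads or addresses" — no lakes or mountains), and stamped with a day of
week and hour of day drawn from configurable probability mass functions.

The shipped default PMFs are editable placeholders with the qualitative
shape reported for real OHCA data (a daytime peak in hour-of-day, a mild
weekday elevation in day-of-week); they are not measured values.  Both can
be replaced from a two-column CSV (``index,probability``).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from shapely.geometry import Point as _SPoint, Polygon as _SPolygon

from .geo import GeoPoint, haversine_km
from .synthgeo import Region, Trust

__all__ = [
    "TemporalPMF",
    "Incident",
    "allocate_by_density",
    "sample_location",
    "sample_time",
    "generate_incidents",
    "incidents_to_csv",
    "incidents_from_csv",
]

# Hour-of-day placeholder: low overnight, rising through the morning to a
# broad 09:00-17:00 plateau, tapering in the evening.
_HOUR_WEIGHTS = np.array(
    [1.0, 0.8, 0.7, 0.7, 0.8, 1.2, 2.0, 3.0, 4.0, 5.0, 5.2, 5.2,
     5.0, 5.0, 5.0, 5.0, 5.0, 4.8, 4.0, 3.2, 2.6, 2.2, 1.8, 1.4]
)
# Day-of-week placeholder (Mon..Sun): mildly weekday-elevated.
_DAY_WEIGHTS = np.array([1.05, 1.05, 1.05, 1.05, 1.05, 0.9, 0.85])


@dataclass(frozen=True)
class TemporalPMF:
    """Marginal day-of-week (Mon=0) and hour-of-day (0-23) distributions."""

    day_pmf: tuple[float, ...]
    hour_pmf: tuple[float, ...]

    def __post_init__(self) -> None:
        for name, pmf, n in (("day_pmf", self.day_pmf, 7), ("hour_pmf", self.hour_pmf, 24)):
            v = np.asarray(pmf, dtype=float)
            if v.shape != (n,):
                raise ValueError(f"{name} must have {n} entries")
            if (v < 0).any():
                raise ValueError(f"{name} entries must be non-negative")
            if abs(v.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {v.sum()!r})")

    @classmethod
    def default(cls) -> "TemporalPMF":
        return cls(
            day_pmf=tuple(_DAY_WEIGHTS / _DAY_WEIGHTS.sum()),
            hour_pmf=tuple(_HOUR_WEIGHTS / _HOUR_WEIGHTS.sum()),
        )

    @classmethod
    def from_csvs(cls, day_csv: str | Path, hour_csv: str | Path) -> "TemporalPMF":
        return cls(day_pmf=_read_pmf_csv(day_csv, 7), hour_pmf=_read_pmf_csv(hour_csv, 24))


def _read_pmf_csv(path: str | Path, n: int) -> tuple[float, ...]:
    vals = [0.0] * n
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            vals[int(row["index"])] = float(row["probability"])
    return tuple(vals)


@dataclass(frozen=True)
class Incident:
    incident_id: int
    trust_id: str
    location: GeoPoint
    day: int   # 0 = Monday
    hour: int  # 0-23

    def __post_init__(self) -> None:
        if not (0 <= self.day <= 6):
            raise ValueError("day must be in 0..6")
        if not (0 <= self.hour <= 23):
            raise ValueError("hour must be in 0..23")


def allocate_by_density(trusts: Sequence[Trust], n_total: int) -> list[int]:
    """Largest-remainder apportionment of ``n_total`` incidents by density.

    Quotas are proportional to ``population_density``; each trust gets the
    floor of its quota, and leftover units go to the largest fractional
    remainders (ties to the earlier trust).  Counts always sum to n_total.
    """
    if not trusts:
        raise ValueError("trust list is empty")
    if n_total < 0:
        raise ValueError("n_total must be >= 0")
    w = np.array([t.population_density for t in trusts], dtype=float)
    quotas = n_total * w / w.sum()
    counts = np.floor(quotas).astype(int)
    remainder = n_total - int(counts.sum())
    if remainder:
        order = np.argsort(-(quotas - counts), kind="stable")
        counts[order[:remainder]] += 1
    return counts.tolist()


def sample_location(
    trust: Trust, rng: np.random.Generator, max_attempts: int = 10_000
) -> GeoPoint:
    """Rejection-sample a uniform point in the trust polygon, accepting only
    points that fall inside at least one residential disk.

    Proposals are uniform on the polygon's bounding box; a proposal is
    accepted iff it is in the polygon and within ``radius_km`` of some
    residential centre (great-circle distance).  Raises after
    ``max_attempts`` rejections so infeasible geometry (e.g. residential
    disks wholly outside the trust) fails loudly rather than spinning.
    """
    if not trust.residential_centers:
        raise ValueError(f"trust {trust.trust_id} has no residential centers")
    poly = _SPolygon([(p.lon_deg, p.lat_deg) for p in trust.polygon])
    lons, lats_, maxlon, maxlat = poly.bounds
    centers = trust.residential_centers
    for _ in range(max_attempts):
        lat = rng.uniform(lats_, maxlat)
        lon = rng.uniform(lons, maxlon)
        try:
            p = GeoPoint(lat, lon)
        except ValueError:
            continue
        if not any(haversine_km(p, d.center) <= d.radius_km for d in centers):
            continue
        if poly.covers(_SPoint(lon, lat)):
            return p
    raise RuntimeError(
        f"no acceptable residential location found in trust {trust.trust_id} "
        f"after {max_attempts} attempts"
    )


def sample_time(pmf: TemporalPMF, rng: np.random.Generator) -> tuple[int, int]:
    """Draw (day, hour) independently from the two marginal PMFs."""
    day = int(rng.choice(7, p=np.asarray(pmf.day_pmf)))
    hour = int(rng.choice(24, p=np.asarray(pmf.hour_pmf)))
    return day, hour


def generate_incidents(
    region: Region,
    n_total: int = 10_000,
    pmf: TemporalPMF | None = None,
    seed: int = 0,
    max_attempts: int = 10_000,
) -> list[Incident]:
    """Generate the full incident set: allocate counts by trust density,
    then sample a residential location and a (day, hour) for each incident.

    Deterministic for a fixed seed.  Default size 10,000 incidents.
    """
    pmf = pmf or TemporalPMF.default()
    rng = np.random.default_rng(seed)
    counts = allocate_by_density(region.trusts, n_total)
    incidents: list[Incident] = []
    next_id = 0
    for trust, n in zip(region.trusts, counts):
        for _ in range(n):
            loc = sample_location(trust, rng, max_attempts=max_attempts)
            day, hour = sample_time(pmf, rng)
            incidents.append(
                Incident(incident_id=next_id, trust_id=trust.trust_id,
                         location=loc, day=day, hour=hour)
            )
            next_id += 1
    return incidents


def incidents_to_csv(incidents: Sequence[Incident], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["incident_id", "trust_id", "lat", "lon", "day", "hour"])
        for i in incidents:
            w.writerow(
                [i.incident_id, i.trust_id, repr(i.location.lat_deg),
                 repr(i.location.lon_deg), i.day, i.hour]
            )


def incidents_from_csv(path: str | Path) -> list[Incident]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                Incident(
                    incident_id=int(row["incident_id"]),
                    trust_id=row["trust_id"],
                    location=GeoPoint(float(row["lat"]), float(row["lon"])),
                    day=int(row["day"]),
                    hour=int(row["hour"]),
                )
            )
    return out
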