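"""YAML run configuration: one file, one master seed, every model knob.

All quantities carry units in their key names (km, kmh, min) to avoid
silent unit drift.  Each pipeline stage derives its own sub-seed from the
master seed and the stage name, so stages can be rerun independently yet
reproducibly.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .analysis import CostSpec
from .ga import GAConfig
from .geo import EarthModel
from .incidents import TemporalPMF
from .response import DroneSpec, ResponseConfig
from .synthgeo import RegionConfig, RoadModel

__all__ = ["RunConfig", "stage_seed"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31, derived from the master
    seed and the stage name."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class SweepConfig:
    k_max: int = 10
    rel_threshold: float = 0.02
    per_trust: bool = False


@dataclass(frozen=True)
class WorkloadConfig:
    annual_events: float = 1400.0
    operators_per_station: int = 2


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    n_incidents: int = 10_000
    region: RegionConfig = field(default_factory=RegionConfig)
    road: RoadModel = field(default_factory=RoadModel)
    pmf: TemporalPMF = field(default_factory=TemporalPMF.default)
    drone: DroneSpec = field(default_factory=DroneSpec)
    response: ResponseConfig = field(default_factory=ResponseConfig)
    ga: GAConfig = field(default_factory=GAConfig)
    sweep: SweepConfig = field(default_factory=SweepConfig)
    cost: CostSpec = field(default_factory=CostSpec)
    workload: WorkloadConfig = field(default_factory=WorkloadConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        earth = EarthModel(radius_km=float(doc.get("earth_radius_km", 6356.0)))

        region_doc = dict(doc.get("region", {}))
        if "densities" in region_doc and region_doc["densities"] is not None:
            region_doc["densities"] = tuple(float(d) for d in region_doc["densities"])
        region = RegionConfig(earth=earth, **region_doc)

        road_doc = dict(doc.get("road", {}))
        if road_doc.get("hourly_multiplier"):
            road_doc["hourly_multiplier"] = tuple(float(m) for m in road_doc["hourly_multiplier"])
        else:
            road_doc.pop("hourly_multiplier", None)
        road = RoadModel(**road_doc)

        inc_doc = dict(doc.get("incidents", {}))
        day_csv, hour_csv = inc_doc.get("day_pmf_csv"), inc_doc.get("hour_pmf_csv")
        if day_csv and hour_csv:
            pmf = TemporalPMF.from_csvs(day_csv, hour_csv)
        else:
            pmf = TemporalPMF.default()

        master_seed = int(doc.get("seed", 0))
        ga_doc = dict(doc.get("ga", {}))
        ga_doc.setdefault("seed", stage_seed(master_seed, "ga"))
        return cls(
            seed=master_seed,
            n_incidents=int(inc_doc.get("n_total", 10_000)),
            region=region,
            road=road,
            pmf=pmf,
            drone=DroneSpec(**doc.get("drone", {})),
            response=ResponseConfig(**doc.get("response", {})),
            ga=GAConfig(**ga_doc),
            sweep=SweepConfig(**doc.get("sweep", {})),
            cost=CostSpec(**doc.get("cost", {})),
            workload=WorkloadConfig(**doc.get("workload", {})),
        )
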