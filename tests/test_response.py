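import math

import numpy as np
import pytest

from droneaed.geo import Disk, GeoPoint, haversine_km
from droneaed.incidents import Incident
from droneaed.response import (
    DroneSpec,
    ResponseConfig,
    ResponseEvaluator,
    aed_time,
    ambulance_time,
    drone_time,
    mean_response,
    records_from_csv,
    records_to_csv,
    respond,
    respond_all,
)
from droneaed.synthgeo import Facility, RoadModel

FLAT_ROAD = RoadModel(circuity=1.3, base_speed_kmh=50.0, hourly_multiplier=(1.0,) * 24)


def _km_north(origin: GeoPoint, km: float) -> GeoPoint:
    return GeoPoint(origin.lat_deg + math.degrees(km / 6356.0), origin.lon_deg)


def _incident(lat=0.0, lon=0.0, hour=0, iid=0):
    return Incident(incident_id=iid, trust_id="T1", location=GeoPoint(lat, lon), day=0, hour=hour)


def _fac(fid, kind, loc):
    return Facility(facility_id=fid, kind=kind, location=loc)


class TestAmbulanceTime:
    def test_blue_light_is_three_quarters_of_civilian(self):
        inc = _incident()
        st = [_fac("A1", "ambulance_station", _km_north(inc.location, 10.0))]
        raw = ambulance_time(inc, st, FLAT_ROAD, cfg=ResponseConfig(blue_light_factor=1.0))
        cut = ambulance_time(inc, st, FLAT_ROAD)
        assert raw == pytest.approx(15.6, rel=1e-6)  # 60*13/50
        assert cut == pytest.approx(0.75 * raw)

    def test_colocated_station_zero(self):
        inc = _incident()
        st = [_fac("A1", "ambulance_station", inc.location)]
        assert ambulance_time(inc, st, FLAT_ROAD) == 0.0

    def test_no_stations_unavailable(self):
        assert ambulance_time(_incident(), [], FLAT_ROAD) is None


class TestAedTime:
    def test_round_trip_doubles_one_way(self):
        inc = _incident()
        aeds = [_fac("D1", "public_aed", _km_north(inc.location, 5.0))]
        one_way = ambulance_time(inc, aeds, FLAT_ROAD, cfg=ResponseConfig(blue_light_factor=1.0))
        assert aed_time(inc, aeds, FLAT_ROAD) == pytest.approx(2 * one_way)

    def test_no_blue_light_reduction(self):
        # 4.5 min one way -> 9.0 round trip: distance giving 60*d*1.3/50 = 4.5
        d_km = 4.5 * 50.0 / (60.0 * 1.3)
        inc = _incident()
        aeds = [_fac("D1", "public_aed", _km_north(inc.location, d_km))]
        assert aed_time(inc, aeds, FLAT_ROAD) == pytest.approx(9.0, rel=1e-6)

    def test_no_aeds_unavailable(self):
        assert aed_time(_incident(), [], FLAT_ROAD) is None


class TestDroneTime:
    spec = DroneSpec(speed_kmh=100.0, range_km=12.0)

    def test_at_exact_range_included(self):
        inc = _incident()
        bases = [_fac("B1", "candidate_base", _km_north(inc.location, 12.0))]
        t = drone_time(inc, bases, self.spec)
        assert t == pytest.approx(7.2, abs=1e-6)  # 60 * 12 / 100

    def test_beyond_range_unavailable(self):
        inc = _incident()
        bases = [_fac("B1", "candidate_base", _km_north(inc.location, 12.05))]
        assert drone_time(inc, bases, self.spec) is None

    def test_blocked_nearest_falls_through_to_clear_farther_base(self):
        inc = _incident()
        near = _fac("B1", "candidate_base", _km_north(inc.location, 5.0))
        far = _fac("B2", "candidate_base", GeoPoint(0.0, math.degrees(8.0 / 6356.0)))
        zone = Disk(_km_north(inc.location, 2.5), radius_km=1.0)  # sits on the near path
        t = drone_time(inc, [near, far], self.spec, zones=[zone])
        assert t == pytest.approx(60.0 * 8.0 / 100.0, rel=1e-4)

    def test_all_paths_blocked_unavailable(self):
        inc = _incident()
        bases = [_fac("B1", "candidate_base", _km_north(inc.location, 5.0))]
        zone = Disk(_km_north(inc.location, 2.5), radius_km=1.0)
        assert drone_time(inc, bases, self.spec, zones=[zone]) is None

    def test_empty_bases_unavailable(self):
        assert drone_time(_incident(), [], self.spec) is None


class TestRespond:
    def test_minimum_wins(self, small_region, small_incidents):
        rec = respond(small_incidents[0], small_region,
                      [b.facility_id for b in small_region.candidate_bases])
        avail = [t for t in (rec.ambulance_min, rec.aed_min, rec.drone_min) if t is not None]
        assert rec.winner_min == min(avail)

    def test_before_scenario_has_no_drone_winner(self, small_region, small_incidents):
        for rec in respond_all(small_incidents[:50], small_region, ()):
            assert rec.winner in ("ambulance", "public_aed")
            assert rec.drone_min is None

    def test_tie_prefers_ambulance_then_drone(self):
        from droneaed.synthgeo import Region, Trust

        spot = GeoPoint(0.2, 0.2)
        trust = Trust(
            trust_id="T1", name="T1",
            polygon=(GeoPoint(0, 0), GeoPoint(0, 1), GeoPoint(1, 1), GeoPoint(1, 0)),
            population_density=100.0,
            residential_centers=(Disk(spot, 5.0),),
        )
        region = Region(
            trusts=(trust,),
            facilities=(
                _fac("A1", "ambulance_station", spot),
                _fac("D1", "public_aed", spot),
                _fac("B1", "candidate_base", spot),
            ),
        )
        inc = Incident(incident_id=0, trust_id="T1", location=spot, day=0, hour=0)
        rec = respond(inc, region, ["B1"])
        # all three responders take 0 min; the professional responder wins
        assert rec.ambulance_min == rec.drone_min == rec.aed_min == 0.0
        assert rec.winner == "ambulance"
        # without the station, the drone outranks the public AED on the tie
        region2 = Region(trusts=(trust,), facilities=region.facilities[1:])
        rec2 = respond(inc, region2, ["B1"])
        assert rec2.winner == "drone"

    def test_mean_response_is_arithmetic_mean(self, small_region, small_incidents):
        ids = [b.facility_id for b in small_region.candidate_bases[:3]]
        recs = respond_all(small_incidents[:20], small_region, ids)
        m = mean_response(small_incidents[:20], small_region, ids)
        assert m == pytest.approx(np.mean([r.winner_min for r in recs]))

    def test_mean_response_empty_rejected(self, small_region):
        with pytest.raises(ValueError):
            mean_response([], small_region)


class TestEvaluator:
    def test_agrees_with_scalar_path(self, small_region, small_incidents, evaluator):
        ids = sorted(b.facility_id for b in small_region.candidate_bases)[:5]
        vec = evaluator.records(ids)
        scal = respond_all(small_incidents, small_region, ids)
        for v, s in zip(vec, scal):
            assert v.winner == s.winner
            assert v.winner_min == pytest.approx(s.winner_min, abs=1e-9)
            assert (v.drone_min is None) == (s.drone_min is None)

    def test_superset_monotonicity(self, evaluator):
        rng = np.random.default_rng(4)
        ids = evaluator.base_ids
        for _ in range(30):
            k = int(rng.integers(1, len(ids)))
            small = list(rng.choice(ids, size=k, replace=False))
            extra = [i for i in ids if i not in small]
            big = small + [extra[int(rng.integers(len(extra)))]]
            assert np.all(evaluator.winner_minutes(big) <= evaluator.winner_minutes(small) + 1e-12)

    def test_drone_time_bounded_by_range(self, evaluator):
        t = evaluator.drone_minutes(evaluator.base_ids)
        finite = t[np.isfinite(t)]
        assert np.all(finite <= 60.0 * 12.0 / 100.0 + 1e-9)


class TestRecordsCsv:
    def test_round_trip_with_unavailable_drone(self, small_region, small_incidents, tmp_path):
        recs = respond_all(small_incidents[:30], small_region, ())
        path = tmp_path / "records.csv"
        records_to_csv(recs, path)
        assert records_from_csv(path) == recs
        header = path.read_text().splitlines()[0]
        assert header == "incident_id,ambulance_min,aed_min,drone_min,winner,winner_min"
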