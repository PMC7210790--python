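import pytest

from droneaed import (
    RegionConfig,
    ResponseEvaluator,
    generate_incidents,
    generate_region,
)

# Small desk-scale region: 3 trusts, one denser than the others, a single
# no-fly zone so the zone-avoidance code path is exercised.
SMALL_CONFIG = RegionConfig(
    n_trusts=3,
    densities=(800.0, 120.0, 90.0),
    residential_centers_per_trust=5,
    n_ambulance_stations=6,
    n_public_aeds=10,
    n_candidate_bases=12,
    n_no_fly_zones=1,
)

# Rural-like scenario: sparse professional coverage (few stations/AEDs),
# low densities, plenty of candidate drone sites.
RURAL_CONFIG = RegionConfig(
    n_trusts=3,
    densities=(150.0, 90.0, 60.0),
    residential_centers_per_trust=6,
    n_ambulance_stations=3,
    n_public_aeds=5,
    n_candidate_bases=25,
    n_no_fly_zones=0,
)


@pytest.fixture(scope="session")
def small_region():
    return generate_region(SMALL_CONFIG, seed=7)


@pytest.fixture(scope="session")
def small_incidents(small_region):
    return generate_incidents(small_region, n_total=300, seed=3)


@pytest.fixture(scope="session")
def evaluator(small_region, small_incidents):
    return ResponseEvaluator(small_incidents, small_region)


@pytest.fixture(scope="session")
def rural_region():
    return generate_region(RURAL_CONFIG, seed=11)
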