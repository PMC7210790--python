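# Methods

## Scope and data model

The package simulates out-of-hospital cardiac arrest (OHCA) response over
a region divided into health trusts and sites a network of AED-carrying
drone bases. The real-world analogue of the input data — trust boundary
polygons with population densities, ambulance-station and public-AED
locations, civic facilities usable as drone bases, restricted airspace —
is proprietary or unpublished, so the package ships a synthetic-region
generator with the same structure and accepts user data in the same
schemas (GeoJSON FeatureCollection for trusts, residential centres and
no-fly zones; `facility_id,kind,lat,lon` CSV for facilities).

All geometry is spherical-earth: great-circle (haversine) distances on a
sphere of radius 6356 km (the polar radius; configurable via
`EarthModel`). Geodesic ellipsoid corrections are below 0.5% at this scale
and are deliberately out of scope. No-fly-zone checks project the flight
segment into a local equirectangular plane centred on the zone (longitude
scaled by cos of the zone latitude); this is accurate to well under 1% for
the 5 km zone radii and ≤ 12 km flight legs the model works with.
Boundary conventions are inclusive everywhere (a point on a polygon edge
is inside; a path tangent to a no-fly disk intersects it; a base at
exactly the range limit is usable), so exclusion rules err on the
conservative side.

## Synthetic regions

`generate_region` partitions a bounding box (default ≈ 1.3° × 2.8°, the
extent of a Northern-Ireland-sized region) into Voronoi cells around
random seed points — the trusts. Default densities are stylized: one dense
urban trust (2,570 persons/km²) and four sparser rural ones (89–178),
mimicking a capital-city trust surrounded by rural trusts. Each trust gets
8 residential disks of radius 2.5 km; facilities are placed with Gaussian
jitter (σ = half the disk radius) around residential centres, the trust
chosen density-weighted so facilities concentrate where people are.
Default inventories — 30 ambulance stations, 80 public AEDs, 60 candidate
bases, 2 no-fly zones — are desk-scale stand-ins chosen to keep exhaustive
validation and repeated GA runs cheap while preserving the qualitative
regime (candidate bases outnumber the network size several-fold; AED and
station coverage is dense in the urban trust and sparse elsewhere). All
counts, densities and radii are config-exposed.

What the generator does **not** emulate: road networks (travel is
crow-flies × circuity), real settlement geography, coastline/land-use
constraints, joint day×hour incident structure, and concurrent-incident
contention. Passing tests therefore demonstrate the correctness of the
method's machinery and its qualitative behaviour (drones help most where
professional coverage is sparse), not calibrated predictions for any real
region.

## Incident process

Incident counts per trust follow largest-remainder apportionment
proportional to population density — density is used as the literal
weight, with the caveat that this weights small dense trusts more than
total population would; the weight column is user-overridable by supplying
custom densities. Locations are rejection-sampled uniformly over the trust
polygon restricted to the union of residential disks (cap: 10,000
proposals per point, then a hard error — infeasible geometry fails loudly).
Day-of-week and hour-of-day are drawn independently from two marginal
PMFs; the shipped defaults are **placeholders** with the qualitative shape
of published OHCA temporality (broad 09:00–17:00 peak, mild weekday
elevation), not measured values, and can be replaced from two-column CSVs.
The incident hour doubles as the traffic hour in the road model.

## Response model

Tunable parameters, with defaults:

| parameter | default | meaning |
|---|---|---|
| `circuity` | 1.3 | road distance / crow-flies distance |
| `base_speed_kmh` | 50 | free-flow driving speed |
| `hourly_multiplier[h]` | 1.0–1.5 | congestion divisor of speed by hour |
| `blue_light_factor` | 0.75 | ambulance time as fraction of civilian time |
| `speed_kmh` (drone) | 100 | cruise speed |
| `range_km` (drone) | 12 | one-way range, inclusive at the limit |
| `*_overhead_min` | 0 | additive per-responder overheads |

The blue-light reduction applies only to the ambulance leg; the bystander
AED trip is civilian driving both ways. No dispatch/takeoff/landing
overheads are added by default (travel time only), but additive overheads
are exposed for sensitivity analysis. The drone search considers bases in
increasing distance and takes the first with a clear path, so a farther
base serves when the nearest is blocked by a no-fly zone. Tie-break when
times are equal: ambulance > drone > public AED (professional responder
preferred). With no active bases the model is the "before" scenario.

`ResponseEvaluator` vectorises this: per-incident ambulance/AED minutes
and an incident × candidate-base distance matrix (entries set to ∞ beyond
range or across a zone) are precomputed once, making one network
evaluation a masked column-minimum. A test asserts the evaluator agrees
with the scalar `respond` on every incident; the scalar path is the
defining implementation.

## Genetic algorithm

Chromosomes are k-subsets of candidate-base ids; fitness is the mean
winning time (cached by sorted id tuple; cached and fresh evaluations are
identical by construction). Each generation: sort ascending by fitness
(ties broken by id tuple for determinism), keep the 2 elites, cross
consecutive pairs (1st×2nd, 3rd×4th, …), mutate children at rate 0.10
(one gene swapped for a uniform outside candidate), refill with random
chromosomes to the fixed population size. The crossover operator —
a uniform random k-subset of the parents' union — was an open design
point: it is unbiased between parents, preserves set semantics exactly,
and degenerates to cloning for identical parents. Population size (50)
and generation count (100) are not model claims, just defaults that
comfortably reach the exhaustive optimum on every oracle-sized instance
tested; both are config-exposed. Elitism makes the best-ever fitness
monotone non-increasing, which the tests assert on every run.

Both whole-region and per-trust optimisation are supported
(`--per-trust` unions five independent per-trust networks, using only that
trust's incidents and the candidate bases inside its polygon); per-trust
`k` caps express saturation of already well-covered urban trusts.

`brute_force_best` enumerates all C(n,k) subsets (refusing above a 20,000
cap) and is the oracle the GA is validated against: on 8–10-candidate /
k = 2–3 instances the GA matches the global optimum in ≥ 18/20 seeds.

## Network sizing and reporting

The size sweep runs one GA per k = 1..k_max and keeps the best-so-far
envelope, so the curve is monotone even though individual GA runs are
noisy; the chosen size is the smallest k after which every further step
improves the envelope by less than 2% (relative) — the diminishing-returns
plateau. The threshold is a reporting choice, not a model claim, and is
configurable.

Coverage fractions use strict "< threshold" at 3–8 minutes. Five-number
summaries use linear interpolation between order statistics. The
before/after comparison is a paired Wilcoxon signed-rank test (pairing by
incident): zero differences dropped, W = the smaller signed-rank sum,
two-sided p exact for n ≤ 25 (convolution over the 2ⁿ sign assignments on
doubled midranks, so ties are handled exactly) and a tie- and
continuity-corrected normal approximation otherwise. The continuity
correction was kept because it brings the approximation within 0.007 of
the exact p at n = 25 on random continuous data.

Cost is `n · unit_cost · (1 + maintenance_rate · lifespan_years)` with
defaults $15,000, 20%/yr, 4 years; workload spreads annual events evenly
over stations and months. Both are transparent arithmetic exposed for
what-if analysis.

## Numerical and degenerate-input choices

- Haversine clamps its radicand into [0, 1] before `asin`, so antipodal
  round-off cannot produce NaN.
- `allocate_by_density` breaks remainder ties toward the earlier trust
  (stable argsort), making apportionment deterministic.
- "Unavailable" responders are `None`/∞ sentinels, never exceptions; an
  incident with no responder of any kind is a hard error.
- All randomness flows through `numpy.random.default_rng` seeded per
  stage via SHA-256 of `master_seed:stage_name` (kept below 2³¹), so any
  stage can be rerun independently and byte-identically.
- Empty inputs (no records, no incidents, empty trust list, degenerate
  polygons, PMFs that do not sum to 1) raise `ValueError` at the boundary
  rather than propagating garbage.

## Problem sizes used in the shipped checks

The default pipeline scale is 10,000 incidents over 60 candidate bases
with a sweep to k = 15. GA-vs-oracle validation uses 30-incident,
8–10-candidate instances (exhaustive enumeration is exact there); the
rural-like significance check uses 3 trusts with densities
(150, 90, 60) persons/km², 3 ambulance stations, 5 public AEDs,
25 candidate bases, 1,000 incidents and a GA-placed 5-base network,
20 seeds. These sizes were fixed as the package's study conditions and
are the ones its distributional guarantees refer to.

## Known limitations

Concurrent incidents, drone recharge/turnaround, fleet queueing, weather,
real road routing and survival-outcome modelling are out of scope. The
road model's calibration constants are stand-ins for a travel-time
provider; any conclusions about a real region require real boundaries,
facility inventories, temporal PMFs and travel times behind the same
interfaces.
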