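# droneaed

Simulation and genetic-algorithm siting of AED-carrying drone bases for
out-of-hospital cardiac arrest (OHCA) response.

Survival after OHCA falls sharply with every minute before defibrillation,
and large parts of a rural region cannot be reached by a blue-light
ambulance inside the 8-minute target for life-threatening calls. Drones
that fly an automated external defibrillator (AED) directly to the scene
are a candidate fix — if their bases are sited well. This package is for
emergency-medicine researchers and EMS planners who want to explore that
siting problem quantitatively: it simulates a probabilistic incident load
over a region partitioned into health trusts, scores three responder types
per incident, and selects a drone base network that minimises the mean
response time.

## Model

**Incidents.** A configurable number of OHCA events (default n = 10,000)
is apportioned across trusts proportionally to population density
(largest-remainder rule), placed by rejection sampling inside each trust
polygon restricted to residential disks, and stamped with a day-of-week and
hour-of-day drawn from configurable probability mass functions.

**Responders.** For incident *i* at hour *h*, with great-circle (haversine)
distance *d* on a sphere of radius *r* = 6356 km:

- ambulance: `0.75 · t_road(nearest station → i, h)` — a 25% blue-light
  reduction of civilian driving time;
- public AED: `t_road(i → nearest AED, h) + t_road(nearest AED → i, h)` — a
  bystander drives there and back, no reduction;
- drone: `60 · d / v` minutes at cruise speed *v* = 100 km/h from the
  nearest active base with `d ≤ 12 km` whose straight path crosses no
  no-fly zone (5 km disks); *unavailable* if no base qualifies.

Driving time uses a parametric road model,
`t_road = 60 · d · circuity / (v_road / m(h))` with circuity 1.3, free-flow
speed 50 km/h and an hourly congestion multiplier `m(h) ≥ 1`. The fastest
available responder wins; ties prefer the professional responder.

**Optimisation.** A genetic algorithm over fixed-size sets of candidate
bases (a *chromosome* = one network): fitness is the mean winning response
time, the two fittest chromosomes survive each generation, consecutive
pairs in descending fitness order cross over (uniform k-subset of the
parent union), children mutate with probability 0.10, and random
chromosomes refill the population. An exhaustive k-subset search
(`brute_force_best`) validates the heuristic on small instances. The
network size is chosen where the size-sweep curve plateaus (relative
improvement per added base < 2%).

**Reporting.** Coverage at <3…<8 minute thresholds, responder mix,
per-trust before/after means, five-number summaries with a paired Wilcoxon
signed-rank test (exact by enumeration for n ≤ 25), fleet lifetime cost
`n · 15000 · (1 + 0.20 · 4)` and flights-per-station/operator workload.

## Worked example

```sh
droneaed run-all --config examples/config.yaml --out out/demo
```

generates a 3-trust synthetic region with 6 ambulance stations, 10 public
AEDs and 12 candidate drone bases, samples 2,000 incidents, and sites a
5-base network. The run prints:

```
INFO region: 3 trusts, 6 stations, 10 AEDs, 12 candidate bases, 1 no-fly zones
INFO wrote 2000 incidents
INFO baseline mean response: 21.35 min
INFO national GA: k=5 fitness=13.62 min
INFO after-scenario mean response: 13.62 min
INFO mean before 21.35 min -> after 13.62 min (Wilcoxon p=2.73e-161); drone share 48.8%
```

Mean response falls from 21.35 to 13.62 minutes once the 5 drone bases are
active; drones win 48.8% of incidents, and the paired Wilcoxon test
confirms the per-incident improvement is systematic, not noise. The output
directory holds the per-incident response records (before/after), the
chosen network, coverage/mix/trust-summary tables, `summary.json` with the
five-number summaries, and the corresponding figures. The stages can also
be run separately (`generate-region`, `generate-incidents`, `baseline`,
`optimize`, `sweep`, `report`), all driven by one YAML config and one
master seed; identical seeds reproduce byte-identical outputs.

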