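# example run configuration: a small synthetic region for a quick demo
seed: 42

region:
  n_trusts: 3
  densities: [800.0, 120.0, 90.0]   # persons per km^2
  residential_centers_per_trust: 5
  n_ambulance_stations: 6
  n_public_aeds: 10
  n_candidate_bases: 12
  n_no_fly_zones: 1
  no_fly_radius_km: 5.0

road:
  circuity: 1.3          # road distance / crow-flies distance
  base_speed_kmh: 50.0

incidents:
  n_total: 2000

drone:
  speed_kmh: 100.0
  range_km: 12.0

response:
  blue_light_factor: 0.75   # 25% blue-light reduction

ga:
  population_size: 30
  generations: 50
  mutation_rate: 0.10
  elite_count: 2
  k: 5

sweep:
  k_max: 8
  rel_threshold: 0.02

cost:
  unit_cost: 15000.0
  maintenance_rate: 0.20
  lifespan_years: 4.0

workload:
  annual_events: 1400.0
  operators_per_station: 2
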