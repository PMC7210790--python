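import statistics

import numpy as np
import pytest
from scipy import stats as sstats

from droneaed.analysis import (
    CostSpec,
    SweepCurve,
    boxplot_stats,
    cost_model,
    coverage_table,
    responder_mix,
    select_plateau,
    sweep_bases,
    trust_summaries,
    wilcoxon_signed_rank,
    workload,
)
from droneaed.ga import GAConfig
from droneaed.response import ResponseRecord


def _rec(iid, winner, t):
    return ResponseRecord(incident_id=iid, ambulance_min=t, aed_min=None,
                          drone_min=None, winner=winner, winner_min=t)


class TestSweepAndPlateau:
    def test_sweep_envelope_monotone(self, evaluator):
        cfg = GAConfig(population_size=10, generations=10, seed=0)
        curve = sweep_bases(evaluator, 4, cfg)
        env = curve.best_fitness_min
        assert all(b <= a for a, b in zip(env, env[1:]))
        assert curve.k_values == (1, 2, 3, 4)

    def test_sweep_raw_never_beats_oracle(self, evaluator):
        from droneaed.ga import brute_force_best

        cfg = GAConfig(population_size=10, generations=15, seed=0)
        curve = sweep_bases(evaluator, 3, cfg)
        for k, raw in zip(curve.k_values, curve.raw_fitness_min):
            _, opt = brute_force_best(evaluator, k)
            assert raw >= opt - 1e-12

    def test_plateau_flat_curve(self):
        curve = SweepCurve((1, 2, 3), (10.0, 10.0, 10.0))
        assert select_plateau(curve, 0.02) == 1

    def test_plateau_hand_example(self):
        # steps: 20%, 1.25%, 0.13% -> first k after which all steps < 5% is 2
        curve = SweepCurve((1, 2, 3, 4), (10.0, 8.0, 7.9, 7.89))
        assert select_plateau(curve, 0.05) == 2

    def test_plateau_steep_curve_returns_k_max(self):
        curve = SweepCurve((1, 2, 3), (10.0, 5.0, 2.0))
        assert select_plateau(curve, 0.001) == 3

    def test_non_monotone_envelope_rejected(self):
        with pytest.raises(ValueError):
            SweepCurve((1, 2), (5.0, 6.0))


class TestCoverage:
    def test_direct_count(self):
        recs = [_rec(i, "ambulance", t) for i, t in enumerate([2.0, 4.0, 9.0])]
        cov = coverage_table(recs, thresholds=(3, 8))
        assert cov[3.0] == pytest.approx(1 / 3)
        assert cov[8.0] == pytest.approx(2 / 3)

    def test_all_zero_times_full_coverage(self):
        recs = [_rec(i, "ambulance", 0.0) for i in range(5)]
        assert all(v == 1.0 for v in coverage_table(recs).values())

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        recs = [_rec(i, "ambulance", float(t)) for i, t in enumerate(rng.uniform(0, 12, 200))]
        cov = coverage_table(recs)
        vals = [cov[t] for t in sorted(cov)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_strictly_less_than_convention(self):
        recs = [_rec(0, "ambulance", 3.0)]
        assert coverage_table(recs, thresholds=(3,))[3.0] == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            coverage_table([])


class TestResponderMix:
    def test_counts_and_fractions(self):
        recs = [_rec(0, "drone", 1), _rec(1, "drone", 1),
                _rec(2, "ambulance", 1), _rec(3, "public_aed", 1)]
        mix = responder_mix(recs)
        assert mix["drone"]["count"] == 2 and mix["drone"]["fraction"] == 0.5
        assert mix["ambulance"]["fraction"] == 0.25
        assert sum(m["fraction"] for m in mix.values()) == pytest.approx(1.0, abs=1e-9)
        assert sum(m["count"] for m in mix.values()) == 4

    def test_before_scenario_zero_drone_share(self, small_region, evaluator):
        mix = responder_mix(evaluator.records(()))
        assert mix["drone"]["count"] == 0


class TestBoxplotStats:
    def test_odd_length_median(self):
        assert boxplot_stats(list(range(1, 10)))[2] == 5.0

    def test_constant_list(self):
        assert boxplot_stats([4.0, 4.0, 4.0]) == (4.0, 4.0, 4.0, 4.0, 4.0)

    def test_matches_independent_quantile_oracle(self):
        # statistics.quantiles with the inclusive method is the same linear
        # interpolation between order statistics, computed independently
        data = [1.0, 2.0, 3.0, 4.0]
        q = statistics.quantiles(data, n=4, method="inclusive")
        mn, q1, med, q3, mx = boxplot_stats(data)
        assert (q1, med, q3) == pytest.approx(tuple(q))
        assert (mn, mx) == (1.0, 4.0)

    def test_ordered_five_numbers(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=37)
        s = boxplot_stats(v)
        assert all(b >= a for a, b in zip(s, s[1:]))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            boxplot_stats([])


class TestWilcoxon:
    def test_all_positive_distinct_n5(self):
        # W = 0; exact two-sided p = 2/2^5 = 0.0625 by full sign enumeration
        res = wilcoxon_signed_rank([10, 10, 10, 10, 10], [9, 8, 7, 6, 5])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.0625)
        assert res.method == "exact"

    def test_all_zero_differences_degenerate(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == 1.0 and res.method == "degenerate"

    def test_exact_matches_scipy_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            b = rng.normal(10, 2, 15)
            a = b - rng.normal(0.5, 1.0, 15)
            res = wilcoxon_signed_rank(b, a)
            ref = sstats.wilcoxon(a - b, method="exact")
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)
            assert res.statistic == pytest.approx(ref.statistic)

    def test_exact_and_normal_agree_at_n25(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            b = rng.normal(10, 2, 25)
            a = b - rng.normal(0.3, 1.0, 25)
            exact = wilcoxon_signed_rank(b, a, exact_max_n=25)
            approx = wilcoxon_signed_rank(b, a, exact_max_n=0)
            assert abs(exact.p_value - approx.p_value) < 0.01

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0])


class TestTrustSummaries:
    def test_per_trust_means_and_dominance(self, small_region, small_incidents, evaluator):
        before = evaluator.records(())
        after = evaluator.records(evaluator.base_ids)
        rows = trust_summaries(small_incidents, before, after)
        assert {r["trust_id"] for r in rows} == {t.trust_id for t in small_region.trusts}
        for r in rows:
            assert r["mean_after_min"] <= r["mean_before_min"] + 1e-12
        assert sum(r["n_incidents"] for r in rows) == len(small_incidents)

    def test_misaligned_inputs_rejected(self, small_incidents, evaluator):
        with pytest.raises(ValueError):
            trust_summaries(small_incidents, evaluator.records(())[:-1], evaluator.records(()))


class TestCostAndWorkload:
    def test_fleet_of_78_costs_2_11_million(self):
        assert cost_model(78) == pytest.approx(2_106_000.0)

    def test_zero_drones_zero_cost(self):
        assert cost_model(0) == 0.0

    def test_no_maintenance_is_purchase_only(self):
        spec = CostSpec(maintenance_rate=0.0)
        assert cost_model(10, spec) == 10 * spec.unit_cost

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            cost_model(-1)
        with pytest.raises(ValueError):
            CostSpec(unit_cost=-5.0)

    def test_workload_under_two_flights_per_station(self):
        per_station, per_operator = workload(1400, 78, operators_per_station=2)
        assert per_station == pytest.approx(1400 / (78 * 12))
        assert per_station < 2.0
        assert per_operator == pytest.approx(per_station / 2)
        assert per_operator < 1.0

    def test_zero_events(self):
        assert workload(0, 10) == (0.0, 0.0)

    def test_zero_stations_rejected(self):
        with pytest.raises(ValueError):
            workload(100, 0)
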