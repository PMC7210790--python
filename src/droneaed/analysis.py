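"""Result-generation layer: network sizing, coverage, responder mix,
before/after statistics, cost and workload arithmetic.

This module turns per-incident response records into the study's summary
products: the diminishing-returns curve that sizes the drone network, the
share of incidents reached within 3-8 minutes, the responder mix, paired
before/after five-number summaries with a Wilcoxon signed-rank test, the
lifetime cost of the fleet, and per-station / per-operator flight
workload.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats as _sstats

from .ga import GAConfig, brute_force_best, evolve
from .incidents import Incident
from .response import ResponseEvaluator, ResponseRecord

__all__ = [
    "SweepCurve",
    "CostSpec",
    "WilcoxonResult",
    "sweep_bases",
    "select_plateau",
    "coverage_table",
    "responder_mix",
    "boxplot_stats",
    "wilcoxon_signed_rank",
    "trust_summaries",
    "cost_model",
    "workload",
]


@dataclass(frozen=True)
class SweepCurve:
    """Best response time as a function of network size k.

    ``best_fitness_min`` is the best-so-far envelope over k, so the curve
    is monotone non-increasing even when individual GA runs are noisy.
    ``raw_fitness_min`` keeps the per-k GA results before enveloping.
    """

    k_values: tuple[int, ...]
    best_fitness_min: tuple[float, ...]
    raw_fitness_min: tuple[float, ...] = ()
    best_networks: tuple[tuple[str, ...], ...] = ()

    def __post_init__(self) -> None:
        if len(self.k_values) != len(self.best_fitness_min):
            raise ValueError("k_values and best_fitness_min must align")
        env = self.best_fitness_min
        if any(env[i + 1] > env[i] for i in range(len(env) - 1)):
            raise ValueError("envelope must be monotone non-increasing")


@dataclass(frozen=True)
class CostSpec:
    """Fleet cost model: purchase price per drone, annual maintenance as a
    fraction of purchase price, and drone lifespan in years."""

    unit_cost: float = 15_000.0
    maintenance_rate: float = 0.20
    lifespan_years: float = 4.0

    def __post_init__(self) -> None:
        if min(self.unit_cost, self.maintenance_rate, self.lifespan_years) < 0:
            raise ValueError("cost parameters must be >= 0")


def sweep_bases(
    evaluator: ResponseEvaluator,
    k_max: int,
    ga_config: GAConfig = GAConfig(),
    candidates: Sequence[str] | None = None,
) -> SweepCurve:
    """Run the GA for each k = 1..k_max and return the enveloped curve.

    Each k gets its own GA run (seeded from ``ga_config.seed + k`` so runs
    are independent but reproducible); the envelope takes the best fitness
    seen at any size <= k.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    cands = sorted(candidates if candidates is not None else evaluator.base_ids)
    k_max = min(k_max, len(cands))
    ks, raw, env, nets = [], [], [], []
    best_so_far = math.inf
    best_net: tuple[str, ...] = ()
    for k in range(1, k_max + 1):
        cfg = replace(ga_config, k=k, seed=ga_config.seed + k)
        best, _ = evolve(evaluator, cfg, cands)
        ks.append(k)
        raw.append(best.fitness_min)
        if best.fitness_min < best_so_far:
            best_so_far = best.fitness_min
            best_net = best.key
        env.append(best_so_far)
        nets.append(best_net)
    return SweepCurve(tuple(ks), tuple(env), tuple(raw), tuple(nets))


def select_plateau(curve: SweepCurve, rel_threshold: float = 0.02) -> int:
    """Smallest k after which every further step improves the envelope by
    less than ``rel_threshold`` (relative); k_max when no plateau exists.

    This is the diminishing-returns rule used to size the network: beyond
    the chosen k, each extra base buys less than the threshold fraction of
    response time.
    """
    if not curve.k_values:
        raise ValueError("empty sweep curve")
    if not (0.0 < rel_threshold < 1.0):
        raise ValueError("rel_threshold must be in (0, 1)")
    f = curve.best_fitness_min
    rel = [
        (f[i - 1] - f[i]) / f[i - 1] if f[i - 1] > 0 else 0.0
        for i in range(1, len(f))
    ]
    for j in range(len(f)):
        if all(r < rel_threshold for r in rel[j:]):
            return curve.k_values[j]
    return curve.k_values[-1]


def coverage_table(
    records: Sequence[ResponseRecord],
    thresholds: Sequence[float] = (3, 4, 5, 6, 7, 8),
) -> dict[float, float]:
    """Fraction of incidents reached strictly under each threshold (min)."""
    if not records:
        raise ValueError("no records")
    times = np.array([r.winner_min for r in records])
    return {float(t): float((times < t).mean()) for t in thresholds}


def responder_mix(records: Sequence[ResponseRecord]) -> dict[str, dict[str, float]]:
    """Count and fraction of incidents won by each responder type."""
    if not records:
        raise ValueError("no records")
    n = len(records)
    out: dict[str, dict[str, float]] = {}
    for kind in ("ambulance", "public_aed", "drone"):
        c = sum(1 for r in records if r.winner == kind)
        out[kind] = {"count": c, "fraction": c / n}
    return out


def boxplot_stats(times: Sequence[float]) -> tuple[float, float, float, float, float]:
    """Five-number summary (min, Q1, median, Q3, max), quartiles by linear
    interpolation between order statistics."""
    if len(times) == 0:
        raise ValueError("empty sample")
    v = np.asarray(times, dtype=float)
    q1, med, q3 = np.percentile(v, [25, 50, 75], method="linear")
    return float(v.min()), float(q1), float(med), float(q3), float(v.max())


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W = smaller of the two signed-rank sums
    p_value: float    # two-sided
    n: int            # pairs remaining after dropping zero differences
    method: str       # "exact" | "normal" | "degenerate"


def _exact_signed_rank_cdf(ranks2: np.ndarray, w2: int) -> float:
    """P(W+ <= w) under random signs, exact by convolution.

    ``ranks2`` are the (mid)ranks doubled so ties give integers; ``w2`` is
    the doubled target sum.  The null distribution of the positive-rank
    sum is built by multiplying the generating polynomials (1 + x^r)/2.
    """
    total = int(ranks2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in ranks2:
        r = int(r)
        nxt = dist.copy()
        nxt[r:] += dist[: total + 1 - r]
        dist = nxt / 2.0
    return float(dist[: w2 + 1].sum())


def wilcoxon_signed_rank(
    before: Sequence[float], after: Sequence[float], exact_max_n: int = 25
) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test on before/after times.

    Zero differences are dropped.  For n <= ``exact_max_n`` the two-sided
    p-value is exact (full enumeration of the 2^n sign assignments via
    convolution, tie pattern respected); for larger n a normal
    approximation with tie correction and continuity correction is used.
    W is reported as the smaller of the two signed-rank sums.
    """
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.shape != a.shape:
        raise ValueError("before and after must have equal length")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return WilcoxonResult(statistic=0.0, p_value=1.0, n=0, method="degenerate")
    ranks = _sstats.rankdata(np.abs(d))  # midranks under ties
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)
    if n <= exact_max_n:
        ranks2 = np.rint(2 * ranks).astype(int)
        cdf = _exact_signed_rank_cdf(ranks2, int(round(2 * w)))
        return WilcoxonResult(statistic=w, p_value=min(1.0, 2.0 * cdf), n=n, method="exact")
    mu = n * (n + 1) / 4.0
    tie_sizes = np.unique(ranks, return_counts=True)[1]
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_sizes**3 - tie_sizes).sum() / 48.0
    if var <= 0:
        return WilcoxonResult(statistic=w, p_value=1.0, n=n, method="degenerate")
    z = (w - mu + 0.5) / math.sqrt(var)  # continuity-corrected, w <= mu
    p = min(1.0, 2.0 * _sstats.norm.cdf(z))
    return WilcoxonResult(statistic=w, p_value=p, n=n, method="normal")


def trust_summaries(
    incidents: Sequence[Incident],
    before: Sequence[ResponseRecord],
    after: Sequence[ResponseRecord],
) -> list[dict]:
    """Per-trust mean before/after response times and paired Wilcoxon p.

    ``before`` and ``after`` must cover the same incidents in the same
    order (the pairing of the test).
    """
    if not (len(incidents) == len(before) == len(after)):
        raise ValueError("incidents, before and after must align")
    by_trust: dict[str, list[int]] = {}
    for idx, inc in enumerate(incidents):
        by_trust.setdefault(inc.trust_id, []).append(idx)
    out = []
    for trust_id, idxs in by_trust.items():
        b = [before[i].winner_min for i in idxs]
        a = [after[i].winner_min for i in idxs]
        res = wilcoxon_signed_rank(b, a)
        out.append(
            {
                "trust_id": trust_id,
                "n_incidents": len(idxs),
                "mean_before_min": float(np.mean(b)),
                "mean_after_min": float(np.mean(a)),
                "p_value": res.p_value,
            }
        )
    return out


def cost_model(n_drones: int, spec: CostSpec = CostSpec()) -> float:
    """Lifetime cost of the fleet: purchase plus annual maintenance at
    ``maintenance_rate`` of the purchase price over ``lifespan_years``.

    n x unit_cost x (1 + maintenance_rate x lifespan_years).
    """
    if n_drones < 0:
        raise ValueError("n_drones must be >= 0")
    return n_drones * spec.unit_cost * (1.0 + spec.maintenance_rate * spec.lifespan_years)


def workload(
    annual_events: float, n_stations: int, operators_per_station: int = 1
) -> tuple[float, float]:
    """Projected monthly flight workload.

    Returns ``(flights per station per month, flights per operator per
    month)`` assuming events are spread evenly over stations and months.
    """
    if n_stations < 1 or operators_per_station < 1:
        raise ValueError("stations and operators must be >= 1")
    if annual_events < 0:
        raise ValueError("annual_events must be >= 0")
    per_station = annual_events / (n_stations * 12.0)
    return per_station, per_station / operators_per_station
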