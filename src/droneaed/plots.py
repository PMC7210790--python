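"""Figure helpers mirroring the study's summary graphics: the
diminishing-returns curve, time-threshold coverage bars, responder-mix
bars, and before/after boxplots."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .analysis import SweepCurve


def plot_sweep(curve: SweepCurve, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.k_values, curve.best_fitness_min, marker="o")
    ax.set_xlabel("number of drone bases (k)")
    ax.set_ylabel("mean response time (min)")
    ax.set_title("Effect of adding drone bases on response time")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_coverage(
    thresholds: Sequence[float],
    before: Sequence[float],
    after: Sequence[float],
    path: str | Path,
) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    x = range(len(thresholds))
    w = 0.4
    ax.bar([i - w / 2 for i in x], [100 * f for f in before], width=w, label="before")
    ax.bar([i + w / 2 for i in x], [100 * f for f in after], width=w, label="after")
    ax.set_xticks(list(x), [f"< {t:g} min" for t in thresholds])
    ax.set_ylabel("% of incidents reached")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_mix(mix_before: dict, mix_after: dict, path: str | Path) -> None:
    kinds = ["ambulance", "public_aed", "drone"]
    fig, ax = plt.subplots(figsize=(6, 4))
    x = range(len(kinds))
    w = 0.4
    ax.bar([i - w / 2 for i in x], [mix_before[k]["count"] for k in kinds], width=w, label="before")
    ax.bar([i + w / 2 for i in x], [mix_after[k]["count"] for k in kinds], width=w, label="after")
    ax.set_xticks(list(x), kinds)
    ax.set_ylabel("responses won")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_before_after_box(
    before_min: Sequence[float], after_min: Sequence[float], path: str | Path
) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.boxplot([list(before_min), list(after_min)], tick_labels=["before", "after"], showfliers=False)
    ax.set_ylabel("response time (min)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
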