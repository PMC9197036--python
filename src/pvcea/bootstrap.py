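"""Nonparametric percentile-bootstrap inference and the CE plane.

The resampling unit is the subject, resampled with replacement within arm.
Confidence intervals are empirical percentile intervals (the ``perc``
convention): the alpha/2 and 1-alpha/2 quantiles of the replicate statistics
under linear order-statistic interpolation.  Cost and effectiveness are
resampled jointly within each replicate, which is what makes the
cost-effectiveness plane (one point per replicate: difference in
effectiveness vs difference in cost, bundled minus standard) meaningful.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "BootstrapSpec",
    "CEPlanePoint",
    "CEAResult",
    "bootstrap_percentile_ci",
    "percentile_interval",
    "bootstrap_arm_replicates",
    "ce_plane",
    "dominance_verdict",
]


@dataclasses.dataclass(frozen=True)
class BootstrapSpec:
    n_replicates: int = 1000
    ci_level: float = 0.95
    method: str = "percentile"
    seed: int = 0

    def validate(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")
        if self.method != "percentile":
            raise ValueError("only the percentile interval method is supported")


@dataclasses.dataclass(frozen=True)
class CEPlanePoint:
    """One bootstrap replicate on the cost-effectiveness plane.

    ``delta_effect``: difference in unscheduled removals per PVC-day, bundled
    minus standard (negative = fewer removals = more effective).
    ``delta_cost``: EUR per patient-PVC-day, bundled minus standard
    (negative = saving).
    """

    delta_effect: float
    delta_cost: float


@dataclasses.dataclass(frozen=True)
class CEAResult:
    """Per-arm means with percentile CIs, deltas, and the dominance verdict."""

    mean_cost: dict
    mean_cost_ci: dict
    effectiveness: dict
    effectiveness_ci: dict
    delta_cost: float
    delta_cost_ci: tuple[float, float]
    delta_effect: float
    verdict: str


def percentile_interval(
    replicates: np.ndarray, ci_level: float
) -> tuple[float, float]:
    alpha = 1.0 - ci_level
    lo, hi = np.quantile(replicates, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def bootstrap_percentile_ci(
    per_subject_values: Sequence[float],
    statistic: Callable[[np.ndarray], float],
    spec: BootstrapSpec,
) -> tuple[float, float, float]:
    """Percentile bootstrap CI for a statistic of per-subject values.

    Returns (point estimate on the full sample, CI low, CI high).
    """
    spec.validate()
    values = np.asarray(per_subject_values, dtype=float)
    if values.size < 2:
        raise ValueError("bootstrap requires at least 2 subjects")
    rng = np.random.default_rng(spec.seed)
    reps = np.empty(spec.n_replicates)
    for r in range(spec.n_replicates):
        reps[r] = statistic(values[rng.integers(0, values.size, values.size)])
    lo, hi = percentile_interval(reps, spec.ci_level)
    return float(statistic(values)), lo, hi


def bootstrap_arm_replicates(
    arm_tables: dict,
    statistic: Callable[[dict], dict],
    spec: BootstrapSpec,
) -> list[dict]:
    """Joint within-arm subject resampling.

    ``arm_tables`` maps arm label to an (n_subjects x k) array of per-subject
    quantities; ``statistic`` maps the resampled tables to a dict of
    replicate-level statistics.  Subjects are resampled with replacement
    independently within each arm, jointly across their columns.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    out = []
    labels = sorted(arm_tables)
    for _ in range(spec.n_replicates):
        resampled = {}
        for label in labels:
            tab = arm_tables[label]
            idx = rng.integers(0, tab.shape[0], tab.shape[0])
            resampled[label] = tab[idx]
        out.append(statistic(resampled))
    return out


def ce_plane(replicate_stats: Sequence[dict]) -> list[CEPlanePoint]:
    """Extract CE-plane points from replicate statistics produced by the
    reporting layer (keys ``delta_effect_per_day`` and ``delta_cost_per_day``)."""
    return [
        CEPlanePoint(
            delta_effect=float(r["delta_effect_per_day"]),
            delta_cost=float(r["delta_cost_per_day"]),
        )
        for r in replicate_stats
    ]


def dominance_verdict(delta_cost: float, delta_effect_improvement: float) -> str:
    """Cost-effectiveness verdict.

    ``delta_effect_improvement`` is oriented so that positive means the
    assessed strategy is more effective.  Returns "dominant", "dominated",
    "equivalent", "cost difference only", or "icer:<EUR per unit>".
    """
    if not np.isfinite(delta_cost) or not np.isfinite(delta_effect_improvement):
        raise ValueError("deltas must be finite")
    if delta_cost == 0.0 and delta_effect_improvement == 0.0:
        return "equivalent"
    if delta_effect_improvement == 0.0:
        return "cost difference only"
    if delta_cost < 0.0 and delta_effect_improvement > 0.0:
        return "dominant"
    if delta_cost > 0.0 and delta_effect_improvement < 0.0:
        return "dominated"
    if delta_cost == 0.0:
        return "dominant" if delta_effect_improvement > 0.0 else "dominated"
    return f"icer:{delta_cost / delta_effect_improvement:.2f}"
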