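"""End-to-end scenario reports: simulate -> observe -> cost -> effect -> bootstrap.

A scenario report carries, per arm, the catheter-time-adjusted mean cost per
patient with its percentile-bootstrap CI, the effectiveness endpoint, the
per-PVC-day block (per-patient values divided by the arm's mean state-1
sojourn), the between-arm differences with CIs, and the dominance/ICER
verdict.  The catheter-time adjustment multiplies each arm's raw mean cost
by (longest arm mean state-1 sojourn) / (own arm mean state-1 sojourn), so
the shorter-exposure arm is scaled up (published coefficient 1.1618 for the
standard arm) and the longer arm is left unchanged.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io
import json
from typing import Sequence

import numpy as np

from .bootstrap import (
    BootstrapSpec,
    CEPlanePoint,
    dominance_verdict,
    percentile_interval,
)
from .cohort import CohortConfig, PatientTrajectory, generate_cohort
from .costs import BASE, CostSchedule, Scenario, cohort_cost_table
from .states import Arm, HealthState

__all__ = ["ScenarioReport", "analyse_scenario", "run_scenario", "run_all", "render_report"]

_ARMS = ("SDS", "BDS")


def _hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


@dataclasses.dataclass(frozen=True)
class ScenarioReport:
    scenario: str
    n: dict
    n_included: dict
    n_unscheduled: dict
    effectiveness_pct: dict
    mean_s1_sojourn: dict
    adjustment_coefficient: float
    mean_cost: dict
    mean_cost_ci: dict
    delta_cost: float
    delta_cost_ci: tuple
    delta_effect_per_100: float
    cost_per_day: dict
    cost_per_day_ci: dict
    effect_per_day: dict
    effect_per_day_ci: dict
    delta_cost_per_day: float
    delta_cost_per_day_ci: tuple
    delta_effect_per_day: float
    delta_effect_per_day_ci: tuple
    verdict: str
    provenance: dict
    ce_plane: tuple = ()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ce_plane"] = [
            {"delta_effect_per_day": p.delta_effect, "delta_cost_per_day": p.delta_cost}
            for p in self.ce_plane
        ]
        # JSON-canonical (tuples become lists) so renderings round-trip
        return json.loads(json.dumps(d))


def _subject_tables(
    cohort: Sequence[PatientTrajectory],
    schedule: CostSchedule,
    scenario: Scenario,
) -> dict[str, np.ndarray]:
    """Per-arm arrays of (per-patient cost, unscheduled flag, state-1 sojourn)
    for the subjects the scenario includes."""
    costs = cohort_cost_table(cohort, schedule, scenario)
    cost_by_id = dict(zip(costs["subject_id"], costs["total_per_patient"]))
    tables: dict[str, list] = {a: [] for a in _ARMS}
    for traj in cohort:
        if not scenario.includes(traj):
            continue
        s1 = traj.sojourn(HealthState.S1_NOEVENT_PVC1)
        tables[traj.arm.value].append(
            [
                cost_by_id[traj.subject_id],
                1.0 if traj.had_unscheduled_removal else 0.0,
                s1 if s1 is not None else 0.0,
            ]
        )
    for a in _ARMS:
        if not tables[a]:
            raise ValueError(f"arm {a} has no included subjects")
    return {a: np.asarray(tables[a]) for a in _ARMS}


def _replicate_stat(tables: dict[str, np.ndarray]) -> dict:
    """All replicate-level statistics from (possibly resampled) arm tables."""
    prop, soj, raw = {}, {}, {}
    for a in _ARMS:
        tab = tables[a]
        prop[a] = tab[:, 1].mean()
        unsch = tab[tab[:, 1] == 1.0]
        # adjustment sojourn: unscheduled subgroup, whole arm as fallback
        soj[a] = unsch[:, 2].mean() if len(unsch) else tab[:, 2].mean()
        raw[a] = tab[:, 0].mean()
    ref_soj = max(soj.values())
    adj = {a: raw[a] * ref_soj / soj[a] for a in _ARMS}
    out = {
        "prop": prop,
        "soj": soj,
        "cost": adj,
        "cost_per_day": {a: adj[a] / soj[a] for a in _ARMS},
        "effect_per_day": {a: prop[a] / soj[a] for a in _ARMS},
    }
    out["delta_cost"] = adj["BDS"] - adj["SDS"]
    out["delta_cost_per_day"] = out["cost_per_day"]["BDS"] - out["cost_per_day"]["SDS"]
    out["delta_effect_per_day"] = (
        out["effect_per_day"]["BDS"] - out["effect_per_day"]["SDS"]
    )
    return out


def analyse_scenario(
    cohort: Sequence[PatientTrajectory],
    schedule: CostSchedule,
    scenario: Scenario = BASE,
    spec: BootstrapSpec = BootstrapSpec(),
    provenance: dict | None = None,
) -> ScenarioReport:
    """Cost-effectiveness report for one scenario on a given cohort."""
    spec.validate()
    schedule.validate()
    tables = _subject_tables(cohort, schedule, scenario)
    point = _replicate_stat(tables)

    rng = np.random.default_rng(spec.seed)
    reps: list[dict] = []
    for _ in range(spec.n_replicates):
        resampled = {}
        for a in _ARMS:
            tab = tables[a]
            resampled[a] = tab[rng.integers(0, tab.shape[0], tab.shape[0])]
        reps.append(_replicate_stat(resampled))

    def ci(path) -> tuple[float, float]:
        values = np.array([path(r) for r in reps])
        return percentile_interval(values, spec.ci_level)

    n = {a: sum(t.arm.value == a for t in cohort) for a in _ARMS}
    n_unsch = {
        a: sum(t.arm.value == a and t.had_unscheduled_removal for t in cohort)
        for a in _ARMS
    }
    plane = tuple(
        CEPlanePoint(r["delta_effect_per_day"], r["delta_cost_per_day"]) for r in reps
    )
    improvement = point["prop"]["SDS"] - point["prop"]["BDS"]  # removals avoided
    report = ScenarioReport(
        scenario=scenario.label,
        n=n,
        n_included={a: int(tables[a].shape[0]) for a in _ARMS},
        n_unscheduled=n_unsch,
        effectiveness_pct={a: 100.0 * n_unsch[a] / n[a] for a in _ARMS},
        mean_s1_sojourn={a: float(point["soj"][a]) for a in _ARMS},
        adjustment_coefficient=float(point["soj"]["BDS"] / point["soj"]["SDS"]),
        mean_cost={a: float(point["cost"][a]) for a in _ARMS},
        mean_cost_ci={a: ci(lambda r, a=a: r["cost"][a]) for a in _ARMS},
        delta_cost=float(point["delta_cost"]),
        delta_cost_ci=ci(lambda r: r["delta_cost"]),
        delta_effect_per_100=100.0 * improvement,
        cost_per_day={a: float(point["cost_per_day"][a]) for a in _ARMS},
        cost_per_day_ci={a: ci(lambda r, a=a: r["cost_per_day"][a]) for a in _ARMS},
        effect_per_day={a: float(point["effect_per_day"][a]) for a in _ARMS},
        effect_per_day_ci={a: ci(lambda r, a=a: r["effect_per_day"][a]) for a in _ARMS},
        delta_cost_per_day=float(point["delta_cost_per_day"]),
        delta_cost_per_day_ci=ci(lambda r: r["delta_cost_per_day"]),
        delta_effect_per_day=float(point["delta_effect_per_day"]),
        delta_effect_per_day_ci=ci(lambda r: r["delta_effect_per_day"]),
        verdict=dominance_verdict(float(point["delta_cost"]), improvement),
        provenance={
            **(provenance or {}),
            "schedule_hash": _hash(schedule.to_dict()),
            "bootstrap_seed": spec.seed,
            "n_replicates": spec.n_replicates,
            "ci_level": spec.ci_level,
        },
        ce_plane=plane,
    )
    _check_consistency(report)
    return report


def _check_consistency(report: ScenarioReport) -> None:
    """Render-time cross-check: per-day values = per-patient / mean sojourn."""
    for a in _ARMS:
        expected = report.mean_cost[a] / report.mean_s1_sojourn[a]
        if abs(expected - report.cost_per_day[a]) > 1e-9:
            raise AssertionError(f"per-day cost inconsistent for arm {a}")


def run_scenario(
    config: CohortConfig,
    schedule: CostSchedule,
    scenario: Scenario = BASE,
    spec: BootstrapSpec = BootstrapSpec(),
) -> ScenarioReport:
    """Simulate one cohort from ``config`` and analyse one scenario."""
    cohort = generate_cohort(config)
    return analyse_scenario(
        cohort, schedule, scenario, spec,
        provenance={"config_hash": _hash(config.to_dict()), "cohort_seed": config.seed},
    )


def run_all(
    config: CohortConfig,
    schedule: CostSchedule,
    spec: BootstrapSpec = BootstrapSpec(),
    scenarios: Sequence[Scenario] = (BASE,),
) -> dict[str, ScenarioReport]:
    """Run several scenarios on ONE cohort realisation (paired deltas)."""
    from .costs import SCENARIO_1, SCENARIO_2

    if scenarios == (BASE,):
        scenarios = (BASE, SCENARIO_1, SCENARIO_2)
    cohort = generate_cohort(config)
    prov = {"config_hash": _hash(config.to_dict()), "cohort_seed": config.seed}
    return {
        sc.label: analyse_scenario(cohort, schedule, sc, spec, provenance=prov)
        for sc in scenarios
    }


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

_FORMATS = ("json", "csv", "text")


def render_report(report: ScenarioReport, format: str = "text") -> str:
    """Render a scenario report as lossless JSON, tidy CSV, or a table."""
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; supported: {', '.join(_FORMATS)}")
    _check_consistency(report)
    if format == "json":
        return json.dumps(report.to_dict(), indent=2)
    if format == "csv":
        buf = io.StringIO()
        buf.write("scenario,arm,metric,value,ci_low,ci_high\n")

        def row(arm, metric, value, ci=None):
            lo, hi = ("", "") if ci is None else (ci[0], ci[1])
            buf.write(f"{report.scenario},{arm},{metric},{value},{lo},{hi}\n")

        for a in _ARMS:
            row(a, "mean_cost_per_patient", report.mean_cost[a], report.mean_cost_ci[a])
            row(a, "effectiveness_pct", report.effectiveness_pct[a])
            row(a, "mean_s1_sojourn_days", report.mean_s1_sojourn[a])
            row(a, "cost_per_pvc_day", report.cost_per_day[a], report.cost_per_day_ci[a])
            row(a, "effect_per_pvc_day", report.effect_per_day[a], report.effect_per_day_ci[a])
        row("BDS-SDS", "delta_cost_per_patient", report.delta_cost, report.delta_cost_ci)
        row("SDS-BDS", "delta_effect_per_100", report.delta_effect_per_100)
        row("BDS-SDS", "delta_cost_per_pvc_day", report.delta_cost_per_day, report.delta_cost_per_day_ci)
        row("BDS-SDS", "delta_effect_per_pvc_day", report.delta_effect_per_day, report.delta_effect_per_day_ci)
        row("", "verdict", report.verdict)
        return buf.getvalue()

    # human-readable table mirroring the per-patient / per-PVC-day blocks
    lines = [
        f"Scenario: {report.scenario}   (seed {report.provenance.get('cohort_seed')},"
        f" {report.provenance.get('n_replicates')} bootstrap replicates)",
        f"{'':38s}{'SDs (reference)':>24s}{'BDs (assessed)':>24s}",
    ]

    def fmt(val, ci):
        return f"{val:9.2f} ({ci[0]:.1f}; {ci[1]:.1f})"

    lines.append(
        f"{'Mean cost/patient, adj. (95% CI)':38s}"
        f"{fmt(report.mean_cost['SDS'], report.mean_cost_ci['SDS']):>24s}"
        f"{fmt(report.mean_cost['BDS'], report.mean_cost_ci['BDS']):>24s}"
    )
    lines.append(
        f"{'Unscheduled removal n/N (%)':38s}"
        f"{report.n_unscheduled['SDS']}/{report.n['SDS']:d} "
        f"({report.effectiveness_pct['SDS']:.2f}%)".rjust(24)
        + f"{report.n_unscheduled['BDS']}/{report.n['BDS']:d} "
        f"({report.effectiveness_pct['BDS']:.2f}%)".rjust(24)
    )
    lines.append(
        f"{'Cost/PVC-day (95% CI)':38s}"
        f"{fmt(report.cost_per_day['SDS'], report.cost_per_day_ci['SDS']):>24s}"
        f"{fmt(report.cost_per_day['BDS'], report.cost_per_day_ci['BDS']):>24s}"
    )
    lines.append(
        f"{'Removals/PVC-day (95% CI)':38s}"
        + f"{report.effect_per_day['SDS']:.4f} "
        f"({report.effect_per_day_ci['SDS'][0]:.4f}; {report.effect_per_day_ci['SDS'][1]:.4f})".rjust(24)
        + f"{report.effect_per_day['BDS']:.4f} "
        f"({report.effect_per_day_ci['BDS'][0]:.4f}; {report.effect_per_day_ci['BDS'][1]:.4f})".rjust(24)
    )
    lines.append(
        f"{'Delta cost/patient (BDs-SDs)':38s}"
        f"{fmt(report.delta_cost, report.delta_cost_ci):>48s}"
    )
    lines.append(
        f"{'Delta effectiveness (SDs-BDs)':38s}"
        f"{report.delta_effect_per_100:+.2f} patients / 100".rjust(48)
    )
    lines.append(
        f"{'Delta cost/PVC-day (BDs-SDs)':38s}"
        f"{fmt(report.delta_cost_per_day, report.delta_cost_per_day_ci):>48s}"
    )
    lines.append(
        f"{'Delta removals/PVC-day (BDs-SDs)':38s}"
        + f"{report.delta_effect_per_day:+.4f} "
        f"({report.delta_effect_per_day_ci[0]:.4f}; {report.delta_effect_per_day_ci[1]:.4f})".rjust(36)
    )
    verdict = report.verdict
    if verdict == "dominant":
        verdict = "BDs dominate SDs (less costly, more effective)"
    lines.append(f"{'ICER / dominance':38s}{verdict:>48s}")
    return "\n".join(lines)
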