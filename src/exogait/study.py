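"""Condition-suite orchestration: unassisted + 15 device simulations.

Runs the full set of assistance conditions on one gait cycle with a
deterministic warm-start cascade that also makes the feasibility-nesting
orderings numerically reliable:

* the unassisted problem is solved coarse-to-fine (a coarse-mesh presolve
  warm-starts the production mesh, avoiding poor local basins);
* each single-joint device starts from the unassisted solution (equal
  objective at the start, so the single-joint optimum cannot be worse);
* each multi-joint independent device starts from the best constituent
  single-joint solution (its feasible set contains that solution);
* each coupled device starts from its independent counterpart collapsed onto
  one shared control, since coupled feasible sets are subsets of independent
  ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .collocation import OCPConfig, OCPSolution, build_problem, solve
from .devices import DeviceSpec, enumerate_conditions
from .gait_cycle import GaitCycle
from .metabolics import MetabolicConfig, MetabolicReport, PercentChangeReport, percent_change
from .muscle import MuscleSetModel
from .reporting import DeviceMetrics, device_power_metrics, metabolic_report


@dataclass
class ConditionResult:
    spec: DeviceSpec
    solution: OCPSolution
    report: MetabolicReport
    percent_change: PercentChangeReport | None
    device_metrics: DeviceMetrics | None


@dataclass
class StudyResult:
    """All condition results for one gait cycle, keyed by identifier."""

    conditions: dict[str, ConditionResult]

    @property
    def unassisted(self) -> ConditionResult:
        return self.conditions["unassisted"]

    def savings_table(self) -> pd.DataFrame:
        """Percent change in gross rate per device (negative = savings)."""
        rows = []
        for ident, res in self.conditions.items():
            if ident == "unassisted":
                continue
            rows.append({"device": ident,
                         "percent_change": res.percent_change.total,
                         "objective": res.solution.objective})
        return pd.DataFrame(rows)


def run_condition_suite(cycle: GaitCycle, muscle_set: MuscleSetModel,
                        config: OCPConfig | None = None,
                        conditions: list[DeviceSpec] | None = None,
                        coarse_mesh_per_s: float = 20.0,
                        metabolic: MetabolicConfig | None = None,
                        unassisted: OCPSolution | None = None) -> StudyResult:
    cfg = config or OCPConfig(mesh_per_s=50.0)
    met = metabolic or cfg.metabolic
    if conditions is None:
        conditions = enumerate_conditions()

    if unassisted is None:
        coarse_cfg = OCPConfig(**{**cfg.__dict__, "mesh_per_s": coarse_mesh_per_s})
        sol_coarse = solve(build_problem(cycle, muscle_set, config=coarse_cfg))
        unassisted_sol = solve(build_problem(cycle, muscle_set, config=cfg),
                               warm_start=sol_coarse)
    else:
        unassisted_sol = unassisted
    un_report = metabolic_report(unassisted_sol, cycle, muscle_set, met)
    results: dict[str, ConditionResult] = {
        "unassisted": ConditionResult(DeviceSpec(), unassisted_sol, un_report,
                                      None, None)}

    def run(spec: DeviceSpec, warm: OCPSolution) -> ConditionResult:
        sol = solve(build_problem(cycle, muscle_set, spec, cfg), warm_start=warm)
        rep = metabolic_report(sol, cycle, muscle_set, met,
                               condition=spec.identifier)
        return ConditionResult(spec, sol, rep, percent_change(rep, un_report),
                               device_power_metrics(sol, cycle, spec))

    singles = [c for c in conditions if c.mode == "single"]
    multis_ind = [c for c in conditions if c.mode == "independent"]
    multis_cpl = [c for c in conditions if c.mode == "coupled"]

    for spec in singles:
        results[spec.identifier] = run(spec, unassisted_sol)
    for spec in multis_ind:
        constituents = [results[DeviceSpec(directions=(d,), mode="single").identifier]
                        for d in spec.directions
                        if DeviceSpec(directions=(d,), mode="single").identifier in results]
        warm = min((c.solution for c in constituents),
                   key=lambda s: s.objective, default=unassisted_sol)
        results[spec.identifier] = run(spec, warm)
    for spec in multis_cpl:
        ind_id = spec.identifier.replace("/coupled", "/independent")
        warm = results[ind_id].solution if ind_id in results else unassisted_sol
        results[spec.identifier] = run(spec, warm)

    # ordering-repair pass: feasible sets nest (single within its multi-joint
    # independent superset, coupled within independent), so any inverted
    # objective ordering marks a poorer local basin -- re-solve the
    # should-be-better problem warm-started from the better counterpart
    def polish(target_id, donor_sol):
        cand = run(results[target_id].spec, donor_sol)
        if cand.solution.objective < results[target_id].solution.objective:
            results[target_id] = cand

    constituents = {spec.identifier: tuple(
        DeviceSpec(directions=(d,), mode="single").identifier
        for d in spec.directions) for spec in multis_ind}
    for _ in range(2):
        for spec in multis_ind:
            ind_id = spec.identifier
            cpl_id = ind_id.replace("/independent", "/coupled")
            for s in constituents[ind_id]:
                if s in results and results[ind_id].solution.objective \
                        > results[s].solution.objective:
                    polish(ind_id, results[s].solution)
            if cpl_id in results and results[ind_id].solution.objective \
                    > results[cpl_id].solution.objective:
                polish(ind_id, results[cpl_id].solution)
    return StudyResult(results)


def multi_subject_table(study_fn, subjects: int, devices: list[str],
                        rng: np.random.Generator) -> pd.DataFrame:
    """Helper for statistics tests: stack per-subject savings tables."""
    rows = []
    for s in range(subjects):
        tab = study_fn(s)
        for dev in devices:
            rows.append({"subject": f"S{s}", "device": dev,
                         "percent_change": tab[dev]})
    return pd.DataFrame(rows)
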