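"""Three-step muscle-parameter calibration.

Step 1 scales maximum isometric forces by a linear muscle-volume vs
body-mass regression.  Step 2 fits optimal fiber lengths, tendon slack
lengths and passive strain parameters to experimental passive joint moments
under a rigid-tendon assumption (weighted nonlinear least squares with a
passive-force penalty and a deviation penalty).  Step 3 refits optimal fiber
lengths and tendon slack lengths (passive strains frozen) within +/-25% of
their step-2 values by solving a tracking optimal-control problem whose
primary term is the error between EMG and muscle excitations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.optimize import least_squares

from .collocation import OCPConfig, OCPSolution, build_problem, solve
from .gait_cycle import GaitCycle
from .muscle import (MuscleSetModel, joint_moments_from_muscles,
                     rigid_tendon_passive_force)
from .synthetic import PassiveMomentData, PlanarGeometry


class CalibrationError(RuntimeError):
    pass


@dataclass
class CalibrationResult:
    """Updated parameters plus the objective breakdown of the fitting step."""

    muscle_set: MuscleSetModel
    objective_breakdown: dict[str, float]
    bound_active: dict[str, np.ndarray] = field(default_factory=dict)
    solution: OCPSolution | None = None


# ---------------------------------------------------------------------------
# step 1: force scaling by the muscle-volume vs body-mass regression
# ---------------------------------------------------------------------------

#: linear lower-limb muscle-volume regression v(m) = slope*m + intercept, cm^3
VOLUME_REGRESSION = {"slope": 47.0, "intercept": 1285.0, "reference_mass": 75.0}


def scale_max_isometric_forces(muscle_set: MuscleSetModel, body_mass: float,
                               regression: Mapping[str, float] | None = None
                               ) -> MuscleSetModel:
    """Scale every f_max by predicted-volume(body_mass)/predicted-volume(ref).

    The documented default regression is linear in total body mass; a pure
    mass change therefore preserves the force proportions among muscles.
    """
    if body_mass <= 0:
        raise CalibrationError("body_mass must be > 0")
    reg = dict(VOLUME_REGRESSION)
    if regression:
        reg.update(regression)
    factor = (reg["slope"] * body_mass + reg["intercept"]) \
        / (reg["slope"] * reg["reference_mass"] + reg["intercept"])
    updated = {m.name: replace(m, f_max=m.f_max * factor)
               for m in muscle_set.muscles}
    return muscle_set.with_params(updated)


# ---------------------------------------------------------------------------
# step 2: passive-moment fitting (rigid tendon)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PassiveFitConfig:
    moment_weight: float = 1.0             # per N.m of moment error
    passive_force_weight: float = 1.0e-4   # per unit of F_passive / f_max
    deviation_weight: float = 1.0e-3       # per relative parameter deviation
    bound_halfwidth: float = 0.25          # +/- box around initial values
    max_nfev: int = 1200


def fit_passive_parameters(muscle_set: MuscleSetModel, data: PassiveMomentData,
                           geometry: PlanarGeometry | None = None,
                           config: PassiveFitConfig = PassiveFitConfig(),
                           free_params: tuple[str, ...] = (
                               "l_m_opt", "l_t_slack", "passive_strain")
                           ) -> CalibrationResult:
    """Fit {l_m_opt, l_t_slack, passive_strain} to passive joint moments.

    Weighted least squares of the rigid-tendon model moments against the
    measured moments, plus secondary residuals minimizing total passive force
    and parameter deviations from the initial values.  Bounds: +/-25% boxes.
    ``free_params`` restricts the fit to a subset (the three parameter
    families trade off against each other on smooth posture sets, so
    single-family fits are better identified).
    """
    geom = geometry or PlanarGeometry()
    ms = muscle_set
    names = ms.names
    n_m = len(names)
    l_mt = geom.mtu_lengths(data.postures)          # (P, M)
    arms = geom.moment_arms(data.postures)          # (P, M, 3)

    p_full = np.concatenate([ms.array("l_m_opt"), ms.array("l_t_slack"),
                             ms.array("passive_strain_at_fmax")])
    families = ("l_m_opt", "l_t_slack", "passive_strain")
    free = np.zeros(3 * n_m, dtype=bool)
    for fam in free_params:
        if fam not in families:
            raise CalibrationError(f"unknown parameter family {fam!r}")
        i = families.index(fam)
        free[i * n_m:(i + 1) * n_m] = True

    p0 = p_full[free]
    lo = p0 * (1.0 - config.bound_halfwidth)
    hi = p0 * (1.0 + config.bound_halfwidth)
    w_m = np.sqrt(np.asarray(data.weights, dtype=float)) * np.sqrt(config.moment_weight)

    def expand(p: np.ndarray) -> np.ndarray:
        full = p_full.copy()
        full[free] = p
        return full

    def build_set(p: np.ndarray) -> MuscleSetModel:
        full = expand(p)
        upd = {}
        for i, m in enumerate(ms.muscles):
            upd[m.name] = replace(m, l_m_opt=float(full[i]),
                                  l_t_slack=float(full[n_m + i]),
                                  passive_strain_at_fmax=float(full[2 * n_m + i]))
        return ms.with_params(upd)

    def passive_forces(p: np.ndarray) -> np.ndarray:
        cand = build_set(p)
        return np.column_stack([
            rigid_tendon_passive_force(l_mt[:, i], mp)
            for i, mp in enumerate(cand.muscles)])

    f_max = ms.array("f_max")

    def residuals(p: np.ndarray) -> np.ndarray:
        forces = passive_forces(p)
        moments = joint_moments_from_muscles(forces, arms)
        r_mom = (w_m * (moments - data.moments)).ravel()
        r_force = np.sqrt(config.passive_force_weight) \
            * (forces / f_max[None, :]).ravel()
        r_dev = np.sqrt(config.deviation_weight) * (p - p0) / p0
        return np.concatenate([r_mom, r_force, r_dev])

    res = least_squares(residuals, p0, bounds=(lo, hi),
                        max_nfev=config.max_nfev, method="trf")
    if not res.success and res.status <= 0:
        raise CalibrationError(f"passive fit did not converge: {res.message}")
    p = res.x
    forces = passive_forces(p)
    moments = joint_moments_from_muscles(forces, arms)
    breakdown = {
        "passive_moment_error": float(np.sum((w_m * (moments - data.moments)) ** 2)),
        "passive_force_penalty": float(config.passive_force_weight
                                       * np.sum((forces / f_max[None, :]) ** 2)),
        "deviation_penalty": float(config.deviation_weight
                                   * np.sum(((p - p0) / p0) ** 2)),
    }
    tol = 1e-8
    bound_active = {"lower": p - lo < tol * p0, "upper": hi - p < tol * p0}
    return CalibrationResult(muscle_set=build_set(p),
                             objective_breakdown=breakdown,
                             bound_active=bound_active)


# ---------------------------------------------------------------------------
# step 3: EMG-informed refit via a tracking OCP
# ---------------------------------------------------------------------------

def calibrate_to_emg(muscle_set: MuscleSetModel, cycle: GaitCycle,
                     config: OCPConfig | None = None,
                     warm_start: OCPSolution | None = None) -> CalibrationResult:
    """Refit l_m_opt and l_t_slack (+/-25%, passive strains frozen) to EMG.

    Solves the muscle-redundancy tracking problem with the parameter scales
    as static decision variables.  The objective's primary term is the
    squared error between EMG and muscle excitations over the muscles with
    measured EMG (unmeasured muscles, e.g. iliopsoas, are simply excluded
    from the tracking term); secondary terms penalize passive force and
    activation.  ``muscle_set`` should be the step-2 result (the initial
    guess and the center of the +/-25% box).
    """
    if cycle.emg is None or len(cycle.emg) == 0:
        raise CalibrationError("cycle has no EMG; step 3 requires EMG data")
    cfg = config or OCPConfig(mesh_per_s=50.0)
    # tracking objectives are O(1e-2), so the stationarity tolerance maps
    # two decades below the moment-matching default; the secondary effort
    # terms stay well below the tracking term so they aid convergence
    # without biasing the fitted parameters
    cfg = replace(cfg, objective="emg_tracking", calibrate_params=True,
                  nlp_tol=min(cfg.nlp_tol, 3e-5),
                  w_excitation=min(cfg.w_excitation, 0.005),
                  w_activation=min(cfg.w_activation, 0.005),
                  w_passive=min(cfg.w_passive, 0.001))
    # collocate on the cycle's own grid when it is uniform and at least as
    # fine as the requested mesh: the sampled dynamics are then representable
    # without interpolation bias
    node_times = None
    dt = np.diff(cycle.time)
    if np.allclose(dt, dt[0]) and (len(cycle.time) - 1) \
            >= cfg.mesh_per_s * cycle.duration:
        node_times = cycle.time
    # stage 1: fit the trajectories with the parameters frozen, so the
    # parameter stage starts from an EMG-consistent state
    if warm_start is None:
        cfg1 = replace(cfg, calibrate_params=False)
        ocp1 = build_problem(cycle, muscle_set, config=cfg1,
                             node_times=node_times)
        warm_start = solve(ocp1)
    ocp = build_problem(cycle, muscle_set, config=cfg, node_times=node_times)
    sol = solve(ocp, warm_start=warm_start)
    s_lopt = sol.param_scales["l_m_opt"]
    s_lts = sol.param_scales["l_t_slack"]
    fitted = muscle_set.scaled(s_lopt, s_lts)
    lo, hi = cfg.param_scale_bounds
    bound_active = {
        "lower": np.concatenate([s_lopt - lo, s_lts - lo]) < 1e-6,
        "upper": np.concatenate([hi - s_lopt, hi - s_lts]) < 1e-6,
    }
    breakdown = dict(sol.objective_terms)
    return CalibrationResult(muscle_set=fitted, objective_breakdown=breakdown,
                             bound_active=bound_active, solution=sol)


def calibrate(muscle_set: MuscleSetModel, body_mass: float,
              passive_data: PassiveMomentData, cycle: GaitCycle,
              geometry: PlanarGeometry | None = None,
              ocp_config: OCPConfig | None = None) -> CalibrationResult:
    """Run all three calibration steps in sequence."""
    step1 = scale_max_isometric_forces(muscle_set, body_mass)
    step2 = fit_passive_parameters(step1, passive_data, geometry)
    step3 = calibrate_to_emg(step2.muscle_set, cycle, config=ocp_config)
    merged = {**step2.objective_breakdown,
              **{f"emg_{k}": v for k, v in step3.objective_breakdown.items()}}
    return CalibrationResult(muscle_set=step3.muscle_set,
                             objective_breakdown=merged,
                             bound_active=step3.bound_active,
                             solution=step3.solution)
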