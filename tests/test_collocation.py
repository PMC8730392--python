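"""Transcription structure, analytic toy problems, and mesh refinement."""

import numpy as np
import pytest

from exogait.collocation import (OCPConfig, OCPError, build_problem,
                                 refine_mesh, solve,
                                 variable_constraint_counts,
                                 _interval_dynamics_errors, _Transcription)
from exogait.devices import DeviceSpec, make_device
from exogait.gait_cycle import GaitCycle
from exogait.muscle import MuscleParams


class ToyMuscleSet:
    """Minimal muscle-set protocol for single-muscle analytic problems."""

    def __init__(self, *muscles: MuscleParams, spans=None):
        self.muscles = tuple(muscles)
        self._spans = spans or [(False, False, True)] * len(muscles)

    @property
    def names(self):
        return tuple(m.name for m in self.muscles)

    def array(self, attr):
        return np.array([getattr(m, attr) for m in self.muscles])

    def span_matrix(self):
        return np.array(self._spans, dtype=bool)


def toy_problem(net_ankle_moment=-30.0, device=DeviceSpec(), n=26,
                duration=0.5, scheme="trapezoid", mesh_per_s=40.0):
    """One ankle plantarflexor holding a constant moment at a fixed posture."""
    p = MuscleParams(name="toy_pf", f_max=3000.0, l_m_opt=0.1, l_t_slack=0.2,
                     pennation_opt=0.0)
    ms = ToyMuscleSet(p)
    t = np.linspace(0.0, duration, n)
    z = np.zeros((n, 3))
    moments = np.zeros((n, 3))
    moments[:, 2] = net_ankle_moment
    arms = np.zeros((n, 1, 3))
    arms[:, 0, 2] = -0.05  # plantarflexor: negative arm, force ~ -moment
    cycle = GaitCycle(time=t, joint_angles=z, joint_velocities=z,
                      net_moments=moments,
                      mtu_lengths=np.full((n, 1), 0.3),
                      mtu_velocities=np.zeros((n, 1)),
                      moment_arms=arms, body_mass=72.4,
                      muscle_names=("toy_pf",))
    cfg = OCPConfig(mesh_per_s=mesh_per_s, scheme=scheme)
    return build_problem(cycle, ms, device, cfg), p


def test_build_problem_structure(ground_truth):
    cyc, ms = ground_truth["cycle"], ground_truth["muscle_set"]
    cfg = OCPConfig(mesh_per_s=30.0)

    un = build_problem(cyc, ms, config=cfg)
    c_un = variable_constraint_counts(un)
    n1 = un.n_intervals + 1
    # hand-computed: per node 4 muscle blocks x 9 + 3 reserves
    assert c_un["n_variables"] == n1 * (4 * 9 + 3)
    # eq + 2 defect families + moment rows + state periodicity
    assert c_un["n_constraints"] == n1 * 9 + 2 * (n1 - 1) * 9 + n1 * 3 + 18
    assert c_un["n_device_trajectories"] == 0

    cpl = build_problem(cyc, ms, make_device("hf+kf+ap/coupled"), cfg)
    c_cpl = variable_constraint_counts(cpl)
    assert c_cpl["n_device_trajectories"] == 1  # one shared control signal
    assert c_cpl["n_gains"] == 3
    assert c_cpl["n_variables"] == n1 * (4 * 9 + 3 + 1) + 3

    ind = build_problem(cyc, ms, make_device("hf+kf+ap/independent"), cfg)
    c_ind = variable_constraint_counts(ind)
    assert c_ind["n_device_trajectories"] == 3
    assert c_ind["n_gains"] == 0


def test_missing_moment_arm_rejected(ground_truth):
    cyc, ms = ground_truth["cycle"], ground_truth["muscle_set"]
    broken = GaitCycle(
        time=cyc.time, joint_angles=cyc.joint_angles,
        joint_velocities=cyc.joint_velocities, net_moments=cyc.net_moments,
        mtu_lengths=cyc.mtu_lengths, mtu_velocities=cyc.mtu_velocities,
        moment_arms=np.zeros_like(cyc.moment_arms), body_mass=cyc.body_mass)
    with pytest.raises(OCPError, match="moment arms"):
        build_problem(broken, ms)


def test_mesh_minimum_enforced(ground_truth):
    cyc, ms = ground_truth["cycle"], ground_truth["muscle_set"]
    with pytest.raises(OCPError):
        build_problem(cyc, ms, node_times=np.linspace(0, cyc.duration, 6))


@pytest.mark.parametrize("scheme", ["trapezoid", "radau"])
def test_single_muscle_toy_matches_analytic_activation(scheme):
    """Constant moment tau, constant arm r: activation ~= tau / (r * f_max)."""
    ocp, p = toy_problem(scheme=scheme)
    sol = solve(ocp)
    assert sol.success
    predicted = 30.0 / (0.05 * p.f_max)
    inner = slice(2, -2)
    assert np.max(np.abs(sol.activations[inner, 0] - predicted)) < 0.02
    # reserves negligible under the heavy penalty
    assert np.max(np.abs(sol.reserves)) < 1.0
    assert sol.max_moment_residual < 0.1
    assert sol.max_defect < 1e-4


@pytest.mark.parametrize("scheme", ["trapezoid", "radau"])
def test_assisted_toy_device_takes_over(scheme):
    """A device able to cover the whole moment drives muscle cost to ~basal."""
    spec = make_device("ap")  # plantarflexion assist, 2 N.m/kg >> demand
    ocp, p = toy_problem(device=spec, scheme=scheme)
    sol = solve(ocp)
    assert sol.success
    assert np.max(sol.activations) < 0.06
    # near-basal whole-body cost (the A^0.6 heat term is steep near zero, so
    # a few percent of residual activation still leaves a small remainder)
    basal = ocp.config.metabolic.basal_rate
    assert sol.objective_terms["metabolic"] < basal + 0.5
    unassisted, _ = toy_problem(scheme=scheme)
    assert sol.objective_terms["metabolic"] < \
        solve(unassisted).objective_terms["metabolic"] * 0.55
    # the device torque carries the moment
    tau_dev = sol.device_controls[:, 0] * 2.0 * 72.4
    assert np.median(tau_dev) == pytest.approx(30.0, rel=0.1)


def test_unassisted_equals_zero_controlled_device():
    """Forcing device controls to ~0 reproduces the unassisted objective."""
    ocp_un, _ = toy_problem()
    sol_un = solve(ocp_un)
    spec = DeviceSpec(directions=("ankle_plantarflexion",), mode="single",
                      torque_limits={"ankle_plantarflexion": 1e-6})
    ocp_dev, _ = toy_problem(device=spec)
    sol_dev = solve(ocp_dev)
    assert sol_dev.objective == pytest.approx(sol_un.objective, abs=2e-3)


def test_solution_diagnostics_recomputed_from_trajectories(unassisted_solution,
                                                           ground_truth):
    """Defects and moment residuals come from the returned trajectories."""
    sol = unassisted_solution
    assert sol.success
    assert sol.max_defect < 1e-4
    assert sol.max_moment_residual < 1e-3 * ground_truth["cycle"].body_mass


def test_ground_truth_recovery(unassisted_solution, ground_truth):
    """Unassisted solve on the ground-truth cycle recovers the activations."""
    from scipy.interpolate import CubicSpline

    gt = ground_truth
    sol = unassisted_solution
    a_true = CubicSpline(gt["cycle"].time, gt["activations"], axis=0)(sol.time)
    rms = np.sqrt(np.mean((sol.activations - a_true) ** 2))
    assert rms < 0.05


def test_mesh_convergence(unassisted_solution, unassisted_tight, ground_truth):
    """Converged objective at mesh 50/s within 1% of a 100/s solution."""
    cyc, ms = ground_truth["cycle"], ground_truth["muscle_set"]
    fine = build_problem(cyc, ms, config=OCPConfig(mesh_per_s=100.0))
    sol_fine = solve(fine, warm_start=unassisted_solution)
    assert sol_fine.success
    rel = abs(unassisted_tight.objective - sol_fine.objective) \
        / sol_fine.objective
    assert rel < 0.01


def test_refine_mesh_monotone_improvement(ground_truth):
    """A deliberately coarse mesh is subdivided and its defect shrinks."""
    cyc, ms = ground_truth["cycle"], ground_truth["muscle_set"]
    coarse = build_problem(cyc, ms, config=OCPConfig(mesh_per_s=11.0))
    sol0 = solve(coarse)
    errs0 = _interval_dynamics_errors(coarse, sol0)
    refined, sol1 = refine_mesh(coarse, sol0, refine_tol=1e-3,
                                max_refinements=2)
    assert refined.n_intervals > coarse.n_intervals
    errs1 = _interval_dynamics_errors(refined, sol1)
    assert errs1.max() < errs0.max()


def test_refine_mesh_no_op_below_tolerance():
    ocp, _ = toy_problem()  # constant problem: dynamics errors ~ 0
    sol = solve(ocp)
    refined, sol2 = refine_mesh(ocp, sol, refine_tol=1e-3)
    assert refined.n_intervals == ocp.n_intervals
    assert sol2 is sol


def test_interval_error_estimates_match_ivp_oracle(unassisted_solution,
                                                   ground_truth):
    """The refinement error estimator agrees with an independent integration."""
    from scipy.integrate import solve_ivp
    from exogait.muscle import activation_rate

    gt = ground_truth
    sol = unassisted_solution
    ocp = build_problem(gt["cycle"], gt["muscle_set"],
                        config=OCPConfig(mesh_per_s=50.0))
    errs = _interval_dynamics_errors(ocp, sol)
    t = sol.time
    ms = gt["muscle_set"]
    tau_a, tau_d = ms.array("tau_act"), ms.array("tau_deact")
    for k in (5, 20, 40):
        def rhs(time, a):
            e = np.array([np.interp(time, t, sol.excitations[:, m])
                          for m in range(9)])
            return activation_rate(e, np.clip(a, 0, 1), tau_a, tau_d)

        ref = solve_ivp(rhs, (t[k], t[k + 1]), sol.activations[k],
                        rtol=1e-10, atol=1e-12)
        err_a = np.max(np.abs(ref.y[:, -1] - sol.activations[k + 1]))
        # the estimator bounds the true activation-dynamics error closely
        assert errs[k] >= err_a - 1e-4


def test_transcription_jacobian_matches_finite_differences(ground_truth):
    """Colored complex-step Jacobian vs forward differences on random columns."""
    cyc, ms = ground_truth["cycle"], ground_truth["muscle_set"]
    ocp = build_problem(cyc, ms, make_device("he+ke/coupled"),
                        OCPConfig(mesh_per_s=20.0))
    tr = _Transcription(ocp)
    x0 = tr.initial_guess()
    c0 = tr.constraints(x0)
    jac = tr.jac_c(x0)
    rng = np.random.default_rng(0)
    h = 1e-7
    for j in rng.choice(tr.n_x, 12, replace=False):
        xp = x0.copy()
        xp[j] += h
        fd = (tr.constraints(xp) - c0) / h
        assert np.max(np.abs(fd - jac[:, j].toarray().ravel())) < 1e-5
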