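"""Direct-collocation transcription and solution of the muscle-redundancy OCP.

The optimal-control problem: find muscle excitations, activations and
normalized tendon forces (plus device controls/gains when assisted, plus
static parameter scales when calibrating) that minimize a smoothed metabolic
cost (or an EMG-tracking error) subject to

* first-order activation dynamics (defect constraints on the mesh),
* implicit tendon-compliance dynamics (the normalized tendon force is a
  state, its derivative a control, and the Hill equilibrium residual a path
  constraint),
* per-DOF moment balance ``sum_m r * F + tau_device + tau_reserve = tau_net``,
* periodicity of the muscle states across the cycle.

Transcription schemes: trapezoidal, or a Radau-family implicit scheme
(one-point Legendre-Gauss-Radau, i.e. right-endpoint implicit Euler).  The
resulting sparse NLP is solved with SciPy's interior-point trust-region
solver; constraint Jacobians and objective gradients come from the colored
complex-step engine in :mod:`exogait._jacobian`, exact to machine precision.

All decision variables are scaled to O(1): tendon-force derivatives by
``DTENDON_SCALE`` (1/s) and reserve torques by ``RESERVE_SCALE`` (N.m per kg
body mass).  Moment-balance rows are scaled by body mass so residual
tolerances are in N.m/kg.
"""

from __future__ import annotations

import time as _time
from dataclasses import dataclass, field
from types import SimpleNamespace

import numpy as np
from scipy import sparse
from scipy.interpolate import CubicSpline
from scipy.optimize import BFGS, Bounds, NonlinearConstraint, minimize, nnls

from ._lbfgs import LBFGSHessian

from ._jacobian import ColoredJacobian
from .devices import DIRECTIONS, DeviceControls, DeviceSpec
from .gait_cycle import GaitCycle
from .metabolics import MetabolicConfig, muscle_metabolic_rate
from .muscle import (DOF_NAMES, FIBER_DAMPING, MuscleSetModel,
                     active_force_length, activation_rate, fiber_kinematics,
                     force_velocity, passive_force_length)

DTENDON_SCALE = 20.0     # 1/s per unit of the scaled tendon-force-derivative control
RESERVE_SCALE = 1.0      # N.m per kg body mass per unit of the scaled reserve
TENDON_FORCE_MAX = 2.5   # upper bound on normalized tendon force
TENDON_FORCE_MIN = -0.02  # smooth sub-slack extension of the tendon curve


class OCPError(RuntimeError):
    """Ill-posed problem or solver failure."""


@dataclass
class OCPConfig:
    """Numerical configuration of one optimal-control solve."""

    mesh_per_s: float = 100.0
    scheme: str = "trapezoid"          # "trapezoid" | "radau"
    nlp_tol: float = 1e-3
    max_iter: int = 1500
    objective: str = "metabolic"       # "metabolic" | "emg_tracking"
    w_metabolic: float = 1.0
    w_excitation: float = 0.05
    w_activation: float = 0.05
    w_dtendon: float = 0.01
    w_reserve: float = 2.0e3
    w_device: float = 1.0e-3
    w_emg: float = 10.0                # primary weight in emg_tracking mode
    w_passive: float = 0.1             # passive-force penalty (calibration)
    w_param_deviation: float = 0.2     # anchor for unidentified static scales
    calibrate_params: bool = False     # add static l_m_opt / l_t_slack scales
    param_scale_bounds: tuple[float, float] = (0.75, 1.25)
    metabolic: MetabolicConfig = field(default_factory=MetabolicConfig)

    def __post_init__(self) -> None:
        if self.w_metabolic <= 0:
            raise OCPError("w_metabolic must be > 0")
        if self.scheme not in ("trapezoid", "radau"):
            raise OCPError(f"unknown collocation scheme {self.scheme!r}")


@dataclass
class OCPDefinition:
    """A transcribed problem: cycle interpolants sampled on a mesh."""

    cycle: GaitCycle
    muscle_set: MuscleSetModel
    device: DeviceSpec
    config: OCPConfig
    node_times: np.ndarray
    emg_targets: np.ndarray | None = None      # (N1, M) NaN where unmeasured

    def __post_init__(self) -> None:
        if len(self.node_times) < 11:
            raise OCPError("mesh must have at least 10 intervals")
        span = self.muscle_set.span_matrix()
        # every spanned DOF must have a moment arm somewhere in the cycle
        arm_active = np.any(np.abs(self.cycle.moment_arms) > 1e-12, axis=0)
        if np.any(span & ~arm_active):
            missing = [(self.muscle_set.names[i], DOF_NAMES[j])
                       for i, j in zip(*np.where(span & ~arm_active))]
            raise OCPError(f"missing moment arms for spanned DOFs: {missing}")

    @property
    def n_intervals(self) -> int:
        return len(self.node_times) - 1


@dataclass
class OCPSolution:
    """Solution trajectories on the mesh plus independent diagnostics."""

    time: np.ndarray
    activations: np.ndarray
    tendon_forces: np.ndarray
    excitations: np.ndarray
    d_tendon_forces: np.ndarray      # 1/s
    reserves: np.ndarray             # N.m, (N1, 3)
    device_controls: np.ndarray | None
    gains: np.ndarray | None
    param_scales: dict[str, np.ndarray] | None
    objective: float
    objective_terms: dict[str, float]
    max_defect: float
    max_moment_residual: float       # N.m
    status: str
    success: bool
    n_iter: int
    solve_time: float
    device_directions: tuple[str, ...] | None = None
    device_mode: str = "none"
    x: np.ndarray = field(repr=False, default=None)

    def controls(self, spec: DeviceSpec) -> DeviceControls | None:
        if self.device_controls is None:
            return None
        return DeviceControls(trajectories=self.device_controls, gains=self.gains)


# ---------------------------------------------------------------------------
# transcription
# ---------------------------------------------------------------------------

class _Transcription:
    """Flattened-variable view of one OCP instance."""

    def __init__(self, ocp: OCPDefinition):
        self.ocp = ocp
        cfg = ocp.config
        ms = ocp.muscle_set
        cyc = ocp.cycle
        self.t = np.asarray(ocp.node_times, dtype=float)
        self.h = np.diff(self.t)
        self.n1 = len(self.t)
        self.nm = len(ms.names)
        self.nd = len(DOF_NAMES)
        self.mass = cyc.body_mass

        # prescribed quantities at the nodes (cubic interpolants of the cycle)
        def interp(y):
            return CubicSpline(cyc.time, y, axis=0)(self.t)

        self.lmt = interp(cyc.mtu_lengths)
        self.vmt = interp(cyc.mtu_velocities)
        self.arms = interp(cyc.moment_arms)
        self.tau_net = interp(cyc.net_moments)
        self.omega = interp(cyc.joint_velocities)

        # per-muscle parameter arrays
        self.p = SimpleNamespace(
            f_max=ms.array("f_max"), l_m_opt=ms.array("l_m_opt"),
            l_t_slack=ms.array("l_t_slack"), v_max=ms.array("v_max"),
            penn=ms.array("pennation_opt"),
            pstrain=ms.array("passive_strain_at_fmax"),
            tstrain=ms.array("tendon_strain_at_fmax"),
            tau_act=ms.array("tau_act"), tau_deact=ms.array("tau_deact"),
            ft_frac=ms.array("fast_twitch_fraction"),
            spec_tension=ms.array("specific_tension"),
            density=ms.array("muscle_density"))

        # device layout
        dev = ocp.device
        self.k_dev = dev.n_directions
        self.coupled = dev.mode == "coupled"
        self.n_traj_dev = (1 if self.coupled else self.k_dev) if dev.mode not in ("none",) else 0
        self.n_gains = self.k_dev if self.coupled else 0
        self.dev_sign = np.array([DIRECTIONS[d][1] for d in dev.directions], dtype=float)
        self.dev_dof = np.array([DIRECTIONS[d][0] for d in dev.directions], dtype=np.intp)
        self.dev_limit = np.array([dev.torque_limits[d] for d in dev.directions], dtype=float)

        self.calibrate = cfg.calibrate_params
        self.n_static = self.n_gains + (2 * self.nm if self.calibrate else 0)

        # variable layout: node-major blocks, then statics
        n1, nm = self.n1, self.nm
        sizes = {"a": n1 * nm, "f": n1 * nm, "e": n1 * nm, "d": n1 * nm,
                 "r": n1 * self.nd, "u": n1 * self.n_traj_dev}
        off = 0
        self.off = {}
        for k, s in sizes.items():
            self.off[k] = off
            off += s
        self.off["g"] = off
        off += self.n_gains
        if self.calibrate:
            self.off["s_lopt"] = off
            off += nm
            self.off["s_lts"] = off
            off += nm
        self.n_x = off

        # constraint layout
        n = self.n1 - 1
        self.rows = {}
        roff = 0
        for name, size in (("eq", n1 * nm), ("def_a", n * nm),
                           ("def_f", n * nm), ("mom", n1 * self.nd),
                           ("per_a", nm), ("per_f", nm)):
            self.rows[name] = roff
            roff += size
        self.n_c = roff

        # trapezoid quadrature weights on the (possibly nonuniform) mesh,
        # normalized by cycle duration
        qw = np.zeros(n1)
        qw[:-1] += 0.5 * self.h
        qw[1:] += 0.5 * self.h
        self.quad_w = qw / (self.t[-1] - self.t[0])

        self._emg_mask = None
        if ocp.emg_targets is not None:
            self._emg_mask = ~np.isnan(ocp.emg_targets)
            self._emg_vals = np.where(self._emg_mask, np.nan_to_num(ocp.emg_targets), 0.0)

        self._build_sparsity()

    # -- indexing helpers ---------------------------------------------------
    def idx(self, block: str, k=None, j=None) -> np.ndarray:
        off = self.off[block]
        if block in ("g", "s_lopt", "s_lts"):
            return off + np.atleast_1d(j if j is not None else np.arange(
                self.n_gains if block == "g" else self.nm))
        width = {"a": self.nm, "f": self.nm, "e": self.nm, "d": self.nm,
                 "r": self.nd, "u": self.n_traj_dev}[block]
        return off + np.atleast_1d(k) * width + np.atleast_1d(j)

    def unpack(self, x):
        n1, nm, nd = self.n1, self.nm, self.nd
        b = {}
        b["a"] = x[self.off["a"]:self.off["a"] + n1 * nm].reshape(n1, nm)
        b["f"] = x[self.off["f"]:self.off["f"] + n1 * nm].reshape(n1, nm)
        b["e"] = x[self.off["e"]:self.off["e"] + n1 * nm].reshape(n1, nm)
        b["d"] = x[self.off["d"]:self.off["d"] + n1 * nm].reshape(n1, nm)
        b["r"] = x[self.off["r"]:self.off["r"] + n1 * nd].reshape(n1, nd)
        if self.n_traj_dev:
            b["u"] = x[self.off["u"]:self.off["u"] + n1 * self.n_traj_dev].reshape(
                n1, self.n_traj_dev)
        if self.n_gains:
            b["g"] = x[self.off["g"]:self.off["g"] + self.n_gains]
        if self.calibrate:
            b["s_lopt"] = x[self.off["s_lopt"]:self.off["s_lopt"] + nm]
            b["s_lts"] = x[self.off["s_lts"]:self.off["s_lts"] + nm]
        return b

    # -- model evaluation ---------------------------------------------------
    def _effective_params(self, b):
        p = self.p
        if self.calibrate:
            return p.l_m_opt * b["s_lopt"], p.l_t_slack * b["s_lts"]
        return p.l_m_opt, p.l_t_slack

    def _fiber_state(self, b):
        p = self.p
        l_opt, l_ts = self._effective_params(b)
        dft = b["d"] * DTENDON_SCALE
        return fiber_kinematics(b["f"], dft, self.lmt, self.vmt,
                                l_opt, l_ts, p.v_max, p.penn, p.tstrain)

    def device_dof_torque(self, b):
        """Signed device torque per storage DOF, (n1, 3), N.m (complex-safe)."""
        tau = np.zeros((self.n1, self.nd), dtype=b["a"].dtype)
        if not self.n_traj_dev:
            return tau
        u = b["u"]
        if self.coupled:
            u = u * b["g"][None, :]
        scaled = u * (self.dev_sign * self.dev_limit * self.mass)[None, :]
        for j in range(self.k_dev):
            tau[:, self.dev_dof[j]] = tau[:, self.dev_dof[j]] + scaled[:, j]
        return tau

    def constraints(self, x):
        b = self.unpack(x)
        p = self.p
        out = np.zeros(self.n_c, dtype=x.dtype)
        n1, nm, nd, n = self.n1, self.nm, self.nd, self.n1 - 1

        lmn, vmn, cosa = self._fiber_state(b)
        fl = active_force_length(lmn)
        fv = force_velocity(vmn)
        fp = passive_force_length(lmn, p.pstrain)
        res_eq = (b["a"] * fl * fv + fp + FIBER_DAMPING * vmn) * cosa - b["f"]
        out[self.rows["eq"]:self.rows["eq"] + n1 * nm] = res_eq.ravel()

        adot = activation_rate(b["e"], b["a"], p.tau_act, p.tau_deact,
                               validate=False)
        h = self.h[:, None]
        if self.ocp.config.scheme == "trapezoid":
            def_a = b["a"][1:] - b["a"][:-1] - 0.5 * h * (adot[1:] + adot[:-1])
            def_f = b["f"][1:] - b["f"][:-1] \
                - 0.5 * h * DTENDON_SCALE * (b["d"][1:] + b["d"][:-1])
        else:  # one-point Radau: right-endpoint implicit Euler
            def_a = b["a"][1:] - b["a"][:-1] - h * adot[1:]
            def_f = b["f"][1:] - b["f"][:-1] - h * DTENDON_SCALE * b["d"][1:]
        out[self.rows["def_a"]:self.rows["def_a"] + n * nm] = def_a.ravel()
        out[self.rows["def_f"]:self.rows["def_f"] + n * nm] = def_f.ravel()

        forces = p.f_max[None, :] * b["f"]
        mus_mom = np.einsum("km,kmd->kd", forces, self.arms)
        tau_dev = self.device_dof_torque(b)
        tau_res = b["r"] * (RESERVE_SCALE * self.mass)
        mom = (mus_mom + tau_dev + tau_res - self.tau_net) / self.mass
        out[self.rows["mom"]:self.rows["mom"] + n1 * nd] = mom.ravel()

        out[self.rows["per_a"]:self.rows["per_a"] + nm] = b["a"][0] - b["a"][-1]
        out[self.rows["per_f"]:self.rows["per_f"] + nm] = b["f"][0] - b["f"][-1]
        return out

    def objective_pernode(self, x):
        """Per-node objective integrand (length n1), complex-safe."""
        b = self.unpack(x)
        cfg = self.ocp.config
        p = self.p
        out = np.zeros(self.n1, dtype=x.dtype)

        if cfg.objective == "metabolic":
            lmn, vmn, cosa = self._fiber_state(b)
            fl = active_force_length(lmn)
            l_opt, l_ts = self._effective_params(b)
            mass_m = p.f_max / p.spec_tension * l_opt * p.density
            params = SimpleNamespace(
                fast_twitch_fraction=p.ft_frac, v_max=p.v_max,
                f_max=p.f_max, l_m_opt=l_opt, mass=mass_m)
            v_lopt_s = vmn * p.v_max
            rates = muscle_metabolic_rate(b["a"], b["e"], lmn, v_lopt_s, fl,
                                          params, cfg.metabolic, validate=False)
            out = out + cfg.w_metabolic * 2.0 * np.sum(rates, axis=1) / self.mass
        else:  # emg_tracking
            err = (b["e"] - self._emg_vals) * self._emg_mask
            out = out + cfg.w_emg * np.sum(err * err, axis=1) / max(
                1, int(self._emg_mask[0].sum()))
            lmn, vmn, cosa = self._fiber_state(b)
            fp = passive_force_length(lmn, p.pstrain)
            out = out + cfg.w_passive * np.sum(fp * fp, axis=1) / self.nm

        out = out + cfg.w_excitation * np.sum(b["e"] ** 2, axis=1) / self.nm
        out = out + cfg.w_activation * np.sum(b["a"] ** 2, axis=1) / self.nm
        out = out + cfg.w_dtendon * np.sum(b["d"] ** 2, axis=1) / self.nm
        out = out + cfg.w_reserve * np.sum(b["r"] ** 2, axis=1) / self.nd
        if self.n_traj_dev:
            out = out + cfg.w_device * np.sum(b["u"] ** 2, axis=1) / self.n_traj_dev
        if self.calibrate:
            # static anchor: muscles with little EMG signal are otherwise
            # unidentified and would drift freely
            dev = np.sum((b["s_lopt"] - 1.0) ** 2) + np.sum((b["s_lts"] - 1.0) ** 2)
            out = out + cfg.w_param_deviation * dev / (2 * self.nm)
        return out

    def objective(self, x):
        val = float(np.real(self.quad_w @ self.objective_pernode(x)))
        if self.ocp.config.objective == "metabolic":
            val += self.ocp.config.metabolic.basal_rate
        return val

    def objective_terms(self, x) -> dict[str, float]:
        """Per-term breakdown recomputed from the trajectories."""
        b = self.unpack(x)
        cfg = self.ocp.config
        qw = self.quad_w
        terms: dict[str, float] = {}

        def integ(pernode):
            return float(qw @ pernode)

        full = self.objective_pernode(np.asarray(x, dtype=float))
        sub = {}
        for name, attr in (("excitation", "e"), ("activation", "a"),
                           ("dtendon", "d")):
            w = getattr(cfg, f"w_{name}")
            sub[name] = w * integ(np.sum(b[attr] ** 2, axis=1) / self.nm)
        sub["reserve"] = cfg.w_reserve * integ(np.sum(b["r"] ** 2, axis=1) / self.nd)
        if self.n_traj_dev:
            sub["device"] = cfg.w_device * integ(
                np.sum(b["u"] ** 2, axis=1) / self.n_traj_dev)
        if self.calibrate:
            sub["param_deviation"] = cfg.w_param_deviation * float(
                np.sum((b["s_lopt"] - 1.0) ** 2)
                + np.sum((b["s_lts"] - 1.0) ** 2)) / (2 * self.nm)
        primary = integ(np.real(full)) - sum(sub.values())
        key = "metabolic" if cfg.objective == "metabolic" else "emg_tracking"
        terms[key] = primary
        if cfg.objective == "metabolic":
            terms[key] += cfg.metabolic.basal_rate
        terms.update(sub)
        return terms

    # -- sparsity -----------------------------------------------------------
    def _build_sparsity(self):
        n1, nm, nd, n = self.n1, self.nm, self.nd, self.n1 - 1
        trap = self.ocp.config.scheme == "trapezoid"
        rows_c: list[np.ndarray] = [None] * self.n_x
        rows_o: list[np.ndarray] = [None] * self.n_x

        def eq_row(k, m):
            return self.rows["eq"] + k * nm + m

        def def_rows(base, k, m):
            # defect intervals touched by node k
            out = []
            if k > 0:
                out.append(self.rows[base] + (k - 1) * nm + m)
            if k < n and (trap or base == "_"):
                out.append(self.rows[base] + k * nm + m)
            elif k < n and not trap:
                pass
            return out

        for k in range(n1):
            for m in range(nm):
                # a[k,m]
                r = [eq_row(k, m)]
                if k > 0:
                    r.append(self.rows["def_a"] + (k - 1) * nm + m)
                if k < n:
                    r.append(self.rows["def_a"] + k * nm + m)
                if k == 0:
                    r.append(self.rows["per_a"] + m)
                if k == n1 - 1:
                    r.append(self.rows["per_a"] + m)
                rows_c[self.idx("a", k, m)[0]] = np.array(r)
                # f[k,m]
                r = [eq_row(k, m)]
                if k > 0:
                    r.append(self.rows["def_f"] + (k - 1) * nm + m)
                if k < n:
                    r.append(self.rows["def_f"] + k * nm + m)
                r += [self.rows["mom"] + k * nd + d for d in range(nd)]
                if k == 0:
                    r.append(self.rows["per_f"] + m)
                if k == n1 - 1:
                    r.append(self.rows["per_f"] + m)
                rows_c[self.idx("f", k, m)[0]] = np.array(r)
                # e[k,m]: defect rows only (rate at the node(s) it enters)
                r = []
                if k > 0:
                    r.append(self.rows["def_a"] + (k - 1) * nm + m)
                if k < n and trap:
                    r.append(self.rows["def_a"] + k * nm + m)
                rows_c[self.idx("e", k, m)[0]] = np.array(r, dtype=np.intp)
                # d[k,m]: equilibrium (velocity path) + tendon defects
                r = [eq_row(k, m)]
                if k > 0:
                    r.append(self.rows["def_f"] + (k - 1) * nm + m)
                if k < n and trap:
                    r.append(self.rows["def_f"] + k * nm + m)
                rows_c[self.idx("d", k, m)[0]] = np.array(r)
            for d in range(nd):
                rows_c[self.idx("r", k, d)[0]] = np.array(
                    [self.rows["mom"] + k * nd + d])
            for j in range(self.n_traj_dev):
                dofs = set(self.dev_dof) if self.coupled else {self.dev_dof[j]}
                rows_c[self.idx("u", k, j)[0]] = np.array(
                    [self.rows["mom"] + k * nd + d for d in sorted(dofs)])

        all_mom_rows = {
            j: np.array([self.rows["mom"] + k * nd + self.dev_dof[j]
                         for k in range(n1)])
            for j in range(self.n_gains)}
        for j in range(self.n_gains):
            rows_c[self.idx("g", j=j)[0]] = all_mom_rows[j]
        if self.calibrate:
            all_eq = {m: np.array([eq_row(k, m) for k in range(n1)])
                      for m in range(nm)}
            for m in range(nm):
                rows_c[self.idx("s_lopt", j=m)[0]] = all_eq[m]
                rows_c[self.idx("s_lts", j=m)[0]] = all_eq[m]

        # objective rows: every per-node variable -> its node; statics -> all
        all_nodes = np.arange(n1)
        for blk in ("a", "f", "e", "d"):
            for k in range(n1):
                for m in range(nm):
                    rows_o[self.idx(blk, k, m)[0]] = np.array([k])
        for k in range(n1):
            for d in range(nd):
                rows_o[self.idx("r", k, d)[0]] = np.array([k])
            for j in range(self.n_traj_dev):
                rows_o[self.idx("u", k, j)[0]] = np.array([k])
        for j in range(self.n_gains):
            rows_o[self.idx("g", j=j)[0]] = all_nodes
        if self.calibrate:
            for m in range(nm):
                rows_o[self.idx("s_lopt", j=m)[0]] = all_nodes
                rows_o[self.idx("s_lts", j=m)[0]] = all_nodes

        self.jac_c = ColoredJacobian(self.constraints, self.n_x, self.n_c, rows_c)
        self.jac_o = ColoredJacobian(self.objective_pernode, self.n_x, self.n1, rows_o)

    def gradient(self, x):
        return self.jac_o.dense_row_weighted(x, self.quad_w)

    # -- bounds and initial guess -------------------------------------------
    def bounds(self) -> Bounds:
        lb = np.full(self.n_x, -np.inf)
        ub = np.full(self.n_x, np.inf)

        def setb(name, lo, hi):
            off = self.off[name]
            size = {"a": self.n1 * self.nm, "f": self.n1 * self.nm,
                    "e": self.n1 * self.nm, "d": self.n1 * self.nm,
                    "r": self.n1 * self.nd, "u": self.n1 * self.n_traj_dev,
                    "g": self.n_gains, "s_lopt": self.nm, "s_lts": self.nm}[name]
            lb[off:off + size] = lo
            ub[off:off + size] = hi

        setb("a", 0.0, 1.0)
        setb("e", 0.0, 1.0)
        setb("f", TENDON_FORCE_MIN, TENDON_FORCE_MAX)
        setb("d", -2.5, 2.5)
        setb("r", -1.0, 1.0)
        if self.n_traj_dev:
            setb("u", 0.0, 1.0)
        if self.n_gains:
            gb = self.ocp.device.gain_bounds
            setb("g", gb[0], gb[1])
        if self.calibrate:
            lo, hi = self.ocp.config.param_scale_bounds
            setb("s_lopt", lo, hi)
            setb("s_lts", lo, hi)
        return Bounds(lb, ub)

    def initial_guess(self) -> np.ndarray:
        """Static redundancy presolve: nonnegative least-squares per node."""
        x = np.zeros(self.n_x)
        b = self.unpack(x)  # views
        p = self.p
        lam = 0.05
        amat = np.zeros((self.nd + self.nm, self.nm))
        f0 = np.zeros((self.n1, self.nm))
        for k in range(self.n1):
            amat[:self.nd] = (self.arms[k].T * p.f_max[None, :]) / self.mass
            amat[self.nd:] = np.sqrt(lam) * np.eye(self.nm)
            rhs = np.concatenate([self.tau_net[k] / self.mass, np.zeros(self.nm)])
            f0[k], _ = nnls(amat, rhs)
        f0 = np.clip(f0, 1e-3, TENDON_FORCE_MAX - 0.1)
        lmn, _, cosa = fiber_kinematics(
            f0, np.zeros_like(f0), self.lmt, self.vmt, p.l_m_opt, p.l_t_slack,
            p.v_max, p.penn, p.tstrain)
        fl = active_force_length(np.real(lmn))
        fp = passive_force_length(np.real(lmn), p.pstrain)
        act = (f0 / np.real(cosa) - fp) / np.maximum(fl, 0.3)
        act = np.clip(act, 0.02, 0.9)
        # enforce periodic endpoints in the guess
        f0[-1] = f0[0]
        act[-1] = act[0]
        dft = np.gradient(f0, self.t, axis=0) / DTENDON_SCALE

        if self.ocp.config.objective == "emg_tracking" \
                and self.ocp.emg_targets is not None:
            # tracking problems start from the EMG itself where measured
            emg = self.ocp.emg_targets
            act = np.where(np.isnan(emg), act, np.clip(np.nan_to_num(emg),
                                                       0.01, 0.99))
        x[self.off["a"]:self.off["a"] + self.n1 * self.nm] = act.ravel()
        x[self.off["f"]:self.off["f"] + self.n1 * self.nm] = f0.ravel()
        x[self.off["e"]:self.off["e"] + self.n1 * self.nm] = act.ravel()
        x[self.off["d"]:self.off["d"] + self.n1 * self.nm] = np.clip(
            dft, -2.4, 2.4).ravel()
        if self.n_traj_dev:
            x[self.off["u"]:self.off["u"] + self.n1 * self.n_traj_dev] = 0.05
        if self.n_gains:
            x[self.off["g"]:self.off["g"] + self.n_gains] = 0.5
        if self.calibrate:
            x[self.off["s_lopt"]:self.off["s_lopt"] + self.nm] = 1.0
            x[self.off["s_lts"]:self.off["s_lts"] + self.nm] = 1.0
        return x

    def guess_from_solution(self, sol: OCPSolution) -> np.ndarray:
        """Warm start by (re)interpolating a previous solution onto this mesh."""
        x = self.initial_guess()

        def put(name, values):
            size = values.size
            x[self.off[name]:self.off[name] + size] = values.ravel()

        def onto(arr):
            return CubicSpline(sol.time, arr, axis=0)(self.t)

        put("a", np.clip(onto(sol.activations), 0.0, 1.0))
        put("f", np.clip(onto(sol.tendon_forces), 0.0, TENDON_FORCE_MAX))
        put("e", np.clip(onto(sol.excitations), 0.0, 1.0))
        put("d", np.clip(onto(sol.d_tendon_forces) / DTENDON_SCALE, -2.5, 2.5))
        put("r", np.clip(onto(sol.reserves) / (RESERVE_SCALE * self.mass), -1, 1))
        if self.n_traj_dev and sol.device_controls is not None \
                and sol.device_directions is not None:
            # map device controls by semantic direction name
            u_src = np.clip(onto(sol.device_controls), 0.0, 1.0)
            src_dirs = list(sol.device_directions)
            my_dirs = list(self.ocp.device.directions)
            if sol.device_mode == "coupled" and not self.coupled:
                # expand shared control: u_j = gain_j * c(t)
                u = np.full((self.n1, self.k_dev), 0.05)
                for j, d in enumerate(my_dirs):
                    if d in src_dirs and sol.gains is not None:
                        u[:, j] = np.clip(
                            sol.gains[src_dirs.index(d)] * u_src[:, 0], 0, 1)
                put("u", u)
            elif sol.device_mode != "coupled" and self.coupled:
                # collapse per-direction controls onto gains and one shared
                # control weighted by torque authority
                gains = np.full(self.k_dev, 0.1)
                num = np.zeros(self.n1)
                den = 0.0
                for j, d in enumerate(my_dirs):
                    if d in src_dirs:
                        col = u_src[:, src_dirs.index(d)]
                        gains[j] = np.clip(col.max(), 0.05, 1.0)
                        num += col * self.dev_limit[j]
                        den += gains[j] * self.dev_limit[j]
                put("g", gains)
                put("u", np.clip(num / max(den, 1e-9), 0.0, 1.0)[:, None])
            elif sol.device_mode == "coupled" and self.coupled:
                put("u", u_src)
                if sol.gains is not None:
                    put("g", sol.gains)
            else:
                u = np.full((self.n1, self.k_dev), 0.05)
                for j, d in enumerate(my_dirs):
                    if d in src_dirs:
                        u[:, j] = u_src[:, src_dirs.index(d)]
                put("u", u)
        return x

    # -- diagnostics ----------------------------------------------------------
    def diagnostics(self, x) -> tuple[float, float]:
        """(max dynamics defect, max moment residual in N.m), recomputed."""
        c = self.constraints(np.asarray(x, dtype=float))
        n, nm = self.n1 - 1, self.nm
        d_a = np.abs(c[self.rows["def_a"]:self.rows["def_a"] + n * nm])
        d_f = np.abs(c[self.rows["def_f"]:self.rows["def_f"] + n * nm])
        mom = np.abs(c[self.rows["mom"]:self.rows["mom"] + self.n1 * self.nd])
        return float(max(d_a.max(), d_f.max())), float(mom.max() * self.mass)

    def solution(self, x, res, elapsed) -> OCPSolution:
        b = self.unpack(np.asarray(x, dtype=float))
        max_defect, max_mom = self.diagnostics(x)
        param_scales = None
        if self.calibrate:
            param_scales = {"l_m_opt": b["s_lopt"].copy(),
                            "l_t_slack": b["s_lts"].copy()}
        return OCPSolution(
            time=self.t.copy(),
            activations=b["a"].copy(),
            tendon_forces=b["f"].copy(),
            excitations=b["e"].copy(),
            d_tendon_forces=b["d"] * DTENDON_SCALE,
            reserves=b["r"] * (RESERVE_SCALE * self.mass),
            device_controls=b.get("u", None).copy() if "u" in b else None,
            gains=b.get("g", None).copy() if "g" in b else None,
            param_scales=param_scales,
            objective=self.objective(np.asarray(x, dtype=float)),
            objective_terms=self.objective_terms(x),
            max_defect=max_defect,
            max_moment_residual=max_mom,
            status=str(getattr(res, "message", "")),
            success=bool(getattr(res, "success", False)),
            n_iter=int(getattr(res, "niter", getattr(res, "nit", 0))),
            solve_time=elapsed,
            device_directions=(tuple(self.ocp.device.directions)
                               if self.ocp.device.mode != "none" else None),
            device_mode=self.ocp.device.mode,
            x=np.asarray(x, dtype=float).copy(),
        )


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def build_problem(cycle: GaitCycle, muscle_set: MuscleSetModel,
                  device: DeviceSpec = DeviceSpec(),
                  config: OCPConfig = OCPConfig(),
                  node_times: np.ndarray | None = None,
                  emg_targets: np.ndarray | None = None) -> OCPDefinition:
    """Transcribe one cycle + muscle set + device into an OCP definition.

    The mesh defaults to ``round(mesh_per_s * duration)`` uniform intervals.
    """
    if node_times is None:
        n = max(10, int(round(config.mesh_per_s * cycle.duration)))
        node_times = np.linspace(cycle.time[0], cycle.time[-1], n + 1)
    emg = None
    if emg_targets is not None or config.objective == "emg_tracking":
        if emg_targets is None:
            if cycle.emg is None:
                raise OCPError("emg_tracking objective requires cycle EMG")
            emg = np.full((len(node_times), len(muscle_set.names)), np.nan)
            for name, sig in cycle.emg.items():
                i = muscle_set.names.index(name)
                emg[:, i] = np.interp(node_times, cycle.time, sig)
        else:
            emg = np.asarray(emg_targets, dtype=float)
    return OCPDefinition(cycle=cycle, muscle_set=muscle_set, device=device,
                         config=config, node_times=np.asarray(node_times, dtype=float),
                         emg_targets=emg)


def variable_constraint_counts(ocp: OCPDefinition) -> dict[str, int]:
    """Closed-form NLP sizes for the given mesh/muscles/DOFs/device."""
    tr = _Transcription(ocp)
    return {"n_variables": tr.n_x, "n_constraints": tr.n_c,
            "n_device_trajectories": tr.n_traj_dev, "n_gains": tr.n_gains}


def solve(ocp: OCPDefinition, nlp_tol: float | None = None,
          warm_start: OCPSolution | None = None,
          x0: np.ndarray | None = None) -> OCPSolution:
    """Solve the transcribed NLP with the interior-point trust-region method."""
    tol = nlp_tol if nlp_tol is not None else ocp.config.nlp_tol
    tr = _Transcription(ocp)
    warm = warm_start is not None or x0 is not None
    if x0 is None:
        x0 = tr.guess_from_solution(warm_start) if warm_start is not None \
            else tr.initial_guess()
    bounds = tr.bounds()
    # keep the initial point strictly interior (interior-point methods stall
    # on a bound); for warm starts begin with a nearly converged barrier so
    # path-following stays near the supplied solution
    width = np.where(np.isfinite(bounds.ub - bounds.lb), bounds.ub - bounds.lb, 1.0)
    margin = (1e-4 if warm else 1e-3) * width
    x0 = np.clip(x0, bounds.lb + margin, bounds.ub - margin)
    mu0 = 1e-4 if warm else 0.1

    n = tr.n_x
    zero_hess = sparse.csr_matrix((n, n))
    con = NonlinearConstraint(tr.constraints, 0.0, 0.0, jac=tr.jac_c,
                              hess=lambda x, v: zero_hess)
    # limited-memory curvature is faster and ample for moment-matching
    # solves at the nominal tolerance; high-accuracy solves and the
    # parameter-tracking problems (ill-conditioned static variables) keep
    # the dense quasi-Newton model
    hess = BFGS(exception_strategy="skip_update") \
        if (ocp.config.objective == "emg_tracking" or tol < 1e-3) \
        else LBFGSHessian(30)
    t0 = _time.perf_counter()
    res = minimize(
        tr.objective, x0, jac=tr.gradient, hess=hess,
        method="trust-constr", bounds=bounds, constraints=[con],
        options={"gtol": tol / 3.0, "xtol": 1e-12, "maxiter": ocp.config.max_iter,
                 "barrier_tol": min(1e-8, tol * 1e-4),
                 "initial_barrier_parameter": mu0, "verbose": 0})
    elapsed = _time.perf_counter() - t0
    sol = tr.solution(res.x, res, elapsed)
    if not sol.success and res.status not in (1, 2, 3):
        # status 1/2/3 are gradient/xtol/callback terminations; 0 = maxiter
        sol.status += " (solver did not report convergence)"
    return sol


def refine_mesh(ocp: OCPDefinition, solution: OCPSolution,
                refine_tol: float = 1e-3, max_refinements: int = 3
                ) -> tuple[OCPDefinition, OCPSolution]:
    """Subdivide mesh intervals whose dynamics error exceeds ``refine_tol``.

    The per-interval error is an independent estimate: the activation and
    tendon-force dynamics are integrated across each interval with
    fixed-step RK4 (controls interpolated linearly) and compared with the
    collocation state at the right endpoint.  Intervals over tolerance are
    bisected and the problem re-solved warm-started from the previous
    solution.  Returns the possibly refined (definition, solution).
    """
    current = ocp
    sol = solution
    for _ in range(max_refinements):
        errs = _interval_dynamics_errors(current, sol)
        bad = np.where(errs > refine_tol)[0]
        if len(bad) == 0:
            return current, sol
        t = current.node_times
        mids = 0.5 * (t[bad] + t[bad + 1])
        new_times = np.sort(np.concatenate([t, mids]))
        current = build_problem(current.cycle, current.muscle_set,
                                current.device, current.config,
                                node_times=new_times,
                                emg_targets=None)
        sol = solve(current, warm_start=sol)
    errs = _interval_dynamics_errors(current, sol)
    if np.any(errs > refine_tol):
        sol.status += " (mesh refinement reached max iterations)"
    return current, sol


def _interval_dynamics_errors(ocp: OCPDefinition, sol: OCPSolution) -> np.ndarray:
    """Max state error per mesh interval vs an RK4 reference integration."""
    tr = _Transcription(ocp)
    t = sol.time
    errs = np.zeros(len(t) - 1)

    def rates(time, a, f):
        e = np.array([np.interp(time, t, sol.excitations[:, m])
                      for m in range(tr.nm)])
        d = np.array([np.interp(time, t, sol.d_tendon_forces[:, m])
                      for m in range(tr.nm)])
        da = activation_rate(np.clip(e, 0, 1), np.clip(a, 0, 1),
                             tr.p.tau_act, tr.p.tau_deact)
        return da, d

    for k in range(len(t) - 1):
        a = sol.activations[k].copy()
        f = sol.tendon_forces[k].copy()
        n_sub = 4
        h = (t[k + 1] - t[k]) / n_sub
        time = t[k]
        for _ in range(n_sub):
            k1a, k1f = rates(time, a, f)
            k2a, k2f = rates(time + h / 2, a + h / 2 * k1a, f + h / 2 * k1f)
            k3a, k3f = rates(time + h / 2, a + h / 2 * k2a, f + h / 2 * k2f)
            k4a, k4f = rates(time + h, a + h * k3a, f + h * k3f)
            a = a + h / 6 * (k1a + 2 * k2a + 2 * k3a + k4a)
            f = f + h / 6 * (k1f + 2 * k2f + 2 * k3f + k4f)
            time += h
        errs[k] = max(np.max(np.abs(a - sol.activations[k + 1])),
                      np.max(np.abs(f - sol.tendon_forces[k + 1])))
    return errs
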