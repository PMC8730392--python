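"""Post-processing: metabolic summaries, device metrics, validation and stats.

Covers the study's reporting conventions: mass-normalized peak/average device
torques and powers, EMG onset/offset timing errors (5% threshold, 75 ms
electromechanical shift, periodic), reserve-torque diagnostics against the
5% RMS-to-peak-moment guideline, convergence-tolerance sensitivity with
objectives normalized by the tightest tolerance, and the device-comparison
statistics (linear mixed model with device as fixed and subject as random
effect, Tukey-adjusted pairwise contrasts at alpha = 0.05).

Sign conventions: percent changes are negative for savings; device powers use
the direction's own sign convention so positive power is energy delivered to
the joint motion.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .collocation import OCPConfig, OCPSolution, build_problem, solve
from .devices import DIRECTIONS, DeviceSpec
from .gait_cycle import GaitCycle
from .metabolics import MetabolicConfig, MetabolicReport, muscle_metabolic_rate, report_from_rates
from .muscle import (MuscleSetModel, active_force_length,
                     fiber_kinematics)


# ---------------------------------------------------------------------------
# metabolic summaries from solutions
# ---------------------------------------------------------------------------

def metabolic_rates_from_solution(sol: OCPSolution, cycle: GaitCycle,
                                  muscle_set: MuscleSetModel,
                                  config: MetabolicConfig = MetabolicConfig()
                                  ) -> np.ndarray:
    """Instantaneous per-muscle metabolic rates (W) on the solution grid."""
    from scipy.interpolate import CubicSpline

    t = sol.time
    lmt = CubicSpline(cycle.time, cycle.mtu_lengths, axis=0)(t)
    vmt = CubicSpline(cycle.time, cycle.mtu_velocities, axis=0)(t)
    rates = np.zeros_like(sol.activations)
    for i, m in enumerate(muscle_set.muscles):
        lmn, vmn, _ = fiber_kinematics(
            sol.tendon_forces[:, i], sol.d_tendon_forces[:, i],
            lmt[:, i], vmt[:, i], m.l_m_opt, m.l_t_slack, m.v_max,
            m.pennation_opt, m.tendon_strain_at_fmax)
        fl = active_force_length(lmn)
        rates[:, i] = muscle_metabolic_rate(
            sol.activations[:, i], sol.excitations[:, i], lmn,
            vmn * m.v_max, fl, m, config)
    return rates


def metabolic_report(sol: OCPSolution, cycle: GaitCycle,
                     muscle_set: MuscleSetModel,
                     config: MetabolicConfig = MetabolicConfig(),
                     condition: str = "unassisted") -> MetabolicReport:
    rates = metabolic_rates_from_solution(sol, cycle, muscle_set, config)
    return report_from_rates(muscle_set.names, rates, sol.time,
                             cycle.body_mass, config, condition)


# ---------------------------------------------------------------------------
# device torque / power metrics
# ---------------------------------------------------------------------------

@dataclass
class DeviceMetrics:
    """Mass-normalized device torque and power metrics per assisted direction."""

    directions: tuple[str, ...]
    peak_torque: np.ndarray            # N.m/kg, magnitude
    peak_positive_power: np.ndarray    # W/kg
    average_positive_power: np.ndarray  # W/kg
    average_negative_power: np.ndarray  # W/kg

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "direction": list(self.directions),
            "peak_torque_nm_per_kg": self.peak_torque,
            "peak_positive_power_w_per_kg": self.peak_positive_power,
            "average_positive_power_w_per_kg": self.average_positive_power,
            "average_negative_power_w_per_kg": self.average_negative_power,
        })


def device_power_metrics(sol: OCPSolution, cycle: GaitCycle,
                         spec: DeviceSpec) -> DeviceMetrics:
    """Peak/average torques and powers: power_d(t) = tau_d(t) * omega_dof(t)."""
    from scipy.interpolate import CubicSpline

    if spec.mode == "none" or sol.device_controls is None:
        return DeviceMetrics((), np.zeros(0), np.zeros(0), np.zeros(0), np.zeros(0))
    from .devices import DeviceControls, device_torques

    controls = DeviceControls(trajectories=sol.device_controls, gains=sol.gains)
    tau = device_torques(spec, controls, cycle.body_mass)  # (T, K) signed N.m
    omega = CubicSpline(cycle.time, cycle.joint_velocities, axis=0)(sol.time)
    t = sol.time
    duration = t[-1] - t[0]
    mass = cycle.body_mass
    k = spec.n_directions
    peak_tau = np.zeros(k)
    peak_pos = np.zeros(k)
    avg_pos = np.zeros(k)
    avg_neg = np.zeros(k)
    for j, d in enumerate(spec.directions):
        dof = DIRECTIONS[d][0]
        power = tau[:, j] * omega[:, dof]
        peak_tau[j] = np.max(np.abs(tau[:, j])) / mass
        peak_pos[j] = max(np.max(power), 0.0) / mass
        avg_pos[j] = np.trapezoid(np.maximum(power, 0.0), t) / duration / mass
        avg_neg[j] = np.trapezoid(np.minimum(power, 0.0), t) / duration / mass
    return DeviceMetrics(tuple(spec.directions), peak_tau, peak_pos, avg_pos, avg_neg)


# ---------------------------------------------------------------------------
# EMG timing validation
# ---------------------------------------------------------------------------

@dataclass
class TimingErrorReport:
    muscle: str
    error_percent: float
    threshold: float
    shift_s: float


def timing_error(activation: np.ndarray, emg: np.ndarray, time: np.ndarray,
                 threshold: float = 0.05, shift: float = 0.075) -> float:
    """Onset/offset timing error as % of the gait cycle.

    Both series are binarized at ``threshold`` of their own peaks; the
    simulated activation is shifted *later* by ``shift`` seconds
    (electromechanical delay), periodically across the cycle boundary; the
    error is the percentage of the cycle where the binary signals disagree
    in either direction.  0% is a perfect match at all points, 100% no match.
    An all-zero series is treated as never-on (0% against another all-zero
    series, 100% against an always-on one).
    """
    activation = np.asarray(activation, dtype=float)
    emg = np.asarray(emg, dtype=float)
    time = np.asarray(time, dtype=float)
    duration = time[-1] - time[0]
    # periodic (wrap-around) shift of the activation by +shift
    if shift % duration == 0.0:
        shifted = activation
    else:
        query = time[0] + (time - time[0] - shift) % duration
        shifted = np.interp(query, time[:-1], activation[:-1], period=duration)
    act_peak = np.max(activation)
    emg_peak = np.max(emg)
    act_on = shifted > threshold * act_peak if act_peak > 0 \
        else np.zeros_like(shifted, dtype=bool)
    emg_on = emg > threshold * emg_peak if emg_peak > 0 \
        else np.zeros_like(emg, dtype=bool)
    # fraction of cycle in disagreement (trapezoid over the indicator)
    disagree = (act_on != emg_on).astype(float)
    return 100.0 * float(np.trapezoid(disagree, time) / duration)


def timing_error_report(sol: OCPSolution, cycle: GaitCycle,
                        threshold: float = 0.05, shift: float = 0.075
                        ) -> list[TimingErrorReport]:
    if cycle.emg is None:
        return []
    out = []
    for name, sig in cycle.emg.items():
        i = cycle.muscle_names.index(name)
        emg_on_grid = np.interp(sol.time, cycle.time, sig)
        err = timing_error(sol.activations[:, i], emg_on_grid, sol.time,
                           threshold, shift)
        out.append(TimingErrorReport(name, err, threshold, shift))
    return out


# ---------------------------------------------------------------------------
# reserve diagnostics
# ---------------------------------------------------------------------------

@dataclass
class ReserveMetrics:
    rms: np.ndarray                 # N.m per DOF
    rms_to_peak_ratio: np.ndarray   # percent per DOF
    mean_ratio: float
    max_ratio: float


def reserve_metrics(sol: OCPSolution, cycle: GaitCycle) -> ReserveMetrics:
    """RMS reserve torque per DOF and its ratio to the peak net moment (%)."""
    from scipy.interpolate import CubicSpline

    tau_net = CubicSpline(cycle.time, cycle.net_moments, axis=0)(sol.time)
    rms = np.sqrt(np.mean(sol.reserves ** 2, axis=0))
    peak = np.max(np.abs(tau_net), axis=0)
    ratio = 100.0 * rms / np.maximum(peak, 1e-12)
    return ReserveMetrics(rms, ratio, float(np.mean(ratio)), float(np.max(ratio)))


# ---------------------------------------------------------------------------
# convergence-tolerance sensitivity
# ---------------------------------------------------------------------------

def tolerance_sensitivity(cycle: GaitCycle, muscle_set: MuscleSetModel,
                          tolerances: tuple[float, ...] = (1.0, 1e-1, 1e-2, 1e-3, 1e-4),
                          config: OCPConfig | None = None) -> pd.DataFrame:
    """Unassisted objective at each tolerance, normalized by the tightest.

    Solves are warm-started from the loosest tolerance downward.  The entry
    at the tightest tolerance is exactly 1 by construction.
    """
    cfg = config or OCPConfig()
    ordered = sorted(tolerances, reverse=True)
    ocp = build_problem(cycle, muscle_set, config=cfg)
    rows = []
    sol = None
    for tol in ordered:
        sol = solve(ocp, nlp_tol=tol, warm_start=sol)
        rows.append({"tolerance": tol, "objective": sol.objective,
                     "converged": sol.success})
    df = pd.DataFrame(rows)
    ref = df.loc[df["tolerance"].idxmin(), "objective"]
    df["normalized_objective"] = df["objective"] / ref
    return df


# ---------------------------------------------------------------------------
# device-comparison statistics
# ---------------------------------------------------------------------------

@dataclass
class PairwiseComparison:
    device_a: str
    device_b: str
    estimate: float
    p_value: float
    significant: bool


@dataclass
class DeviceComparisonReport:
    n_observations: int
    anova_f: float
    anova_p: float
    pairwise: list[PairwiseComparison]
    alpha: float = 0.05

    def pairwise_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "device_a": p.device_a, "device_b": p.device_b,
            "estimate": p.estimate, "p_value": p.p_value,
            "significant": p.significant} for p in self.pairwise])


def compare_devices(table: pd.DataFrame, alpha: float = 0.05,
                    value_col: str = "percent_change") -> DeviceComparisonReport:
    """Mixed-model device comparison with Tukey-adjusted pairwise contrasts.

    ``table`` holds one averaged observation per subject x device with
    columns ``subject``, ``device`` and ``value_col``.  A linear mixed model
    (fixed effect: device; random intercept: subject) is fitted with
    statsmodels; the omnibus test is a Wald F-test on the device effect and
    pairwise contrasts use the studentized-range (Tukey) adjustment.
    """
    import statsmodels.formula.api as smf

    df = table.rename(columns={value_col: "y"}).copy()
    if df[["subject", "device"]].duplicated().any():
        raise ValueError("expected one averaged observation per subject x device")
    counts = df.pivot_table(index="subject", columns="device", values="y",
                            aggfunc="size")
    if counts.isna().any().any():
        raise ValueError("unbalanced/missing subject x device cells: "
                         f"{counts[counts.isna().any(axis=1)].index.tolist()}")
    devices = sorted(df["device"].unique())
    n_dev = len(devices)
    n_sub = df["subject"].nunique()
    if n_dev < 2 or n_sub < 2:
        raise ValueError("need >= 2 subjects and >= 2 devices")

    model = smf.mixedlm("y ~ C(device)", df, groups=df["subject"])
    fit = None
    for method in ("lbfgs", "bfgs", "powell"):
        try:
            fit = model.fit(reml=True, method=method)
            break
        except np.linalg.LinAlgError:
            continue
    if fit is None:
        raise RuntimeError("mixed model failed to converge")

    # omnibus Wald F-test on all device terms (contrast spans every model
    # parameter; only the fixed-effect device columns are tested)
    all_names = list(fit.params.index)
    names = [n for n in fit.fe_params.index if n.startswith("C(device)")]
    contrast = np.zeros((len(names), len(all_names)))
    for i, n in enumerate(names):
        contrast[i, all_names.index(n)] = 1.0
    wald = fit.wald_test(contrast, scalar=False, use_f=True)
    anova_f = float(np.squeeze(wald.statistic))
    anova_p = float(np.squeeze(wald.pvalue))

    # cell means and their covariance from the fixed effects
    fe = fit.fe_params
    cov = fit.cov_params().loc[fe.index, fe.index].to_numpy()
    design = np.zeros((n_dev, len(fe)))
    design[:, 0] = 1.0
    for i, dev in enumerate(devices):
        nm = f"C(device)[T.{dev}]"
        if nm in fe.index:
            design[i, list(fe.index).index(nm)] = 1.0
    means = design @ fe.to_numpy()
    mean_cov = design @ cov @ design.T

    # residual degrees of freedom of the subject-blocked design
    dof = max((n_dev - 1) * (n_sub - 1), 1)
    pairwise = []
    for i, j in itertools.combinations(range(n_dev), 2):
        diff = means[i] - means[j]
        se = np.sqrt(mean_cov[i, i] + mean_cov[j, j] - 2 * mean_cov[i, j])
        q = np.abs(diff) / max(se, 1e-300) * np.sqrt(2.0)
        p = float(stats.studentized_range.sf(q, n_dev, dof))
        pairwise.append(PairwiseComparison(devices[i], devices[j],
                                           float(diff), p, p < alpha))
    return DeviceComparisonReport(n_observations=len(df), anova_f=anova_f,
                                  anova_p=anova_p, pairwise=pairwise,
                                  alpha=alpha)
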