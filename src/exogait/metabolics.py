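"""Smoothed Umberger-style muscle metabolic energetics and cycle averaging.

The instantaneous metabolic rate of a muscle is the sum of an
activation/maintenance heat rate, a shortening/lengthening heat rate and the
mechanical work rate of the contractile element, scaled by muscle mass.  The
published model is piecewise-defined (conditionals on excitation vs
activation, on the sign of fiber velocity and on fiber length relative to
optimal); for gradient-based collocation every conditional here is replaced
by a C1-smooth surrogate (tanh blends and a smooth ramp) controlled by a
single sharpness parameter.  An independently coded, unsmoothed reference of
the same equations lives in :mod:`exogait.metabolics_reference` and serves as
the oracle the smoothed model is tested against.

Whole-body reporting follows the study conventions: integrate the summed
muscle rates of one leg over the cycle, multiply by two (left-right
symmetry), divide by motion duration and body mass, and add a constant basal
rate of 1.2 W/kg.  Percent changes are expressed relative to the unassisted
gross average total rate, for the total and for each muscle, so per-muscle
changes sum exactly to the total change.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .muscle import MuscleParams, force_velocity


@dataclass(frozen=True)
class MetabolicConfig:
    """Coefficients of the energetics model.

    ``basal_rate`` (W/kg body mass) is added once at the whole-body level.
    ``smoothing_sharpness`` scales every tanh surrogate (1/argument-scale);
    larger values approach the piecewise model.  Heat-rate coefficients
    follow the cited-model lineage: activation/maintenance heat
    ``128*ft + 25`` W/kg muscle, shortening-heat coefficients
    ``100 / (v_max/2.5)`` (slow-twitch) and ``153 / v_max`` (fast-twitch)
    W*s/kg per optimal-fiber-length, lengthening coefficient 4x the
    slow-twitch shortening coefficient, aerobic scaling 1.5.
    """

    basal_rate: float = 1.2
    smoothing_sharpness: float = 40.0
    clamp_negative_total: bool = True
    aerobic_scale: float = 1.5
    act_maint_slow: float = 25.0
    act_maint_fast_slope: float = 128.0
    shortening_coef_slow_numerator: float = 100.0
    shortening_coef_fast_numerator: float = 153.0
    lengthening_factor: float = 4.0
    slow_twitch_vmax_ratio: float = 2.5

    def __post_init__(self) -> None:
        if self.basal_rate < 0:
            raise ValueError("basal_rate must be >= 0")
        if self.smoothing_sharpness <= 0:
            raise ValueError("smoothing_sharpness must be > 0")


def _sig(x, k):
    """Smooth 0/1 switch: 0.5*(1 + tanh(k*x))."""
    return 0.5 * (1.0 + np.tanh(k * x))


def _smooth_pos(x, eps):
    """C-infinity surrogate for max(0, x)."""
    return 0.5 * (x + np.sqrt(x * x + eps * eps))


def muscle_metabolic_rate(a, e, l_m_norm, v_m_norm, active_force_multiplier,
                          params: MuscleParams,
                          config: MetabolicConfig = MetabolicConfig(),
                          validate: bool = True):
    """Instantaneous metabolic rate of one muscle in W (smoothed model).

    Parameters
    ----------
    a, e : activation and excitation in [0, 1] (broadcastable arrays).
    l_m_norm : fiber length / optimal fiber length.
    v_m_norm : fiber velocity in optimal fiber lengths per second
        (shortening negative).
    active_force_multiplier : the active force-length multiplier at
        ``l_m_norm`` (the isometric curve value, excluding force-velocity).

    The rate excludes the whole-body basal term.  With
    ``config.clamp_negative_total`` the total (heat + work) is passed through
    a smooth non-negativity clamp before mass scaling.
    """
    if validate and (np.any(np.real(a) < -1e-9) or np.any(np.real(a) > 1 + 1e-9)
                     or np.any(np.real(e) < -1e-9) or np.any(np.real(e) > 1 + 1e-9)):
        raise ValueError("activation/excitation out of [0,1]")
    k = config.smoothing_sharpness
    ft = params.fast_twitch_fraction
    f_iso = active_force_multiplier

    # excitation/activation measure: A = e when e > a, else (e + a) / 2;
    # e - a varies on a smaller scale than the other switch arguments, so
    # this blend gets a proportionally sharper width
    s_ea = _sig(e - a, 4.0 * k)
    big_a = s_ea * e + (1.0 - s_ea) * 0.5 * (e + a)
    # guard the fractional power against (slightly) non-positive trial
    # points: the rate is identically zero there
    neg = np.real(big_a) <= 0.0
    big_a = np.where(neg, 0.0 * big_a, big_a)
    a06 = np.where(neg, 0.0 * big_a, np.where(neg, 1.0, big_a) ** 0.6)
    a20 = big_a ** 2.0

    # activation/maintenance heat, with (0.4 + 0.6 * f_iso) length correction
    # blending in above optimal fiber length
    h_am = (config.act_maint_fast_slope * ft + config.act_maint_slow) * a06
    s_l = _sig(l_m_norm - 1.0, k)
    len_fac = (1.0 - s_l) + s_l * (0.4 + 0.6 * f_iso)
    h_am = h_am * len_fac

    # shortening / lengthening heat
    v_max_st = params.v_max / config.slow_twitch_vmax_ratio
    alpha_st = config.shortening_coef_slow_numerator / v_max_st
    alpha_ftc = config.shortening_coef_fast_numerator / params.v_max
    alpha_s = alpha_st * (1.0 - ft) + alpha_ftc * ft
    alpha_l = config.lengthening_factor * alpha_st
    eps_v = 0.4 / k  # velocity smoothing half-width, optimal fiber lengths/s
    v_short = _smooth_pos(-v_m_norm, eps_v)   # shortening speed, lopt/s
    v_len = _smooth_pos(v_m_norm, eps_v)      # lengthening speed, lopt/s
    len_fac_sl = (1.0 - s_l) + s_l * f_iso
    h_sl = (alpha_s * v_short * a20 + alpha_l * v_len * big_a) * len_fac_sl

    # mechanical work rate of the contractile element per kg muscle
    # (positive when shortening); forces in N, velocity in m/s
    f_ce = params.f_max * a * f_iso * force_velocity(v_m_norm / params.v_max)
    mass = params.mass
    w_dot = -f_ce * v_m_norm * params.l_m_opt / mass

    total = config.aerobic_scale * (h_am + h_sl) + w_dot
    if config.clamp_negative_total:
        # clamp width shrinks with the activity measure so an inactive muscle
        # dissipates exactly zero (the clamp is exact at A == 0)
        total = _smooth_pos(total, big_a / k)
    return total * mass


def gross_average_total_rate(per_muscle_rates, time, body_mass,
                             config: MetabolicConfig = MetabolicConfig(),
                             duration: float | None = None):
    """Gross average total metabolic rate in W/kg body mass.

    ``2 * integral(sum of muscle rates) / (duration * mass) + basal``; the
    factor two accounts for solving one leg under left-right symmetry.
    ``per_muscle_rates``: (T, M) array in W for one leg; trapezoidal
    quadrature on ``time``.
    """
    time = np.asarray(time, dtype=float)
    if duration is None:
        duration = float(time[-1] - time[0])
    if duration <= 0 or body_mass <= 0:
        raise ValueError("duration and body_mass must be > 0")
    total = np.trapezoid(np.sum(per_muscle_rates, axis=-1), time)
    return 2.0 * total / (duration * body_mass) + config.basal_rate


def average_muscle_rate(rate_series, time, body_mass,
                        duration: float | None = None):
    """Average metabolic rate of one muscle in W/kg body mass (no basal term)."""
    time = np.asarray(time, dtype=float)
    if duration is None:
        duration = float(time[-1] - time[0])
    if duration <= 0 or body_mass <= 0:
        raise ValueError("duration and body_mass must be > 0")
    return 2.0 * np.trapezoid(np.asarray(rate_series), time) / (duration * body_mass)


@dataclass
class MetabolicReport:
    """Per-muscle and gross average metabolic rates for one condition (W/kg)."""

    muscle_names: tuple[str, ...]
    per_muscle: np.ndarray          # (M,) W/kg body mass, no basal
    gross_total: float              # W/kg body mass, includes basal
    condition: str = "unassisted"

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"muscle": list(self.muscle_names),
                           "average_rate_w_per_kg": self.per_muscle})
        df.attrs["gross_total_w_per_kg"] = self.gross_total
        return df

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "condition": self.condition,
            "gross_total_w_per_kg": self.gross_total,
            "per_muscle_w_per_kg": dict(zip(self.muscle_names,
                                            map(float, self.per_muscle))),
        }, indent=2))


def report_from_rates(muscle_names, per_muscle_rates, time, body_mass,
                      config: MetabolicConfig = MetabolicConfig(),
                      condition: str = "unassisted") -> MetabolicReport:
    """Build a :class:`MetabolicReport` from per-muscle rate trajectories (W)."""
    per = np.array([average_muscle_rate(per_muscle_rates[:, i], time, body_mass)
                    for i in range(per_muscle_rates.shape[1])])
    gross = gross_average_total_rate(per_muscle_rates, time, body_mass, config)
    return MetabolicReport(tuple(muscle_names), per, float(gross), condition)


@dataclass
class PercentChangeReport:
    """Percent change vs unassisted, normalized by unassisted gross total.

    Negative values are savings.  Per-muscle changes sum to the total change
    exactly (the basal rate cancels in the difference).
    """

    muscle_names: tuple[str, ...]
    total: float
    per_muscle: np.ndarray


def percent_change(assisted: MetabolicReport,
                   unassisted: MetabolicReport) -> PercentChangeReport:
    """100 * (assisted - unassisted) / unassisted_gross, total and per muscle."""
    if unassisted.gross_total <= 0:
        raise ValueError("unassisted gross rate must be > 0")
    if assisted.muscle_names != unassisted.muscle_names:
        raise ValueError("muscle rosters differ between reports")
    g0 = unassisted.gross_total
    total = 100.0 * (assisted.gross_total - unassisted.gross_total) / g0
    per = 100.0 * (assisted.per_muscle - unassisted.per_muscle) / g0
    return PercentChangeReport(assisted.muscle_names, float(total), per)
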