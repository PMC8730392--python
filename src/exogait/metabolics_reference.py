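"""Unsmoothed piecewise reference implementation of the muscle energetics model.

This module is deliberately written independently of :mod:`exogait.metabolics`
(plain conditional logic, no smooth surrogates) and serves as the oracle that
the smoothed, collocation-friendly implementation is verified against.  Only
the whole-rate function is provided; it is not used by the optimal-control
path.
"""

from __future__ import annotations

import numpy as np

from .metabolics import MetabolicConfig
from .muscle import MuscleParams


def _fv_piecewise(v_over_vmax: float) -> float:
    # same analytic force-velocity curve, evaluated directly
    d2 = 8.0
    d1 = 1.0 / np.arcsinh(d2)
    return 1.0 + d1 * np.arcsinh(d2 * v_over_vmax)


def reference_muscle_metabolic_rate(a: float, e: float, l_m_norm: float,
                                    v_m_norm: float,
                                    active_force_multiplier: float,
                                    params: MuscleParams,
                                    config: MetabolicConfig = MetabolicConfig()) -> float:
    """Piecewise (hard-conditional) metabolic rate of one muscle in W.

    Scalar-only.  Conditionals are exact: excitation/activation measure
    switches at ``e == a``, shortening/lengthening heat switches at zero
    fiber velocity, and the fiber-length corrections switch at optimal fiber
    length.  Total rate is hard-clamped at zero when the configuration asks
    for clamping.
    """
    ft = params.fast_twitch_fraction
    f_iso = float(active_force_multiplier)

    if e > a:
        big_a = e
    else:
        big_a = 0.5 * (e + a)

    h_am = (config.act_maint_fast_slope * ft + config.act_maint_slow) * big_a ** 0.6
    if l_m_norm > 1.0:
        h_am *= 0.4 + 0.6 * f_iso

    v_max_st = params.v_max / config.slow_twitch_vmax_ratio
    alpha_st = config.shortening_coef_slow_numerator / v_max_st
    alpha_ftc = config.shortening_coef_fast_numerator / params.v_max
    alpha_l = config.lengthening_factor * alpha_st
    if v_m_norm <= 0.0:  # shortening
        h_sl = (alpha_st * (1.0 - ft) + alpha_ftc * ft) * (-v_m_norm) * big_a ** 2.0
    else:  # lengthening
        h_sl = alpha_l * v_m_norm * big_a
    if l_m_norm > 1.0:
        h_sl *= f_iso

    f_ce = params.f_max * a * f_iso * _fv_piecewise(v_m_norm / params.v_max)
    mass = params.mass
    w_dot = -f_ce * v_m_norm * params.l_m_opt / mass

    total = config.aerobic_scale * (h_am + h_sl) + w_dot
    if config.clamp_negative_total and total < 0.0:
        total = 0.0
    return total * mass
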