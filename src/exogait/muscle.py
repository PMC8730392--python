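"""Hill-type muscle-tendon units with activation dynamics and tendon compliance.

The muscle model is formulated for direct collocation: every curve is smooth
(C1 or better) and every operation is vectorized and complex-step safe (no
branching on input values), so derivatives can be obtained to machine
precision by complex-step differentiation.

Model structure
---------------
Each muscle-tendon unit (MTU) is a fiber (active force-length, force-velocity
and passive elastic elements, constant-height pennation) in series with a
nonlinear elastic tendon.  Tendon compliance is handled *implicitly*: the
normalized tendon force ``f_t_norm`` is a state and its time derivative is a
control, so fiber kinematics follow algebraically from the inverted tendon
force-length curve and the prescribed MTU length/velocity.

Curve family (constants documented in docs/methods.md):

* active force-length: Gaussian ``exp(-(l-1)^2 / gamma)`` with gamma = 0.45
  (anchored so the multiplier is exactly 1 at optimal fiber length);
* passive force-length: scaled exponential that is exactly 0 at optimal
  length and exactly 1 at ``1 + passive_strain_at_fmax``;
* force-velocity: ``1 + d1*asinh(d2*v)`` with ``d1 = 1/asinh(d2)``, which is
  exactly 1 at zero velocity and exactly 0 at maximal shortening velocity;
* tendon force-length: scaled exponential that is exactly 0 at slack length
  and exactly 1 at ``1 + tendon_strain_at_fmax``, with a closed-form inverse.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import numpy as np
import yaml

DOF_NAMES: tuple[str, ...] = ("hip_flexion", "knee_flexion", "ankle_dorsiflexion")

#: Canonical 9-muscle sagittal-plane roster (one leg), merged-muscle set.
MUSCLE_NAMES: tuple[str, ...] = (
    "glut_max",
    "hamstrings",
    "iliopsoas",
    "rect_fem",
    "vasti",
    "bifemsh",
    "gastroc",
    "soleus",
    "tib_ant",
)

# Curve shape constants (single source of truth, see docs/methods.md).
ACTIVE_FL_GAMMA = 0.45
FV_D2 = 8.0
FV_D1 = 1.0 / np.arcsinh(FV_D2)
PASSIVE_KPE = 4.0
TENDON_KT = 35.0
FIBER_DAMPING = 0.01
ACT_SMOOTH_B = 20.0


class MuscleModelError(ValueError):
    """Invalid muscle parameter or state."""


@dataclass(frozen=True)
class MuscleParams:
    """Parameters of one Hill-type muscle-tendon unit.

    Units: forces N, lengths m, times s, v_max in optimal fiber lengths per
    second, specific tension N/m^2, density kg/m^3.
    """

    name: str
    f_max: float
    l_m_opt: float
    l_t_slack: float
    v_max: float = 10.0
    pennation_opt: float = 0.0
    passive_strain_at_fmax: float = 0.6
    tendon_strain_at_fmax: float = 0.049
    tau_act: float = 0.015
    tau_deact: float = 0.060
    fast_twitch_fraction: float = 0.5
    specific_tension: float = 0.25e6
    muscle_density: float = 1059.7

    def __post_init__(self) -> None:
        for attr in ("f_max", "l_m_opt", "l_t_slack", "v_max",
                     "specific_tension", "muscle_density",
                     "passive_strain_at_fmax", "tendon_strain_at_fmax",
                     "tau_act", "tau_deact"):
            if getattr(self, attr) <= 0:
                raise MuscleModelError(f"{self.name}: {attr} must be > 0")
        if not 0.0 <= self.fast_twitch_fraction <= 1.0:
            raise MuscleModelError(f"{self.name}: fast_twitch_fraction not in [0,1]")
        if self.tau_act > self.tau_deact:
            raise MuscleModelError(f"{self.name}: tau_act must be <= tau_deact")

    @property
    def mass(self) -> float:
        """Muscle mass in kg: (f_max / specific_tension) * l_m_opt * density."""
        return self.f_max / self.specific_tension * self.l_m_opt * self.muscle_density


@dataclass(frozen=True)
class MuscleState:
    """State/control bundle of one muscle at one instant."""

    activation: float
    tendon_force_norm: float
    excitation: float = 0.0
    d_tendon_force_norm: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.activation <= 1.0:
            raise MuscleModelError("activation not in [0,1]")
        if not 0.0 <= self.excitation <= 1.0:
            raise MuscleModelError("excitation not in [0,1]")
        if self.tendon_force_norm < 0.0:
            raise MuscleModelError("tendon_force_norm must be >= 0")


@dataclass(frozen=True)
class MuscleSetModel:
    """The 9-muscle planar roster with each muscle's spanned DOFs."""

    muscles: tuple[MuscleParams, ...]
    spans: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        if len(self.muscles) != 9:
            raise MuscleModelError("muscle roster is fixed at 9 muscles")
        names = [m.name for m in self.muscles]
        if sorted(names) != sorted(MUSCLE_NAMES):
            raise MuscleModelError(f"unexpected roster {names}")
        for name, dofs in self.spans.items():
            for d in dofs:
                if d not in DOF_NAMES:
                    raise MuscleModelError(f"{name} spans unknown DOF {d}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.muscles)

    def __getitem__(self, name: str) -> MuscleParams:
        for m in self.muscles:
            if m.name == name:
                return m
        raise KeyError(name)

    def span_matrix(self) -> np.ndarray:
        """Boolean (n_muscles, n_dofs) matrix of anatomical DOF spans."""
        out = np.zeros((len(self.muscles), len(DOF_NAMES)), dtype=bool)
        for i, m in enumerate(self.muscles):
            for d in self.spans[m.name]:
                out[i, DOF_NAMES.index(d)] = True
        return out

    def array(self, attr: str) -> np.ndarray:
        return np.array([getattr(m, attr) for m in self.muscles], dtype=float)

    def with_params(self, updated: Mapping[str, MuscleParams]) -> "MuscleSetModel":
        return MuscleSetModel(
            muscles=tuple(updated.get(m.name, m) for m in self.muscles),
            spans=self.spans,
        )

    def scaled(self, l_m_opt_scale: np.ndarray, l_t_slack_scale: np.ndarray) -> "MuscleSetModel":
        """Return a copy with per-muscle optimal-fiber-length / slack-length scales applied."""
        new = []
        for i, m in enumerate(self.muscles):
            new.append(replace(m, l_m_opt=m.l_m_opt * float(l_m_opt_scale[i]),
                               l_t_slack=m.l_t_slack * float(l_t_slack_scale[i])))
        return MuscleSetModel(muscles=tuple(new), spans=self.spans)


def default_muscle_set() -> MuscleSetModel:
    """Load the versioned default parameter table for the 9 merged muscles."""
    text = resources.files("exogait.data").joinpath("muscles.yaml").read_text()
    raw = yaml.safe_load(text)
    muscles = tuple(MuscleParams(name=name, **fields) for name, fields in raw["muscles"].items())
    spans = {name: tuple(dofs) for name, dofs in raw["spans"].items()}
    return MuscleSetModel(muscles=muscles, spans=spans)


# ---------------------------------------------------------------------------
# characteristic curves
# ---------------------------------------------------------------------------

def active_force_length(l_m_norm):
    """Active force-length multiplier; exactly 1 at optimal length."""
    d = l_m_norm - 1.0
    return np.exp(-d * d / ACTIVE_FL_GAMMA)


def passive_force_length(l_m_norm, passive_strain_at_fmax):
    """Passive multiplier; 0 at optimal length, 1 at 1 + passive strain."""
    return (np.exp(PASSIVE_KPE * (l_m_norm - 1.0) / passive_strain_at_fmax) - 1.0) \
        / (np.exp(PASSIVE_KPE) - 1.0)


def force_velocity(v_m_norm):
    """Force-velocity multiplier of fiber velocity normalized by v_max.

    Monotone increasing; exactly 1 at v = 0 and exactly 0 at maximal
    shortening (v = -1). Shortening is negative.
    """
    return 1.0 + FV_D1 * np.arcsinh(FV_D2 * v_m_norm)


def tendon_force_length(l_t_norm, tendon_strain_at_fmax):
    """Normalized tendon force; 0 at slack length, 1 at 1 + tendon strain."""
    c1 = 1.0 / (np.exp(TENDON_KT * tendon_strain_at_fmax) - 1.0)
    return c1 * (np.exp(TENDON_KT * (l_t_norm - 1.0)) - 1.0)


def tendon_length_from_force(f_t_norm, tendon_strain_at_fmax):
    """Closed-form inverse of the tendon force-length curve."""
    c1 = 1.0 / (np.exp(TENDON_KT * tendon_strain_at_fmax) - 1.0)
    return 1.0 + np.log(f_t_norm / c1 + 1.0) / TENDON_KT


def characteristic_curves(l_m_norm, v_m_norm, l_t_norm, params: MuscleParams) -> dict:
    """Evaluate all dimensionless multipliers at the given normalized state."""
    if np.any(np.real(l_m_norm) <= 0):
        raise MuscleModelError("normalized fiber length must be > 0")
    return {
        "active_fl": active_force_length(l_m_norm),
        "passive_fl": passive_force_length(l_m_norm, params.passive_strain_at_fmax),
        "fv": force_velocity(v_m_norm),
        "tendon_fl": tendon_force_length(l_t_norm, params.tendon_strain_at_fmax),
    }


# ---------------------------------------------------------------------------
# activation dynamics
# ---------------------------------------------------------------------------

def activation_rate(e, a, tau_act, tau_deact, validate: bool = True):
    """First-order activation dynamics da/dt.

    Smooth tanh blend between the activation time constant (scaled by
    0.5 + 1.5a) and the deactivation time constant, continuous in (e, a),
    zero at e == a, driving a toward e.
    """
    if validate and (np.any(np.real(e) < -1e-9) or np.any(np.real(e) > 1 + 1e-9)
                     or np.any(np.real(a) < -1e-9) or np.any(np.real(a) > 1 + 1e-9)):
        raise MuscleModelError("excitation/activation out of [0,1]")
    f = 0.5 + 0.5 * np.tanh(ACT_SMOOTH_B * (e - a))
    scale = 0.5 + 1.5 * a
    return (e - a) * (f / (tau_act * scale) + (1.0 - f) * scale / tau_deact)


# ---------------------------------------------------------------------------
# implicit muscle-tendon equilibrium
# ---------------------------------------------------------------------------

def fiber_kinematics(f_t_norm, d_f_t_norm, l_mt, v_mt,
                     l_m_opt, l_t_slack, v_max, pennation_opt,
                     tendon_strain_at_fmax):
    """Fiber kinematics from the tendon-force state via the inverted tendon curve.

    Constant-height pennation model: ``l_m * sin(alpha) = l_m_opt * sin(alpha_opt)``.
    Returns (l_m_norm, v_m_norm, cos_pennation), where v_m_norm is the fiber
    velocity normalized by ``v_max * l_m_opt``.
    """
    c1 = 1.0 / (np.exp(TENDON_KT * np.asarray(tendon_strain_at_fmax)) - 1.0)
    l_t = l_t_slack * (1.0 + np.log(f_t_norm / c1 + 1.0) / TENDON_KT)
    # chain rule through the inverse tendon curve: d l_t / d f_t_norm
    v_t = l_t_slack * d_f_t_norm / (TENDON_KT * (f_t_norm + c1))
    h = l_m_opt * np.sin(pennation_opt)
    proj = l_mt - l_t
    # smooth guard keeps the along-tendon projection positive
    proj = 0.5 * (proj + np.sqrt(proj * proj + (1e-4 * l_m_opt) ** 2))
    l_m = np.sqrt(proj * proj + h * h)
    cos_a = proj / l_m
    v_m = (v_mt - v_t) * cos_a
    return l_m / l_m_opt, v_m / (v_max * l_m_opt), cos_a


def equilibrium_residual(state: MuscleState | None, l_mt, v_mt, params: MuscleParams,
                         *, arrays: tuple | None = None):
    """Implicit muscle-tendon equilibrium residual (dimensionless).

    residual = (a*fl_act*fv + fl_pass + beta*v_m_norm) * cos(pennation) - f_t_norm

    A zero residual defines muscle-tendon force equilibrium.  Either a
    :class:`MuscleState` or a raw ``arrays=(a, f_t_norm, d_f_t_norm)`` tuple
    (vectorized / complex-valued) may be supplied.

    Returns (residual, info-dict with l_m_norm, v_m_norm, cos_pennation).
    """
    if arrays is None:
        a = state.activation
        f_t = state.tendon_force_norm
        d_f_t = state.d_tendon_force_norm
    else:
        a, f_t, d_f_t = arrays
    if np.any(np.real(l_mt) <= params.l_t_slack * 0.5):
        raise MuscleModelError("geometrically impossible MTU configuration")
    l_m_norm, v_m_norm, cos_a = fiber_kinematics(
        f_t, d_f_t, l_mt, v_mt, params.l_m_opt, params.l_t_slack,
        params.v_max, params.pennation_opt, params.tendon_strain_at_fmax)
    fl = active_force_length(l_m_norm)
    fv = force_velocity(v_m_norm)
    fp = passive_force_length(l_m_norm, params.passive_strain_at_fmax)
    res = (a * fl * fv + fp + FIBER_DAMPING * v_m_norm) * cos_a - f_t
    return res, {"l_m_norm": l_m_norm, "v_m_norm": v_m_norm, "cos_pennation": cos_a}


def rigid_tendon_fiber_length(l_mt, params: MuscleParams):
    """Fiber kinematics under a rigid-tendon assumption (l_t == l_t_slack)."""
    h = params.l_m_opt * np.sin(params.pennation_opt)
    proj = l_mt - params.l_t_slack
    proj = 0.5 * (proj + np.sqrt(proj * proj + (1e-4 * params.l_m_opt) ** 2))
    l_m = np.sqrt(proj * proj + h * h)
    return l_m / params.l_m_opt, proj / l_m


def rigid_tendon_passive_force(l_mt, params: MuscleParams):
    """Passive fiber force along the tendon (N) with a rigid tendon."""
    l_m_norm, cos_a = rigid_tendon_fiber_length(l_mt, params)
    return params.f_max * passive_force_length(
        l_m_norm, params.passive_strain_at_fmax) * cos_a


# ---------------------------------------------------------------------------
# joint moments
# ---------------------------------------------------------------------------

def joint_moments_from_muscles(forces, moment_arms):
    """Net muscle-generated moments: moment_d = sum_m r(m, d) * F(m).

    ``forces``: (..., n_muscles); ``moment_arms``: (..., n_muscles, n_dofs).
    """
    forces = np.asarray(forces)
    moment_arms = np.asarray(moment_arms)
    if forces.shape != moment_arms.shape[:-1]:
        raise MuscleModelError(
            f"shape mismatch: forces {forces.shape} vs arms {moment_arms.shape}")
    return np.einsum("...m,...md->...d", forces, moment_arms)
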