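"""Seeded synthetic gait-data generator.

Emulates the inputs a treadmill-walking study provides, so every pipeline
stage is testable offline: one ~1.1 s gait cycle of sagittal-plane walking
kinematics and net joint moments built from low-order periodic (Fourier-bump)
templates, kinematically consistent muscle-tendon lengths/velocities and
moment arms for the 9-muscle planar set, EMG-like excitation envelopes in
[0, 1], and a forward-consistent ground-truth dataset for recovery tests.

Geometry is analytic by construction: each muscle's moment arm about a DOF is
a polynomial in that joint angle, and the MTU length is the corresponding
antiderivative, ``l(theta) = l_ref - sum_dof P(theta_dof)`` with ``P' = r``,
so moment arms equal ``-d l / d theta`` exactly and MTU velocities follow by
the chain rule.  Everything is deterministic given (seed, config).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .gait_cycle import GaitCycle
from .muscle import (DOF_NAMES, MUSCLE_NAMES, MuscleSetModel, FIBER_DAMPING,
                     FV_D1, FV_D2, TENDON_KT, active_force_length,
                     default_muscle_set, joint_moments_from_muscles,
                     passive_force_length, tendon_force_length,
                     activation_rate)

# ---------------------------------------------------------------------------
# templates: periodic harmonics (amp, phase) and excitation bumps
# ---------------------------------------------------------------------------

#: joint-angle templates, rad: (offset, ((amp, phase), ...)) with
#: value = offset + sum_k amp_k * cos(2*pi*k*(phi - phase_k)), phi in [0, 1)
ANGLE_TEMPLATES: dict[str, tuple[float, tuple[tuple[float, float], ...]]] = {
    "hip_flexion": (0.08, ((0.32, 0.97), (0.04, 0.30))),
    "knee_flexion": (0.38, ((0.45, 0.70), (0.11, 0.13))),
    "ankle_dorsiflexion": (0.00, ((0.12, 0.40), (0.15, 0.37))),
}

#: net-moment templates, N.m per kg body mass (same harmonic form)
MOMENT_TEMPLATES: dict[str, tuple[float, tuple[tuple[float, float], ...]]] = {
    "hip_flexion": (-0.05, ((0.85, 0.55), (0.10, 0.30))),
    "knee_flexion": (0.05, ((0.10, 0.40), (0.30, 0.37))),
    "ankle_dorsiflexion": (-0.35, ((0.55, 0.98), (0.25, 0.20))),
}

#: moment-arm polynomials r(theta) = c0 + c1*theta + c2*theta^2, meters,
#: keyed (muscle, dof); signs fixed by anatomy (flexion/dorsiflexion positive)
MOMENT_ARM_POLYS: dict[tuple[str, str], tuple[float, ...]] = {
    ("glut_max", "hip_flexion"): (-0.062, -0.010),
    ("hamstrings", "hip_flexion"): (-0.055, -0.005),
    ("hamstrings", "knee_flexion"): (0.030, -0.010),
    ("iliopsoas", "hip_flexion"): (0.045, 0.005),
    ("rect_fem", "hip_flexion"): (0.035, 0.000),
    ("rect_fem", "knee_flexion"): (-0.048, 0.010),
    ("vasti", "knee_flexion"): (-0.045, 0.010),
    ("bifemsh", "knee_flexion"): (0.028, -0.008),
    ("gastroc", "knee_flexion"): (0.020, -0.006),
    ("gastroc", "ankle_dorsiflexion"): (-0.048, 0.008),
    ("soleus", "ankle_dorsiflexion"): (-0.046, 0.006),
    ("tib_ant", "ankle_dorsiflexion"): (0.040, 0.004),
}

#: ground-truth excitation programs: muscle -> ((amp, center, width), ...)
#: phases in fraction of gait cycle (heel-strike start), periodic bumps
EXCITATION_PROGRAMS: dict[str, tuple[tuple[float, float, float], ...]] = {
    "glut_max": ((0.3509, 0.0177, 0.0835),),
    "hamstrings": ((0.1078, 0.8984, 0.0582),),
    "iliopsoas": ((0.3246, 0.5396, 0.0768),),
    "rect_fem": ((0.081, 0.5495, 0.044),),
    "vasti": ((0.1809, 0.0954, 0.0739),),
    "bifemsh": ((0.0371, 0.3724, 0.0387),),
    "gastroc": ((0.0254, 0.4149, 0.039),),
    "soleus": ((0.6992, 0.4234, 0.0885),),
    "tib_ant": ((0.1807, 0.0199, 0.0558), (0.0618, 0.661, 0.0493)),
}

EXCITATION_FLOOR = 0.01

#: muscles with measurable surface/fine-wire EMG (iliopsoas excluded: deep)
DEFAULT_EMG_MUSCLES: tuple[str, ...] = tuple(
    m for m in MUSCLE_NAMES if m != "iliopsoas")


def _harmonics(phi, template):
    offset, harmonics = template
    out = np.full_like(np.asarray(phi, dtype=float), offset)
    for k, (amp, phase) in enumerate(harmonics, start=1):
        out = out + amp * np.cos(2.0 * np.pi * k * (phi - phase))
    return out


def _harmonics_deriv(phi, template, duration):
    _, harmonics = template
    out = np.zeros_like(np.asarray(phi, dtype=float))
    for k, (amp, phase) in enumerate(harmonics, start=1):
        out = out - amp * 2.0 * np.pi * k * np.sin(2.0 * np.pi * k * (phi - phase))
    return out / duration


def _bump(phi, center, width):
    """Periodic Gaussian-like bump (von Mises kernel), peak 1 at center."""
    kappa = 1.0 / (2.0 * np.pi * width) ** 2 * 2.0
    return np.exp((np.cos(2.0 * np.pi * (phi - center)) - 1.0) * kappa)


def excitation_templates(phi, programs: Mapping | None = None) -> np.ndarray:
    """Ground-truth excitations, shape (T, 9), values in [floor, 1]."""
    programs = programs or EXCITATION_PROGRAMS
    phi = np.asarray(phi, dtype=float)
    out = np.zeros((phi.shape[0], len(MUSCLE_NAMES)))
    for i, m in enumerate(MUSCLE_NAMES):
        e = np.zeros_like(phi)
        for amp, center, width in programs[m]:
            e = e + amp * _bump(phi, center, width)
        out[:, i] = EXCITATION_FLOOR + (1.0 - EXCITATION_FLOOR) * np.minimum(e, 1.0)
    return out


# ---------------------------------------------------------------------------
# analytic planar geometry
# ---------------------------------------------------------------------------

class PlanarGeometry:
    """Polynomial moment-arm geometry with analytic MTU lengths.

    ``l_ref`` places each fiber at optimal length (zero tendon strain) in the
    neutral posture of the *reference* muscle set; the skeletal paths do not
    change when muscle parameters are later calibrated.
    """

    def __init__(self, muscle_set: MuscleSetModel | None = None,
                 arm_polys: Mapping | None = None):
        ms = muscle_set or default_muscle_set()
        self.arm_polys = dict(arm_polys or MOMENT_ARM_POLYS)
        self.l_ref = np.array([
            m.l_t_slack + m.l_m_opt * np.cos(m.pennation_opt)
            for m in ms.muscles])
        self._muscle_names = ms.names

    def _poly(self, muscle: str, dof: str) -> np.ndarray | None:
        key = (muscle, dof)
        if key not in self.arm_polys:
            return None
        return np.asarray(self.arm_polys[key], dtype=float)

    def moment_arms(self, angles: np.ndarray) -> np.ndarray:
        """(..., 3) joint angles -> (..., M, 3) moment arms in meters."""
        angles = np.asarray(angles, dtype=float)
        out = np.zeros(angles.shape[:-1] + (len(self._muscle_names), 3))
        for i, m in enumerate(self._muscle_names):
            for j, d in enumerate(DOF_NAMES):
                c = self._poly(m, d)
                if c is not None:
                    out[..., i, j] = np.polynomial.polynomial.polyval(
                        angles[..., j], c)
        return out

    def mtu_lengths(self, angles: np.ndarray) -> np.ndarray:
        """(..., 3) joint angles -> (..., M) MTU lengths in meters.

        ``l = l_ref - sum_dof P(theta)`` where P is the antiderivative of the
        moment-arm polynomial with P(0) = 0, so ``r = -dl/dtheta`` exactly.
        """
        angles = np.asarray(angles, dtype=float)
        out = np.broadcast_to(self.l_ref, angles.shape[:-1] + (len(self._muscle_names),)).copy()
        for i, m in enumerate(self._muscle_names):
            for j, d in enumerate(DOF_NAMES):
                c = self._poly(m, d)
                if c is not None:
                    anti = np.polynomial.polynomial.polyint(c)
                    out[..., i] -= np.polynomial.polynomial.polyval(
                        angles[..., j], anti)
        return out

    def mtu_velocities(self, angles: np.ndarray,
                       joint_velocities: np.ndarray) -> np.ndarray:
        """Chain rule: v_mtu = -sum_dof r(theta) * theta_dot."""
        arms = self.moment_arms(angles)
        return -np.einsum("...md,...d->...m", arms, np.asarray(joint_velocities))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions the generator emulates.

    Defaults emulate a typical healthy adult walking on a treadmill:
    1.1 s stride at 1.25 m/s, 72.4 kg body mass.
    """

    seed: int = 0
    duration: float = 1.1
    body_mass: float = 72.4
    n_samples: int = 151
    emg_noise_sd: float = 0.0
    moment_noise_sd: float = 0.0
    emg_muscles: tuple[str, ...] = DEFAULT_EMG_MUSCLES

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.body_mass <= 0 or self.n_samples < 2:
            raise ValueError("invalid synthetic configuration")


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_gait_cycle(config: SyntheticConfig = SyntheticConfig(),
                        muscle_set: MuscleSetModel | None = None,
                        geometry: PlanarGeometry | None = None) -> GaitCycle:
    """One synthetic gait cycle with template moments (no muscle consistency)."""
    ms = muscle_set or default_muscle_set()
    geom = geometry or PlanarGeometry(ms)
    rng = np.random.default_rng(config.seed)
    t = np.linspace(0.0, config.duration, config.n_samples)
    phi = t / config.duration

    angles = np.column_stack([_harmonics(phi, ANGLE_TEMPLATES[d]) for d in DOF_NAMES])
    vels = np.column_stack([_harmonics_deriv(phi, ANGLE_TEMPLATES[d], config.duration)
                            for d in DOF_NAMES])
    moments = np.column_stack([_harmonics(phi, MOMENT_TEMPLATES[d]) for d in DOF_NAMES])
    moments = moments * config.body_mass
    if config.moment_noise_sd > 0:
        moments = moments + rng.normal(0.0, config.moment_noise_sd, moments.shape)

    emg = {}
    exc = excitation_templates(phi)
    for m in config.emg_muscles:
        sig = exc[:, MUSCLE_NAMES.index(m)]
        if config.emg_noise_sd > 0:
            # multiplicative log-normal envelope noise plus additive floor
            sig = sig * rng.lognormal(0.0, config.emg_noise_sd, sig.shape) \
                + rng.uniform(0.0, 0.01, sig.shape)
        emg[m] = np.clip(sig, 0.0, 1.0)

    return GaitCycle(
        time=t,
        joint_angles=angles,
        joint_velocities=vels,
        net_moments=moments,
        mtu_lengths=geom.mtu_lengths(angles),
        mtu_velocities=geom.mtu_velocities(angles, vels),
        moment_arms=geom.moment_arms(angles),
        body_mass=config.body_mass,
        emg=emg or None,
    )


def _fiber_velocity_root(a, l_m_norm, f_t_norm, cos_a, ms_arrays):
    """Solve the damped fiber force balance for normalized fiber velocity.

    Damped Hill equilibrium, monotone in velocity; vectorized Newton.
    Velocity is normalized by v_max (optimal fiber lengths/s / v_max).
    """
    fl = active_force_length(l_m_norm)
    fp = passive_force_length(l_m_norm, ms_arrays["passive_strain"])
    v = np.zeros_like(l_m_norm)
    target = f_t_norm / np.maximum(cos_a, 1e-6)
    for _ in range(25):
        fv = 1.0 + FV_D1 * np.arcsinh(FV_D2 * v)
        g = a * fl * fv + fp + FIBER_DAMPING * v - target
        dg = a * fl * FV_D1 * FV_D2 / np.sqrt(1.0 + (FV_D2 * v) ** 2) + FIBER_DAMPING
        step = g / dg
        v = v - np.clip(step, -0.5, 0.5)
    return v


def generate_ground_truth_dataset(config: SyntheticConfig = SyntheticConfig(),
                                  muscle_set: MuscleSetModel | None = None,
                                  geometry: PlanarGeometry | None = None) -> dict:
    """Forward-consistent ground truth for recovery tests.

    Smooth periodic excitations drive activation and fiber dynamics forward
    at the true parameters; the cycle's net moments are then *defined* as the
    muscle-generated moments, so the true trajectories are feasible with zero
    reserve torque and near-optimal for the unassisted problem.  EMG equals
    the excitations (optionally noised).

    Returns a dict with keys ``cycle``, ``muscle_set`` (true parameters),
    ``excitations``, ``activations``, ``tendon_forces``, ``fiber_lengths_norm``
    (all on the cycle's grid).
    """
    ms = muscle_set or default_muscle_set()
    geom = geometry or PlanarGeometry(ms)
    rng = np.random.default_rng(config.seed)

    arrays = {
        "f_max": ms.array("f_max"), "l_m_opt": ms.array("l_m_opt"),
        "l_t_slack": ms.array("l_t_slack"), "v_max": ms.array("v_max"),
        "penn": ms.array("pennation_opt"),
        "passive_strain": ms.array("passive_strain_at_fmax"),
        "tendon_strain": ms.array("tendon_strain_at_fmax"),
        "tau_act": ms.array("tau_act"), "tau_deact": ms.array("tau_deact"),
    }
    h_penn = arrays["l_m_opt"] * np.sin(arrays["penn"])

    # Implicit-trapezoid forward integration on the output grid itself, over
    # two cycles for periodicity (activation/fiber time constants are far
    # below the cycle duration).  Using the same quadrature rule as the
    # trapezoidal collocation transcription makes the generated states
    # *exactly* representable on a mesh that coincides with this grid, so
    # recovery tests measure identifiability rather than discretization bias.
    n = config.n_samples
    t_out = np.linspace(0.0, config.duration, n)
    h = t_out[1] - t_out[0]
    phi_out = t_out / config.duration

    exc = excitation_templates(phi_out)
    angles = np.column_stack([_harmonics(phi_out, ANGLE_TEMPLATES[d]) for d in DOF_NAMES])
    vels = np.column_stack([_harmonics_deriv(phi_out, ANGLE_TEMPLATES[d], config.duration)
                            for d in DOF_NAMES])
    l_mt = geom.mtu_lengths(angles)
    v_mt = geom.mtu_velocities(angles, vels)
    arms = geom.moment_arms(angles)

    kt = TENDON_KT
    c1 = 1.0 / (np.exp(kt * arrays["tendon_strain"]) - 1.0)
    lts = arrays["l_t_slack"]
    # the tendon curve is extended smoothly below slack (small negative
    # normalized force), so near-slack dynamics stay well-defined
    f_floor = -0.019

    def dft_from_equilibrium(a, f_t, lmt_k, vmt_k):
        """Tendon-force rate implied by the Hill equilibrium at one node."""
        l_t = lts * (1.0 + np.log(f_t / c1 + 1.0) / kt)
        proj = np.maximum(lmt_k - l_t, 1e-6)
        l_m = np.sqrt(proj ** 2 + h_penn ** 2)
        cos_a = proj / l_m
        l_m_norm = l_m / arrays["l_m_opt"]
        v_norm = _fiber_velocity_root(a, l_m_norm, f_t, cos_a, arrays)
        v_m = v_norm * arrays["v_max"] * arrays["l_m_opt"]
        v_t = vmt_k - v_m / cos_a
        return v_t * kt * (f_t + c1) / lts

    def act_step(a0, e0, e1):
        """One implicit-trapezoid step of the activation dynamics."""
        r0 = activation_rate(e0, a0, arrays["tau_act"], arrays["tau_deact"])
        a1 = np.clip(a0 + h * r0, 1e-6, 1.0)
        for _ in range(30):
            r1 = activation_rate(e1, np.clip(a1, 0, 1),
                                 arrays["tau_act"], arrays["tau_deact"])
            g = a1 - a0 - 0.5 * h * (r0 + r1)
            da = 1e-7
            r1p = activation_rate(e1, np.clip(a1 + da, 0, 1),
                                  arrays["tau_act"], arrays["tau_deact"])
            dg = 1.0 - 0.5 * h * (r1p - r1) / da
            a1 = a1 - g / dg
        return np.clip(a1, 1e-6, 1.0)

    def tendon_step(f0, d0, a1, lmt1, vmt1):
        """One implicit-trapezoid step of the tendon-force dynamics."""
        f1 = np.maximum(f0 + h * d0, f_floor)
        for _ in range(30):
            d1 = dft_from_equilibrium(a1, f1, lmt1, vmt1)
            g = f1 - f0 - 0.5 * h * (d0 + d1)
            df = 1e-8
            d1p = dft_from_equilibrium(a1, f1 + df, lmt1, vmt1)
            dg = 1.0 - 0.5 * h * (d1p - d1) / df
            f1 = np.maximum(f1 - g / dg, f_floor)
        return f1

    # initial state: activation at the excitation, tendon force from the
    # rigid-tendon geometry; two cycles wash out the transient
    a = exc[0].copy()
    f_t = np.maximum(tendon_force_length(
        (l_mt[0] - arrays["l_m_opt"] * np.cos(arrays["penn"])) / lts,
        arrays["tendon_strain"]), 0.0)
    for _cycle in range(2):
        a_traj = np.zeros((n, 9))
        ft_traj = np.zeros((n, 9))
        dft_traj = np.zeros((n, 9))
        a_traj[0], ft_traj[0] = a, f_t
        dft_traj[0] = dft_from_equilibrium(a, f_t, l_mt[0], v_mt[0])
        for k in range(n - 1):
            a = act_step(a, exc[k], exc[k + 1])
            f_t = tendon_step(ft_traj[k], dft_traj[k], a, l_mt[k + 1], v_mt[k + 1])
            a_traj[k + 1], ft_traj[k + 1] = a, f_t
            dft_traj[k + 1] = dft_from_equilibrium(a, f_t, l_mt[k + 1], v_mt[k + 1])

    # fiber lengths implied by the tendon state (for reporting)
    l_t_len = lts * (1.0 + np.log(ft_traj / c1 + 1.0) / kt)
    proj = np.maximum(l_mt - l_t_len, 1e-6)
    lm_traj = np.sqrt(proj ** 2 + h_penn[None, :] ** 2)

    forces = arrays["f_max"][None, :] * ft_traj
    net_moments = joint_moments_from_muscles(forces, arms)

    emg = {}
    for m in config.emg_muscles:
        sig = exc[:, MUSCLE_NAMES.index(m)]
        if config.emg_noise_sd > 0:
            sig = np.clip(sig * rng.lognormal(0.0, config.emg_noise_sd, sig.shape),
                          0.0, 1.0)
        emg[m] = sig

    cycle = GaitCycle(
        time=t_out, joint_angles=angles, joint_velocities=vels,
        net_moments=net_moments, mtu_lengths=l_mt, mtu_velocities=v_mt,
        moment_arms=arms, body_mass=config.body_mass, emg=emg or None)
    return {
        "cycle": cycle,
        "muscle_set": ms,
        "excitations": exc,
        "activations": a_traj,
        "tendon_forces": ft_traj,
        "d_tendon_forces": dft_traj,
        "fiber_lengths_norm": lm_traj / arrays["l_m_opt"][None, :],
    }


# ---------------------------------------------------------------------------
# passive-moment fixtures
# ---------------------------------------------------------------------------

@dataclass
class PassiveMomentData:
    """Static postures with experimental (or synthetic) passive joint moments.

    ``postures``: (P, 3) joint angles in rad; ``moments``: (P, 3) N.m;
    ``weights``: (P, 3) fitting weights.
    """

    postures: np.ndarray
    moments: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.postures = np.atleast_2d(np.asarray(self.postures, dtype=float))
        self.moments = np.atleast_2d(np.asarray(self.moments, dtype=float))
        self.weights = np.atleast_2d(np.asarray(self.weights, dtype=float))
        if self.postures.shape != self.moments.shape \
                or self.postures.shape != self.weights.shape:
            raise ValueError("postures, moments and weights must share shape (P, 3)")


def default_postures() -> np.ndarray:
    """Multi-joint static postures spanning physiological ranges (rad)."""
    hips = [-0.35, 0.0, 0.45, 0.85]
    knees = [0.05, 0.45, 0.95, 1.45]
    ankles = [-0.35, 0.0, 0.30]
    out = []
    for i, h in enumerate(hips):
        for j, k in enumerate(knees):
            # subsample the full grid to keep the fixture compact but
            # multi-joint (hip-knee coupling excites the biarticulars)
            out.append([h, k, ankles[(i + j) % 3]])
    return np.asarray(out)


def generate_passive_moment_data(muscle_set: MuscleSetModel,
                                 postures: np.ndarray | None = None,
                                 noise_sd: float = 0.0,
                                 seed: int = 0,
                                 geometry: PlanarGeometry | None = None) -> PassiveMomentData:
    """Rigid-tendon passive moments at the given parameters, plus noise."""
    from .muscle import rigid_tendon_passive_force

    geom = geometry or PlanarGeometry()
    postures = default_postures() if postures is None else np.atleast_2d(postures)
    rng = np.random.default_rng(seed)
    l_mt = geom.mtu_lengths(postures)
    arms = geom.moment_arms(postures)
    forces = np.column_stack([
        rigid_tendon_passive_force(l_mt[:, i], m)
        for i, m in enumerate(muscle_set.muscles)])
    moments = joint_moments_from_muscles(forces, arms)
    if noise_sd > 0:
        moments = moments + rng.normal(0.0, noise_sd, moments.shape)
    return PassiveMomentData(postures=postures, moments=moments,
                             weights=np.ones_like(moments))
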