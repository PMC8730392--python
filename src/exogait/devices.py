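"""Ideal, massless exoskeleton torque actuators and the study's 15 conditions.

Assistance is applied in up to five semantic joint directions (hip flexion,
hip extension, knee flexion, knee extension, ankle plantarflexion) as pure
torques with mass-normalized peak limits: 1.0 N.m/kg for each hip and knee
direction and 2.0 N.m/kg for ankle plantarflexion.  Multi-joint devices are
driven either by one control trajectory per direction ("independent") or by a
single shared control trajectory scaled per direction by static gain
variables in [0, 1] ("coupled").  Users address directions semantically; the
sign convention (flexion/dorsiflexion positive) is applied internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

from .muscle import DOF_NAMES

#: semantic direction -> (storage DOF index, sign of an assistive torque)
DIRECTIONS: dict[str, tuple[int, int]] = {
    "hip_flexion": (0, +1),
    "hip_extension": (0, -1),
    "knee_flexion": (1, +1),
    "knee_extension": (1, -1),
    "ankle_plantarflexion": (2, -1),
}

#: mass-normalized peak torque limits, N.m/kg
TORQUE_LIMITS: dict[str, float] = {
    "hip_flexion": 1.0,
    "hip_extension": 1.0,
    "knee_flexion": 1.0,
    "knee_extension": 1.0,
    "ankle_plantarflexion": 2.0,
}

_ABBREV = {"hip_flexion": "hf", "hip_extension": "he", "knee_flexion": "kf",
           "knee_extension": "ke", "ankle_plantarflexion": "ap"}
_FROM_ABBREV = {v: k for k, v in _ABBREV.items()}

#: the five studied multi-joint direction combinations
MULTI_JOINT_COMBOS: tuple[tuple[str, ...], ...] = (
    ("hip_extension", "knee_extension"),
    ("hip_flexion", "knee_flexion"),
    ("knee_flexion", "ankle_plantarflexion"),
    ("hip_flexion", "ankle_plantarflexion"),
    ("hip_flexion", "knee_flexion", "ankle_plantarflexion"),
)


class DeviceError(ValueError):
    """Invalid device specification or controls."""


@dataclass(frozen=True)
class DeviceSpec:
    """One assistance condition (or the unassisted condition, mode='none')."""

    directions: tuple[str, ...] = ()
    mode: str = "none"
    torque_limits: Mapping[str, float] = field(default_factory=lambda: dict(TORQUE_LIMITS))
    gain_bounds: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.mode not in ("none", "single", "independent", "coupled"):
            raise DeviceError(f"unknown mode {self.mode!r}")
        for d in self.directions:
            if d not in DIRECTIONS:
                raise DeviceError(f"unknown direction {d!r}")
            if self.torque_limits[d] <= 0:
                raise DeviceError("torque limits must be > 0")
        if self.mode == "none" and self.directions:
            raise DeviceError("mode 'none' takes no directions")
        if self.mode == "single" and len(self.directions) != 1:
            raise DeviceError("mode 'single' requires exactly one direction")
        if self.mode in ("independent", "coupled") \
                and tuple(self.directions) not in MULTI_JOINT_COMBOS:
            raise DeviceError(
                f"{self.directions} is not one of the studied multi-joint combinations")

    @property
    def identifier(self) -> str:
        if self.mode == "none":
            return "unassisted"
        base = "+".join(_ABBREV[d] for d in self.directions)
        return base if self.mode == "single" else f"{base}/{self.mode}"

    @property
    def n_directions(self) -> int:
        return len(self.directions)

    def to_yaml(self) -> str:
        return yaml.safe_dump({"directions": list(self.directions),
                               "mode": self.mode,
                               "torque_limits": {d: self.torque_limits[d]
                                                 for d in self.directions},
                               "gain_bounds": list(self.gain_bounds)})


def make_device(identifier: str) -> DeviceSpec:
    """Parse a stable condition identifier (e.g. ``hf``, ``he+ke/coupled``)."""
    if identifier == "unassisted":
        return DeviceSpec()
    if "/" in identifier:
        base, mode = identifier.split("/", 1)
    else:
        base, mode = identifier, "single"
    try:
        directions = tuple(_FROM_ABBREV[a] for a in base.split("+"))
    except KeyError as exc:
        raise DeviceError(f"unknown direction abbreviation in {identifier!r}") from exc
    return DeviceSpec(directions=directions, mode=mode)


def enumerate_conditions() -> list[DeviceSpec]:
    """The 16 study conditions: unassisted + 5 single + 5 coupled + 5 independent."""
    out = [DeviceSpec()]
    out += [DeviceSpec(directions=(d,), mode="single") for d in DIRECTIONS]
    out += [DeviceSpec(directions=c, mode="coupled") for c in MULTI_JOINT_COMBOS]
    out += [DeviceSpec(directions=c, mode="independent") for c in MULTI_JOINT_COMBOS]
    return out


@dataclass
class DeviceControls:
    """Control trajectories for one device.

    ``trajectories``: (T, K) in [0, 1] -- one column per direction for
    independent/single devices, a single shared column for coupled devices.
    ``gains``: (K,) static per-direction gains in [0, 1] (coupled mode only).
    """

    trajectories: np.ndarray
    gains: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.trajectories = np.atleast_2d(np.asarray(self.trajectories, dtype=float))
        if np.any(self.trajectories < -1e-9) or np.any(self.trajectories > 1 + 1e-9):
            raise DeviceError("device controls must lie in [0, 1]")
        if self.gains is not None:
            self.gains = np.asarray(self.gains, dtype=float)
            if np.any(self.gains < -1e-9) or np.any(self.gains > 1 + 1e-9):
                raise DeviceError("gains must lie in [0, 1]")


def device_torques(spec: DeviceSpec, controls: DeviceControls,
                   body_mass: float) -> np.ndarray:
    """Signed device torques in N.m, shape (T, n_directions).

    Independent/single: ``tau_d(t) = sign_d * u_d(t) * limit_d * mass``.
    Coupled: ``tau_d(t) = sign_d * gain_d * c(t) * limit_d * mass``.
    Torques are unidirectional (assistive direction only) and satisfy
    ``|tau_d| <= limit_d * mass`` by construction of the [0, 1] bounds.
    """
    if spec.mode == "none":
        return np.zeros((controls.trajectories.shape[0], 0))
    k = spec.n_directions
    u = controls.trajectories
    if spec.mode == "coupled":
        if u.shape[1] != 1 or controls.gains is None \
                or controls.gains.shape != (k,):
            raise DeviceError("coupled mode needs one shared trajectory and one gain per direction")
        u = u * controls.gains[None, :]
    else:
        if u.shape[1] != k or controls.gains is not None:
            raise DeviceError("independent/single mode needs one trajectory per direction and no gains")
    signs = np.array([DIRECTIONS[d][1] for d in spec.directions], dtype=float)
    limits = np.array([spec.torque_limits[d] for d in spec.directions], dtype=float)
    return u * (signs * limits * body_mass)[None, :]


def torques_by_dof(spec: DeviceSpec, direction_torques: np.ndarray) -> np.ndarray:
    """Scatter per-direction torques (T, K) into storage-DOF torques (T, 3)."""
    out = np.zeros((direction_torques.shape[0], len(DOF_NAMES)))
    for j, d in enumerate(spec.directions):
        out[:, DIRECTIONS[d][0]] += direction_torques[:, j]
    return out
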