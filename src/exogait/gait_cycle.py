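"""Gait-cycle trajectory container and readers/writers (CSV and STO dialect).

One :class:`GaitCycle` holds everything a muscle-redundancy simulation of one
stride needs: sagittal joint kinematics and net moments for the hip, knee and
ankle, per-muscle muscle-tendon kinematics and moment arms, optional
normalized EMG envelopes, and subject mass.

Conventions
-----------
* The cycle starts at right heel-strike and spans one full stride; percent
  gait cycle is ``100 * (t - t0) / duration``.
* Hip flexion, knee flexion and ankle dorsiflexion are positive; a
  plantarflexion moment is therefore negative in storage.
* CSV is the canonical format; a tab-separated OpenSim-style STO dialect
  (``endheader`` sentinel) is offered for interoperability.
* Interpolation on resampling: cubic for kinematics and moments (their
  derivatives are consumed downstream), linear for EMG envelopes.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .muscle import DOF_NAMES, MUSCLE_NAMES


class GaitFormatError(ValueError):
    """File does not follow the documented column/header convention."""


class GaitDataError(ValueError):
    """Data violates a gait-cycle invariant (e.g. non-monotone time)."""


@dataclass
class GaitCycle:
    """One gait cycle of trajectories on a strictly increasing time grid.

    Shapes: time (T,), joint arrays (T, 3) ordered as
    (hip_flexion, knee_flexion, ankle_dorsiflexion), muscle arrays (T, M),
    moment_arms (T, M, 3); ``emg`` maps measured muscle names to (T,) arrays
    normalized to [0, 1].
    """

    time: np.ndarray
    joint_angles: np.ndarray
    joint_velocities: np.ndarray
    net_moments: np.ndarray
    mtu_lengths: np.ndarray
    mtu_velocities: np.ndarray
    moment_arms: np.ndarray
    body_mass: float
    muscle_names: tuple[str, ...] = MUSCLE_NAMES
    emg: Mapping[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        for name in ("joint_angles", "joint_velocities", "net_moments",
                     "mtu_lengths", "mtu_velocities", "moment_arms"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        t, n_m = self.time.shape[0], len(self.muscle_names)
        if np.any(np.diff(self.time) <= 0):
            raise GaitDataError("time grid must be strictly increasing")
        if self.time.shape != (t,) or self.joint_angles.shape != (t, 3) \
                or self.joint_velocities.shape != (t, 3) \
                or self.net_moments.shape != (t, 3) \
                or self.mtu_lengths.shape != (t, n_m) \
                or self.mtu_velocities.shape != (t, n_m) \
                or self.moment_arms.shape != (t, n_m, 3):
            raise GaitDataError("inconsistent trajectory shapes")
        if self.body_mass <= 0:
            raise GaitDataError("body_mass must be > 0")
        if self.emg is not None:
            for name, sig in self.emg.items():
                if name not in self.muscle_names:
                    raise GaitDataError(f"EMG for unknown muscle {name!r}")
                sig = np.asarray(sig, dtype=float)
                if sig.shape != (t,):
                    raise GaitDataError(f"EMG shape mismatch for {name!r}")
                if np.any(sig < -1e-12) or np.any(sig > 1 + 1e-12):
                    raise GaitDataError(f"EMG for {name!r} outside [0, 1]")

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    @property
    def n_samples(self) -> int:
        return int(self.time.shape[0])

    def percent_gait_cycle(self) -> np.ndarray:
        return 100.0 * (self.time - self.time[0]) / self.duration


# ---------------------------------------------------------------------------
# (de)serialization
# ---------------------------------------------------------------------------

def _to_frame(cycle: GaitCycle) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {"time": cycle.time}
    for j, dof in enumerate(DOF_NAMES):
        cols[f"{dof}/angle"] = cycle.joint_angles[:, j]
        cols[f"{dof}/velocity"] = cycle.joint_velocities[:, j]
        cols[f"{dof}/moment"] = cycle.net_moments[:, j]
    for i, m in enumerate(cycle.muscle_names):
        cols[f"{m}/mtu_length"] = cycle.mtu_lengths[:, i]
        cols[f"{m}/mtu_velocity"] = cycle.mtu_velocities[:, i]
        for j, dof in enumerate(DOF_NAMES):
            cols[f"{m}/moment_arm/{dof}"] = cycle.moment_arms[:, i, j]
    if cycle.emg is not None:
        for m, sig in cycle.emg.items():
            cols[f"{m}/emg"] = np.asarray(sig, dtype=float)
    return pd.DataFrame(cols)


def _from_frame(df: pd.DataFrame, body_mass: float) -> GaitCycle:
    def col(name: str) -> np.ndarray:
        if name not in df.columns:
            raise GaitFormatError(f"missing mandatory column {name!r}")
        return df[name].to_numpy(dtype=float)

    time = col("time")
    t, n_m = len(time), len(MUSCLE_NAMES)
    angles = np.column_stack([col(f"{d}/angle") for d in DOF_NAMES])
    vels = np.column_stack([col(f"{d}/velocity") for d in DOF_NAMES])
    moments = np.column_stack([col(f"{d}/moment") for d in DOF_NAMES])
    lengths = np.column_stack([col(f"{m}/mtu_length") for m in MUSCLE_NAMES])
    mtu_v = np.column_stack([col(f"{m}/mtu_velocity") for m in MUSCLE_NAMES])
    arms = np.zeros((t, n_m, 3))
    for i, m in enumerate(MUSCLE_NAMES):
        for j, d in enumerate(DOF_NAMES):
            name = f"{m}/moment_arm/{d}"
            arms[:, i, j] = df[name].to_numpy(dtype=float) if name in df.columns else 0.0
    emg = {m: df[f"{m}/emg"].to_numpy(dtype=float)
           for m in MUSCLE_NAMES if f"{m}/emg" in df.columns} or None
    return GaitCycle(time=time, joint_angles=angles, joint_velocities=vels,
                     net_moments=moments, mtu_lengths=lengths,
                     mtu_velocities=mtu_v, moment_arms=arms,
                     body_mass=body_mass, emg=emg)


def write_gait_cycle(cycle: GaitCycle, path: str | Path, format: str = "csv") -> None:
    """Write a cycle to ``path`` in ``csv`` or the STO dialect (deterministic)."""
    path = Path(path)
    df = _to_frame(cycle)
    if format == "csv":
        buf = io.StringIO()
        buf.write(f"# body_mass_kg={cycle.body_mass!r}\n")
        df.to_csv(buf, index=False, float_format="%.12g", lineterminator="\n")
        path.write_text(buf.getvalue())
    elif format == "sto":
        lines = [path.stem, "version=1", f"nRows={len(df)}",
                 f"nColumns={df.shape[1]}", "inDegrees=no",
                 f"body_mass_kg={cycle.body_mass!r}", "endheader"]
        buf = io.StringIO()
        df.to_csv(buf, index=False, sep="\t", float_format="%.12g",
                  lineterminator="\n")
        path.write_text("\n".join(lines) + "\n" + buf.getvalue())
    else:
        raise GaitFormatError(f"unknown format {format!r}")


def read_gait_cycle(path: str | Path, format: str | None = None,
                    body_mass: float | None = None) -> GaitCycle:
    """Read a gait cycle written by :func:`write_gait_cycle`.

    ``format`` defaults from the file suffix.  ``body_mass`` overrides the
    value embedded in the file header (required if the header lacks one).
    """
    path = Path(path)
    if format is None:
        format = "sto" if path.suffix.lower() in (".sto", ".mot") else "csv"
    text = path.read_text()
    mass = body_mass
    if format == "csv":
        lines = text.splitlines()
        skip = 0
        for ln in lines:
            if ln.startswith("#"):
                skip += 1
                if "body_mass_kg=" in ln and mass is None:
                    mass = float(ln.split("body_mass_kg=")[1])
            else:
                break
        df = pd.read_csv(io.StringIO("\n".join(lines[skip:])))
    elif format == "sto":
        lines = text.splitlines()
        try:
            end = next(i for i, ln in enumerate(lines) if ln.strip() == "endheader")
        except StopIteration:
            raise GaitFormatError("STO file missing 'endheader' sentinel")
        header = lines[:end]
        meta = dict(ln.split("=", 1) for ln in header if "=" in ln)
        if mass is None and "body_mass_kg" in meta:
            mass = float(meta["body_mass_kg"])
        df = pd.read_csv(io.StringIO("\n".join(lines[end + 1:])), sep="\t")
        if "nRows" in meta and int(meta["nRows"]) != len(df):
            raise GaitFormatError("STO header nRows inconsistent with data")
        if "nColumns" in meta and int(meta["nColumns"]) != df.shape[1]:
            raise GaitFormatError("STO header nColumns inconsistent with data")
    else:
        raise GaitFormatError(f"unknown format {format!r}")
    if mass is None:
        raise GaitFormatError("body mass not in file header; pass body_mass=")
    return _from_frame(df, float(mass))


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def resample(cycle: GaitCycle, n: int) -> GaitCycle:
    """Resample onto a uniform ``n``-point grid spanning the same duration.

    Cubic-spline interpolation for kinematics, moments, lengths and moment
    arms (linear-exact and endpoint-exact); linear interpolation for EMG.
    """
    if n < 2:
        raise GaitDataError("resample requires n >= 2")
    t_new = np.linspace(cycle.time[0], cycle.time[-1], n)

    def cubic(y: np.ndarray) -> np.ndarray:
        return CubicSpline(cycle.time, y, axis=0)(t_new)

    emg = None
    if cycle.emg is not None:
        emg = {m: np.interp(t_new, cycle.time, sig) for m, sig in cycle.emg.items()}
    return GaitCycle(
        time=t_new,
        joint_angles=cubic(cycle.joint_angles),
        joint_velocities=cubic(cycle.joint_velocities),
        net_moments=cubic(cycle.net_moments),
        mtu_lengths=cubic(cycle.mtu_lengths),
        mtu_velocities=cubic(cycle.mtu_velocities),
        moment_arms=cubic(cycle.moment_arms),
        body_mass=cycle.body_mass,
        muscle_names=cycle.muscle_names,
        emg=emg,
    )


# ---------------------------------------------------------------------------
# consistency validation
# ---------------------------------------------------------------------------

@dataclass
class ConsistencyCheck:
    name: str
    passed: bool
    residual: float
    tolerance: float
    detail: str = ""


@dataclass
class ConsistencyReport:
    checks: list[ConsistencyCheck]

    @property
    def all_passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def __getitem__(self, name: str) -> ConsistencyCheck:
        for c in self.checks:
            if c.name == name:
                return c
        raise KeyError(name)


def validate_consistency(cycle: GaitCycle, tol: float = 0.05) -> ConsistencyReport:
    """Check the cycle's kinematic invariants; reports, never raises.

    * ``velocity_consistency``: mtu_velocities vs central finite differences
      of mtu_lengths (relative RMS residual).
    * ``arm_length_consistency``: along the trajectory the chain rule gives
      d(mtu_length)/dt = -sum_dof r * dof_velocity; checked against the
      stored moment arms (relative RMS residual).
    * ``joint_velocity_consistency``: joint_velocities vs finite differences
      of joint_angles.
    * ``emg_bounds``: EMG within [0, 1] (margin residual).
    """
    checks: list[ConsistencyCheck] = []
    t = cycle.time

    def rel_rms(residual: np.ndarray, ref: np.ndarray) -> float:
        scale = max(float(np.sqrt(np.mean(ref ** 2))), 1e-12)
        return float(np.sqrt(np.mean(residual ** 2)) / scale)

    fd_v = np.gradient(cycle.mtu_lengths, t, axis=0)
    r = rel_rms(fd_v - cycle.mtu_velocities, cycle.mtu_velocities)
    checks.append(ConsistencyCheck("velocity_consistency", r <= tol, r, tol,
                                   "mtu_velocities vs d(mtu_lengths)/dt"))

    pred_v = -np.einsum("tmd,td->tm", cycle.moment_arms, cycle.joint_velocities)
    r = rel_rms(pred_v - cycle.mtu_velocities, cycle.mtu_velocities)
    checks.append(ConsistencyCheck("arm_length_consistency", r <= tol, r, tol,
                                   "mtu_velocities vs -sum(r * joint_velocity)"))

    fd_q = np.gradient(cycle.joint_angles, t, axis=0)
    r = rel_rms(fd_q - cycle.joint_velocities, cycle.joint_velocities)
    checks.append(ConsistencyCheck("joint_velocity_consistency", r <= tol, r, tol,
                                   "joint_velocities vs d(joint_angles)/dt"))

    if cycle.emg is not None:
        worst = 0.0
        for sig in cycle.emg.values():
            worst = max(worst, float(np.max(np.maximum(-sig, sig - 1.0), initial=0.0)))
        checks.append(ConsistencyCheck("emg_bounds", worst <= 1e-9, worst, 1e-9,
                                       "EMG envelopes within [0, 1]"))
    return ConsistencyReport(checks)
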