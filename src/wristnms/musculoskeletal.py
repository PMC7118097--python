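"""Simplified wrist musculoskeletal model and open-loop forward dynamics.

Six rigid-tendon Hill-type muscle-tendon units (FCU, FCR, ECU, ECRL, PT, SUP)
act on three wrist degrees of freedom (flexion/extension FE, radial/ulnar
deviation RU, pronation/supination PS) through a constant signed moment-arm
matrix.  First-order excitation-to-activation dynamics, Gaussian force-length,
a hyperbolic force-velocity curve and an exponential passive-force curve feed
per-DoF lumped rotational dynamics with passive stiffness and damping that
hold the rest posture.  The passive muscle force vanishes at and below optimal
fiber length, so at the rest posture zero excitation produces exactly zero net
torque (verified by :func:`verify_rest_equilibrium`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "DOF_NAMES",
    "MUSCLE_NAMES",
    "MuscleTendonUnit",
    "WristModel",
    "WristState",
    "ExcitationTrajectory",
    "default_wrist_model",
    "activation_step",
    "muscle_force",
    "joint_torques",
    "forward_simulate",
    "verify_rest_equilibrium",
]

DOF_NAMES = ("FE", "RU", "PS")
MUSCLE_NAMES = ("FCU", "FCR", "ECU", "ECRL", "PT", "SUP")

# force-length Gaussian width
_FL_WIDTH = 0.45
# passive curve shape (exponential, zero at normalized length <= 1)
_FP_SHAPE = 4.0
_FP_STRAIN = 0.6
# force-velocity: concentric curvature and eccentric plateau
_FV_CURV = 0.25
_FV_ECC_MAX = 1.5
_FV_ECC_C = 0.1


class IntegrationError(RuntimeError):
    """Raised when forward integration produces non-finite state."""


@dataclass
class MuscleTendonUnit:
    name: str
    f_max: float
    l_opt: float
    v_max: float
    tau_act: float
    tau_deact: float
    moment_arms: np.ndarray  # signed, m, columns FE/RU/PS

    def __post_init__(self) -> None:
        self.moment_arms = np.asarray(self.moment_arms, dtype=float)
        if self.moment_arms.shape != (3,):
            raise ValueError("moment_arms must be a 3-vector")
        if self.f_max <= 0 or self.l_opt <= 0:
            raise ValueError("f_max and l_opt must be positive")
        if self.tau_act <= 0 or self.tau_deact <= 0:
            raise ValueError("activation time constants must be positive")


@dataclass
class WristModel:
    muscles: list[MuscleTendonUnit]
    inertia: np.ndarray  # kg m^2 per DoF
    stiffness: np.ndarray  # N m / rad per DoF
    damping: np.ndarray  # N m s / rad per DoF
    joint_limits: np.ndarray  # (3, 2) rad
    q_rest: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.inertia = np.asarray(self.inertia, float)
        self.stiffness = np.asarray(self.stiffness, float)
        self.damping = np.asarray(self.damping, float)
        self.joint_limits = np.asarray(self.joint_limits, float)
        self.q_rest = np.asarray(self.q_rest, float)
        if len(self.muscles) != 6:
            raise ValueError("expected 6 muscle-tendon units")
        if np.any(self.inertia <= 0) or np.any(self.stiffness <= 0) or np.any(self.damping <= 0):
            raise ValueError("inertia, stiffness and damping must be positive")
        lo, hi = self.joint_limits[:, 0], self.joint_limits[:, 1]
        if np.any(self.q_rest < lo) or np.any(self.q_rest > hi):
            raise ValueError("joint limits must contain the rest posture")
        # cached parameter arrays for the vectorized force path
        self._R = np.stack([m.moment_arms for m in self.muscles])
        self._f_max = np.array([m.f_max for m in self.muscles])
        self._l_opt = np.array([m.l_opt for m in self.muscles])
        self._v_max = np.array([m.v_max for m in self.muscles])

    @property
    def muscle_names(self) -> list[str]:
        return [m.name for m in self.muscles]

    @property
    def moment_arm_matrix(self) -> np.ndarray:
        """6 x 3 signed moment-arm matrix R (rows muscles, cols DoFs)."""
        return self._R

    # -- YAML round trip ---------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "muscles": [
                {**asdict(m), "moment_arms": m.moment_arms.tolist()}
                for m in self.muscles
            ],
            "inertia": self.inertia.tolist(),
            "stiffness": self.stiffness.tolist(),
            "damping": self.damping.tolist(),
            "joint_limits": self.joint_limits.tolist(),
            "q_rest": self.q_rest.tolist(),
        }
        Path(path).write_text(yaml.safe_dump(doc))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "WristModel":
        doc = yaml.safe_load(Path(path).read_text())
        muscles = [MuscleTendonUnit(**m) for m in doc.pop("muscles")]
        return cls(muscles=muscles, **{k: np.asarray(v, float) for k, v in doc.items()})


@dataclass
class WristState:
    q: np.ndarray
    qdot: np.ndarray
    activations: np.ndarray

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, float)
        self.qdot = np.asarray(self.qdot, float)
        self.activations = np.clip(np.asarray(self.activations, float), 0.0, 1.0)

    @classmethod
    def rest(cls) -> "WristState":
        return cls(np.zeros(3), np.zeros(3), np.zeros(6))


@dataclass
class ExcitationTrajectory:
    """Per-muscle excitations in [0, 1], zero-order-held on window start times."""

    times: np.ndarray  # window start times, s
    values: np.ndarray  # n_windows x n_muscles
    muscle_names: tuple[str, ...] = MUSCLE_NAMES

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 2 or self.values.shape[0] != self.times.size:
            raise ValueError("values must be n_windows x n_muscles")

    @property
    def n_windows(self) -> int:
        return int(self.times.size)

    def at(self, t: float | np.ndarray) -> np.ndarray:
        """Zero-order-hold lookup; zero before the first window."""
        idx = np.searchsorted(self.times, np.atleast_1d(t), side="right") - 1
        out = np.zeros((np.size(idx), self.values.shape[1]))
        ok = idx >= 0
        out[ok] = self.values[idx[ok]]
        return out[0] if np.isscalar(t) else out

    def to_frame(self) -> "pd.DataFrame":  # noqa: F821 - lazy import
        import pandas as pd

        df = pd.DataFrame(self.values, columns=list(self.muscle_names))
        df.insert(0, "time_s", self.times)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ExcitationTrajectory":
        import pandas as pd

        df = pd.read_csv(path)
        times = df.pop("time_s").to_numpy(float)
        return cls(times, df.to_numpy(float), tuple(df.columns))


def default_wrist_model() -> WristModel:
    """Generic adult-scale wrist model used throughout as the default.

    Moment arms (m), inertias, stiffness and damping are desk-scale stand-ins
    for a generic arm model; PT/SUP act on PS only (their FE/RU contribution
    is negligible in this reduced model).  Maximal isometric forces are sized
    so that single-DoF tracking tasks use a healthy fraction of the excitation
    range without saturating.
    """
    arms = {
        "FCU": (+0.015, -0.010, 0.0),
        "FCR": (+0.015, +0.008, 0.0),
        "ECU": (-0.012, -0.012, 0.0),
        "ECRL": (-0.012, +0.010, 0.0),
        "PT": (0.0, 0.0, +0.010),
        "SUP": (0.0, 0.0, -0.012),
    }
    fmax = {"FCU": 100.0, "FCR": 100.0, "ECU": 130.0, "ECRL": 130.0, "PT": 350.0, "SUP": 300.0}
    muscles = [
        MuscleTendonUnit(
            name=name,
            f_max=fmax[name],
            l_opt=0.06,
            v_max=10.0,
            tau_act=0.015,
            tau_deact=0.060,
            moment_arms=np.asarray(arms[name]),
        )
        for name in MUSCLE_NAMES
    ]
    return WristModel(
        muscles=muscles,
        inertia=np.array([0.004, 0.004, 0.002]),
        stiffness=np.array([1.0, 1.0, 1.0]),
        damping=np.array([0.2, 0.2, 0.2]),
        joint_limits=np.array([[-1.2, 1.2], [-0.4, 0.4], [-1.4, 1.4]]),
    )


def activation_step(
    a: float | np.ndarray,
    u: float | np.ndarray,
    dt: float,
    tau_act: float | np.ndarray,
    tau_deact: float | np.ndarray,
) -> np.ndarray:
    """Exact exponential update of first-order activation dynamics.

    ``da/dt = (u - a)/tau`` with ``tau = tau_act`` when the excitation exceeds
    the activation (activation builds up) and ``tau_deact`` otherwise.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    a = np.asarray(a, float)
    u = np.asarray(u, float)
    tau = np.where(u > a, tau_act, tau_deact)
    out = u + (a - u) * np.exp(-dt / tau)
    return np.clip(out, 0.0, 1.0)


def _force_length(l_norm: np.ndarray) -> np.ndarray:
    return np.exp(-(((l_norm - 1.0) / _FL_WIDTH) ** 2))


def _force_velocity(v_norm: np.ndarray) -> np.ndarray:
    """Hyperbolic force-velocity; v_norm > 0 is lengthening, f_v(0) = 1."""
    v = np.clip(np.asarray(v_norm, float), -1.0, None)
    con = (1.0 + v) / (1.0 - v / _FV_CURV)
    ecc = (_FV_ECC_MAX * v + _FV_ECC_C) / (v + _FV_ECC_C)
    return np.where(v < 0, con, ecc)


def _force_passive(l_norm: np.ndarray) -> np.ndarray:
    l = np.asarray(l_norm, float)
    fp = (np.exp(_FP_SHAPE * (l - 1.0) / _FP_STRAIN) - 1.0) / (np.expm1(_FP_SHAPE))
    return np.where(l > 1.0, fp, 0.0)


def _fiber_geometry(mtu: MuscleTendonUnit, q: np.ndarray, qdot: np.ndarray,
                    q_rest: np.ndarray) -> tuple[float, float]:
    """Normalized fiber length and velocity for a rigid-tendon unit."""
    l = mtu.l_opt - float(mtu.moment_arms @ (q - q_rest))
    l_norm = l / mtu.l_opt
    v = -float(mtu.moment_arms @ qdot) / mtu.l_opt  # lengths per second
    v_norm = v / mtu.v_max
    return l_norm, v_norm


def muscle_force(
    mtu: MuscleTendonUnit,
    a: float,
    q: np.ndarray,
    qdot: np.ndarray,
    q_rest: np.ndarray | None = None,
) -> float:
    """Rigid-tendon Hill-type force F = f_max (a f_l f_v + f_p), clipped >= 0."""
    if not 0.0 <= a <= 1.0 + 1e-12:
        raise ValueError("activation must be in [0, 1]")
    if q_rest is None:
        q_rest = np.zeros(3)
    l_norm, v_norm = _fiber_geometry(mtu, np.asarray(q, float), np.asarray(qdot, float), q_rest)
    if l_norm <= 0:
        raise ValueError("non-physical fiber length (model out of range)")
    f = mtu.f_max * (a * _force_length(l_norm) * _force_velocity(v_norm) + _force_passive(l_norm))
    return max(float(f), 0.0)


def active_force_gains(model: WristModel, q: np.ndarray, qdot: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-muscle (active gain, passive offset) at a given state.

    With a rigid tendon the Hill force is affine in the activation:
    ``F_m = c_m a_m + p_m`` with ``c_m = f_max f_l f_v`` and
    ``p_m = f_max f_p``; used by the static-optimization calibration step.
    """
    l_norm = 1.0 - (model._R @ (q - model.q_rest)) / model._l_opt
    v_norm = -(model._R @ qdot) / (model._l_opt * model._v_max)
    c = model._f_max * _force_length(l_norm) * _force_velocity(v_norm)
    p = model._f_max * _force_passive(l_norm)
    return c, p


def _all_forces(model: WristModel, a: np.ndarray, q: np.ndarray, qdot: np.ndarray) -> np.ndarray:
    c, p = active_force_gains(model, q, qdot)
    return np.maximum(c * a + p, 0.0)


def joint_torques(model: WristModel, forces: np.ndarray,
                  q: np.ndarray | None = None, qdot: np.ndarray | None = None) -> np.ndarray:
    """Net joint torques: muscle moments minus passive stiffness and damping."""
    forces = np.asarray(forces, float)
    if forces.shape != (6,):
        raise ValueError("expected 6 muscle forces")
    if np.any(forces < 0):
        raise ValueError("muscle forces must be non-negative")
    q = model.q_rest if q is None else np.asarray(q, float)
    qdot = np.zeros(3) if qdot is None else np.asarray(qdot, float)
    tau = model.moment_arm_matrix.T @ forces
    tau -= model.stiffness * (q - model.q_rest)
    tau -= model.damping * qdot
    return tau


def forward_simulate(
    model: WristModel,
    excitations: ExcitationTrajectory,
    initial: WristState | None = None,
    dt: float = 0.001,
    duration: float | None = None,
    dof_gate: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Open-loop forward dynamics under zero-order-held excitations.

    Fixed-step RK4 on the joint mechanics at ``1/dt`` Hz (default 1 kHz), with
    the exact exponential activation update once per step.  Joint limits are
    enforced by clamping the angle and zeroing the velocity.  ``dof_gate``
    optionally zeroes the muscle torque on non-actuated DoFs, window by window
    (n_windows x 3 boolean, True = DoF driven).

    Returns ``(times, q, qdot)`` with ``times`` of shape (n,) and the angle
    and velocity arrays of shape (n, 3).
    """
    if initial is None:
        initial = WristState.rest()
    step = float(np.median(np.diff(excitations.times))) if excitations.n_windows > 1 else dt
    if dt > step + 1e-12:
        raise ValueError("dt must not exceed the excitation step")
    if duration is None:
        duration = float(excitations.times[-1] + step)
    n_steps = int(round(duration / dt))
    times = np.arange(n_steps + 1) * dt

    q = initial.q.copy()
    qdot = initial.qdot.copy()
    a = initial.activations.copy()
    tau_act = np.array([m.tau_act for m in model.muscles])
    tau_deact = np.array([m.tau_deact for m in model.muscles])

    qs = np.empty((n_steps + 1, 3))
    qds = np.empty((n_steps + 1, 3))
    qs[0], qds[0] = q, qdot
    lo, hi = model.joint_limits[:, 0], model.joint_limits[:, 1]

    u_idx = np.searchsorted(excitations.times, times + 1e-12, side="right") - 1

    def accel(q_, qd_, a_, gate_) -> np.ndarray:
        forces = _all_forces(model, a_, q_, qd_)
        tau_m = model.moment_arm_matrix.T @ forces
        if gate_ is not None:
            tau_m = tau_m * gate_
        tau = tau_m - model.stiffness * (q_ - model.q_rest) - model.damping * qd_
        return tau / model.inertia

    for k in range(n_steps):
        wi = u_idx[k]
        u = excitations.values[wi] if wi >= 0 else np.zeros(6)
        gate = None
        if dof_gate is not None:
            gate = dof_gate[wi].astype(float) if wi >= 0 else np.zeros(3)
        a = activation_step(a, u, dt, tau_act, tau_deact)
        # RK4 on (q, qdot) with activation held over the step
        k1q, k1v = qdot, accel(q, qdot, a, gate)
        k2q, k2v = qdot + 0.5 * dt * k1v, accel(q + 0.5 * dt * k1q, qdot + 0.5 * dt * k1v, a, gate)
        k3q, k3v = qdot + 0.5 * dt * k2v, accel(q + 0.5 * dt * k2q, qdot + 0.5 * dt * k2v, a, gate)
        k4q, k4v = qdot + dt * k3v, accel(q + dt * k3q, qdot + dt * k3v, a, gate)
        q = q + dt / 6.0 * (k1q + 2 * k2q + 2 * k3q + k4q)
        qdot = qdot + dt / 6.0 * (k1v + 2 * k2v + 2 * k3v + k4v)
        # joint limits: clamp and zero velocity
        below, above = q < lo, q > hi
        q = np.clip(q, lo, hi)
        qdot = np.where(below | above, 0.0, qdot)
        if not (np.all(np.isfinite(q)) and np.all(np.isfinite(qdot))):
            raise IntegrationError(f"forward integration diverged at t={times[k]:.3f}s")
        qs[k + 1], qds[k + 1] = q, qdot
    return times, qs, qds


def verify_rest_equilibrium(model: WristModel, tol: float = 1e-9) -> tuple[bool, float]:
    """Check that the rest posture with zero activation is an equilibrium.

    Returns ``(ok, residual)`` where the residual is the norm of the net
    torque at ``(q_rest, qdot=0, a=0)``.
    """
    forces = _all_forces(model, np.zeros(6), model.q_rest, np.zeros(3))
    tau = joint_torques(model, forces, model.q_rest, np.zeros(3))
    residual = float(np.linalg.norm(tau))
    return residual < tol, residual
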