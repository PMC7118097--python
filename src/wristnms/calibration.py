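"""Closed-loop calibration of the wrist model.

Scales recorded kinematics onto the model's joint limits and computes
tracking muscle excitations by PD acceleration tracking plus static
optimization of the muscle redundancy, with antagonist excitations forced to
zero while the absolute angle of the actuated DoF increases.  The resulting
excitations are dynamically consistent: forward-simulating them in open loop
reproduces the reference kinematics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy.optimize import lsq_linear

from .musculoskeletal import (
    ExcitationTrajectory,
    WristModel,
    WristState,
    activation_step,
    active_force_gains,
)
from .spike_features import WindowGrid

__all__ = [
    "KinematicsScaler",
    "TrackingConfig",
    "fit_scaler",
    "antagonist_mask",
    "static_optimization_step",
    "tracking_excitations",
]


class CalibrationError(RuntimeError):
    pass


@dataclass
class KinematicsScaler:
    """Per-DoF zero-preserving piecewise-linear map recorded -> model range.

    Positive and negative excursions get independent gains so that the
    recorded [min, max] lands exactly on the model's joint limits while the
    rest angle (0) is preserved.
    """

    pos_gain: np.ndarray  # (3,)
    neg_gain: np.ndarray  # (3,)

    def scale(self, q: np.ndarray) -> np.ndarray:
        q = np.asarray(q, float)
        return np.where(q >= 0, q * self.pos_gain, q * self.neg_gain)

    def inverse(self, q_model: np.ndarray) -> np.ndarray:
        q_model = np.asarray(q_model, float)
        return np.where(q_model >= 0, q_model / self.pos_gain, q_model / self.neg_gain)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(
                {"pos_gain": self.pos_gain.tolist(), "neg_gain": self.neg_gain.tolist()}
            )
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "KinematicsScaler":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(np.asarray(doc["pos_gain"], float), np.asarray(doc["neg_gain"], float))


@dataclass
class TrackingConfig:
    kp: float = 400.0  # 1/s^2
    kv: float = 40.0  # 1/s
    lookahead: float = 0.01  # s
    control_dt: float = 0.01  # s
    sim_dt: float = 0.001  # s, mechanics integration step inside control loop
    torque_tol: float = 1e-3  # N m, above -> flagged saturated
    slope_smooth: float = 0.05  # s, moving average before slope sign test

    def __post_init__(self) -> None:
        if self.kp <= 0 or self.kv <= 0:
            raise ValueError("gains must be positive")


def fit_scaler(kinematics: np.ndarray, model: WristModel,
               min_range: float = 1e-6) -> KinematicsScaler:
    """Fit the per-DoF affine scaler from recorded kinematics (n x 3, rad).

    DoFs with no recorded excursion on a side keep gain 1 on that side; a DoF
    with no excursion at all on either side raises ``CalibrationError``.
    """
    q = np.asarray(kinematics, float)
    if q.ndim != 2 or q.shape[1] != 3:
        raise ValueError("kinematics must be n x 3")
    pos = np.ones(3)
    neg = np.ones(3)
    any_range = False
    for d in range(3):
        qmax, qmin = float(q[:, d].max()), float(q[:, d].min())
        if qmax > min_range:
            pos[d] = model.joint_limits[d, 1] / qmax
            any_range = True
        if qmin < -min_range:
            neg[d] = model.joint_limits[d, 0] / qmin
            any_range = True
    if not any_range:
        raise CalibrationError("recorded kinematics have no excursion on any DoF")
    return KinematicsScaler(pos, neg)


def _smoothed(x: np.ndarray, dt: float, width: float) -> np.ndarray:
    n = max(int(round(width / dt)), 1)
    kernel = np.ones(n) / n
    return np.convolve(x, kernel, mode="same")


def antagonist_mask(
    times: np.ndarray,
    kinematics: np.ndarray,
    model: WristModel,
    actuated_dof: int | None = None,
    slope_smooth: float = 0.05,
) -> np.ndarray:
    """Per-sample muscle mask (True = excitation forced to zero).

    Defined for single-DoF reference trials: while the smoothed absolute angle
    of the actuated DoF increases, muscles whose moment arm opposes the
    ongoing direction are masked; during the pause and the return ramp all
    muscles are free.  Muscles without a moment arm on the actuated DoF are
    never masked.
    """
    q = np.asarray(kinematics, float)
    times = np.asarray(times, float)
    if actuated_dof is None:
        ranges = np.abs(q).max(axis=0)
        active = np.flatnonzero(ranges > 1e-9)
        if active.size > 1:
            raise ValueError("multi-DoF reference unsupported for antagonist masking")
        actuated_dof = int(active[0]) if active.size else 0
    dt = float(np.median(np.diff(times))) if times.size > 1 else 1.0
    qa = q[:, actuated_dof]
    abs_sm = _smoothed(np.abs(qa), dt, slope_smooth)
    dabs = np.gradient(abs_sm, dt)
    increasing = dabs > 1e-6
    # direction of the ongoing excursion: sign of the angle (fall back to the
    # slope sign near zero crossing)
    sign = np.sign(qa)
    slope_sign = np.sign(np.gradient(_smoothed(qa, dt, slope_smooth), dt))
    sign = np.where(sign == 0, slope_sign, sign)

    arms = model.moment_arm_matrix[:, actuated_dof]  # (6,)
    mask = np.zeros((times.size, 6), dtype=bool)
    # antagonist: moment arm works against the ongoing direction
    opposes = arms[None, :] * sign[:, None] < -1e-15
    mask[increasing] = opposes[increasing]
    mask[:, arms == 0.0] = False
    return mask


def static_optimization_step(
    model: WristModel,
    q: np.ndarray,
    qdot: np.ndarray,
    tau_req: np.ndarray,
    mask: np.ndarray | None = None,
    torque_tol: float = 1e-3,
    torque_weight: float = 1e4,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Minimal-effort activations producing a required muscle torque.

    Minimizes ``sum(a^2)`` subject to ``R^T F(a) = tau_req`` (soft, heavily
    weighted), ``0 <= a <= 1`` and ``a = 0`` for masked muscles.  With the
    rigid-tendon Hill force affine in the activation this is a
    bound-constrained least-squares problem.  Returns
    ``(activations, torque_residual, saturated)``.
    """
    tau_req = np.asarray(tau_req, float)
    if not np.all(np.isfinite(tau_req)):
        raise ValueError("required torque must be finite")
    c, p = active_force_gains(model, np.asarray(q, float), np.asarray(qdot, float))
    R = model.moment_arm_matrix  # 6 x 3
    b = tau_req - R.T @ p
    free = np.ones(6, dtype=bool) if mask is None else ~np.asarray(mask, bool)
    a = np.zeros(6)
    if free.any():
        A = (R[free] * c[free, None]).T  # 3 x n_free
        n_free = int(free.sum())
        # heavily weighted torque rows + unit-weight ridge rows pick the
        # minimum-norm activation among torque-feasible solutions
        M = np.vstack([torque_weight * A, np.eye(n_free)])
        rhs = np.concatenate([torque_weight * b, np.zeros(n_free)])
        sol = lsq_linear(M, rhs, bounds=(0.0, 1.0), method="bvls")
        a[free] = sol.x
    residual = R.T @ (c * a + p) - tau_req
    saturated = bool(np.max(np.abs(residual)) > torque_tol)
    return a, residual, saturated


def _invert_activation(a_prev: np.ndarray, a_target: np.ndarray, dt: float,
                       tau_act: np.ndarray, tau_deact: np.ndarray) -> np.ndarray:
    """Excitation that moves the activation from a_prev toward a_target in dt.

    Inverts the exponential update for each branch and picks the consistent
    one; clipped to [0, 1] when the one-step target is unreachable.
    """
    out = np.empty_like(a_prev)
    for i in range(a_prev.size):
        for tau in (tau_act[i], tau_deact[i]):
            k = np.exp(-dt / tau)
            u = (a_target[i] - a_prev[i] * k) / (1.0 - k)
            consistent = (u > a_prev[i] and tau == tau_act[i]) or (
                u <= a_prev[i] and tau == tau_deact[i]
            )
            if consistent:
                break
        out[i] = u
    return np.clip(out, 0.0, 1.0)


def tracking_excitations(
    model: WristModel,
    times: np.ndarray,
    reference: np.ndarray,
    grid: WindowGrid,
    cfg: TrackingConfig | None = None,
    actuated_dof: int | None = None,
    apply_mask: bool = True,
) -> tuple[ExcitationTrajectory, dict]:
    """Compute tracking excitations for a (scaled) reference trajectory.

    At each control step the desired acceleration is the reference
    acceleration plus PD feedback; the matching muscle torque is resolved by
    :func:`static_optimization_step` under the antagonist mask; excitations
    are recovered by inverting the activation dynamics; the model state is
    advanced with the computed excitations (closed loop).  The per-control-step
    excitations are then averaged onto the window grid, on which they are
    zero-order-held downstream.

    Returns the excitation trajectory and a diagnostics dict with the realized
    closed-loop trajectory and saturation flags.
    """
    cfg = cfg or TrackingConfig()
    times = np.asarray(times, float)
    ref = np.asarray(reference, float)
    if ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("reference must be n x 3")
    duration = float(times[-1])
    dt_ref = float(np.median(np.diff(times)))
    ref_d = np.gradient(ref, dt_ref, axis=0)
    ref_dd = np.gradient(ref_d, dt_ref, axis=0)

    h = cfg.control_dt
    n_ctrl = int(round(duration / h))
    t_ctrl = np.arange(n_ctrl) * h
    if apply_mask:
        mask_ctrl = antagonist_mask(times, ref, model, actuated_dof, cfg.slope_smooth)
        mask_at = lambda t: mask_ctrl[min(int(round(t / dt_ref)), len(times) - 1)]
    else:
        mask_at = lambda t: None

    def interp(t, arr):
        return np.array([np.interp(t, times, arr[:, d]) for d in range(3)])

    tau_a = np.array([m.tau_act for m in model.muscles])
    tau_d = np.array([m.tau_deact for m in model.muscles])
    state = WristState.rest()
    u_log = np.zeros((n_ctrl, 6))
    sat_log = np.zeros(n_ctrl, dtype=bool)
    q_log = np.zeros((n_ctrl, 3))

    n_sub = max(int(round(h / cfg.sim_dt)), 1)
    sub_dt = h / n_sub
    lo, hi = model.joint_limits[:, 0], model.joint_limits[:, 1]

    from .musculoskeletal import _all_forces  # mechanics RHS shared with forward sim

    def accel(q_, qd_, a_):
        forces = _all_forces(model, a_, q_, qd_)
        tau = model.moment_arm_matrix.T @ forces
        tau -= model.stiffness * (q_ - model.q_rest) + model.damping * qd_
        return tau / model.inertia

    for k, t in enumerate(t_ctrl):
        t_la = min(t + cfg.lookahead, duration)
        q_des = interp(t_la, ref)
        qd_des = interp(t_la, ref_d)
        qdd_ff = interp(t_la, ref_dd)
        qdd_des = qdd_ff + cfg.kv * (qd_des - state.qdot) + cfg.kp * (q_des - state.q)
        tau_req = (
            model.inertia * qdd_des
            + model.stiffness * (state.q - model.q_rest)
            + model.damping * state.qdot
        )
        a_des, _, sat = static_optimization_step(
            model, state.q, state.qdot, tau_req, mask_at(t), cfg.torque_tol
        )
        u = _invert_activation(state.activations, a_des, h, tau_a, tau_d)
        m = mask_at(t)
        if m is not None:
            u[m] = 0.0
        u_log[k] = u
        sat_log[k] = sat
        # advance plant with the commanded excitation
        a = state.activations
        q, qd = state.q, state.qdot
        for _ in range(n_sub):
            a = activation_step(a, u, sub_dt, tau_a, tau_d)
            k1q, k1v = qd, accel(q, qd, a)
            k2q, k2v = qd + 0.5 * sub_dt * k1v, accel(q + 0.5 * sub_dt * k1q, qd + 0.5 * sub_dt * k1v, a)
            k3q, k3v = qd + 0.5 * sub_dt * k2v, accel(q + 0.5 * sub_dt * k2q, qd + 0.5 * sub_dt * k2v, a)
            k4q, k4v = qd + sub_dt * k3v, accel(q + sub_dt * k3q, qd + sub_dt * k3v, a)
            q = q + sub_dt / 6.0 * (k1q + 2 * k2q + 2 * k3q + k4q)
            qd = qd + sub_dt / 6.0 * (k1v + 2 * k2v + 2 * k3v + k4v)
            below, above = q < lo, q > hi
            q = np.clip(q, lo, hi)
            qd = np.where(below | above, 0.0, qd)
        state = WristState(q, qd, a)
        q_log[k] = q

    # average control-rate excitations onto the zero-order-hold segments of
    # the window grid
    starts = grid.start_times
    edges = np.append(starts, duration)
    values = np.zeros((grid.n_windows, 6))
    for w in range(grid.n_windows):
        sel = (t_ctrl >= edges[w] - 1e-12) & (t_ctrl < edges[w + 1] - 1e-12)
        if sel.any():
            values[w] = u_log[sel].mean(axis=0)
        elif w > 0:
            values[w] = values[w - 1]
    values = np.clip(values, 0.0, 1.0)
    diagnostics = {
        "control_times": t_ctrl,
        "control_excitations": u_log,
        "realized_q": q_log,
        "saturated": sat_log,
    }
    return ExcitationTrajectory(starts, values, tuple(model.muscle_names)), diagnostics
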