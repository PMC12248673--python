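"""Error-state Kalman filter (ESKF) fusing IMU and GPS in the ENU frame.

The filter integrates a nominal state (attitude quaternion, velocity,
position, gyroscope and accelerometer biases) with bias-corrected IMU
samples and estimates a 15-dimensional error state

    [delta_p (3), delta_v (3), delta_theta (3), b_g (3), b_a (3)]

about it. GPS position fixes (3-dimensional observation) correct the
error state through the standard Kalman update; the Joseph form keeps the
covariance symmetric positive semidefinite, and the estimated error is
folded back into the nominal state and reset to zero after each update.
The attitude error uses the multiplicative small-angle (body-side)
quaternion convention, and the transition matrix is the first-order
discretization Phi = I + F*dt of the continuous error dynamics at the IMU
period.

From the fused solution the *flight acceleration* used downstream is the
signed rate of change of speed (tangential component of the gravity-free
linear acceleration), low-pass filtered below the wingbeat band; the full
navigation-frame acceleration vector is also reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .config import GRAVITY, EskfConfig
from .io import MultimodalRecording

ERROR_STATE_DIM = 15
OBS_DIM = 3

# error-state block slices
P_SL = slice(0, 3)
V_SL = slice(3, 6)
TH_SL = slice(6, 9)
BG_SL = slice(9, 12)
BA_SL = slice(12, 15)


# ----------------------------------------------------------------------
# quaternion helpers (scalar-last [x, y, z, w], Hamilton convention)
# ----------------------------------------------------------------------

def quat_multiply(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    x1, y1, z1, w1 = q1
    x2, y2, z2, w2 = q2
    return np.array([
        w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
        w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
        w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
    ])


def quat_from_rotvec(v: np.ndarray) -> np.ndarray:
    angle = float(np.linalg.norm(v))
    if angle < 1e-12:
        return np.array([0.5 * v[0], 0.5 * v[1], 0.5 * v[2], 1.0])
    axis = v / angle
    s = np.sin(angle / 2)
    return np.array([axis[0] * s, axis[1] * s, axis[2] * s,
                     np.cos(angle / 2)])


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    x, y, z, w = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def skew(v: np.ndarray) -> np.ndarray:
    return np.array([[0, -v[2], v[1]],
                     [v[2], 0, -v[0]],
                     [-v[1], v[0], 0]], dtype=float)


# ----------------------------------------------------------------------
# generic Kalman algebra (shared by the ESKF and the linear reference)
# ----------------------------------------------------------------------

def predict_covariance(P: np.ndarray, Phi: np.ndarray,
                       Q: np.ndarray) -> np.ndarray:
    """P <- Phi P Phi^T + Q, re-symmetrized."""
    P = Phi @ P @ Phi.T + Q
    return 0.5 * (P + P.T)


def kalman_gain(P: np.ndarray, H: np.ndarray, R: np.ndarray) -> np.ndarray:
    """K = P H^T (H P H^T + R)^(-1), with a regularized solve on
    numerically singular innovation covariance."""
    S = H @ P @ H.T + R
    try:
        return np.linalg.solve(S.T, (P @ H.T).T).T
    except np.linalg.LinAlgError:
        warnings.warn("innovation covariance singular; regularizing")
        S = S + 1e-9 * np.trace(S) / S.shape[0] * np.eye(S.shape[0])
        return np.linalg.solve(S.T, (P @ H.T).T).T


def joseph_update(P: np.ndarray, K: np.ndarray, H: np.ndarray,
                  R: np.ndarray) -> np.ndarray:
    """Joseph-form covariance update (I-KH) P (I-KH)^T + K R K^T."""
    ikh = np.eye(P.shape[0]) - K @ H
    P = ikh @ P @ ikh.T + K @ R @ K.T
    return 0.5 * (P + P.T)


class LinearKalmanFilter:
    """Plain linear Kalman filter built on the same algebra as the ESKF.

    Used for the 1-D equivalence check against textbook recursions.
    """

    def __init__(self, x0, P0, Phi, H, Q, R):
        self.x = np.atleast_1d(np.asarray(x0, dtype=float))
        self.P = np.atleast_2d(np.asarray(P0, dtype=float))
        self.Phi = np.atleast_2d(np.asarray(Phi, dtype=float))
        self.H = np.atleast_2d(np.asarray(H, dtype=float))
        self.Q = np.atleast_2d(np.asarray(Q, dtype=float))
        self.R = np.atleast_2d(np.asarray(R, dtype=float))

    def predict(self):
        self.x = self.Phi @ self.x
        self.P = predict_covariance(self.P, self.Phi, self.Q)

    def update(self, z):
        z = np.atleast_1d(np.asarray(z, dtype=float))
        K = kalman_gain(self.P, self.H, self.R)
        self.x = self.x + K @ (z - self.H @ self.x)
        self.P = joseph_update(self.P, K, self.H, self.R)


# ----------------------------------------------------------------------
# ESKF proper
# ----------------------------------------------------------------------

@dataclass
class NominalState:
    """Nominal (integrated) state about which errors are estimated."""

    q: np.ndarray            # body->nav quaternion, scalar-last
    v: np.ndarray            # m/s ENU
    p: np.ndarray            # m ENU
    b_g: np.ndarray          # rad/s
    b_a: np.ndarray          # m/s^2
    t: float = 0.0


@dataclass
class FilterModel:
    """Matrices of the discrete error-state filter."""

    Q: np.ndarray            # 15x15 process-noise covariance per step
    R: np.ndarray            # 3x3 observation-noise covariance
    H: np.ndarray            # 3x15 observation matrix (selects delta_p)
    gravity: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, -GRAVITY]))

    @classmethod
    def from_config(cls, cfg: EskfConfig, dt: float) -> "FilterModel":
        Q = np.zeros((ERROR_STATE_DIM, ERROR_STATE_DIM))
        Q[V_SL, V_SL] = (cfg.accel_noise * dt) ** 2 * np.eye(3)
        Q[TH_SL, TH_SL] = (cfg.gyro_noise * dt) ** 2 * np.eye(3)
        Q[BG_SL, BG_SL] = cfg.gyro_bias_walk ** 2 * dt * np.eye(3)
        Q[BA_SL, BA_SL] = cfg.accel_bias_walk ** 2 * dt * np.eye(3)
        R = cfg.gps_sigma ** 2 * np.eye(OBS_DIM)
        H = np.zeros((OBS_DIM, ERROR_STATE_DIM))
        H[:, P_SL] = np.eye(3)
        return cls(Q=Q, R=R, H=H)


def error_transition_matrix(R_nb: np.ndarray, f_body: np.ndarray,
                            omega_body: np.ndarray, dt: float) -> np.ndarray:
    """First-order discrete transition Phi = I + F dt of the error dynamics."""
    F = np.zeros((ERROR_STATE_DIM, ERROR_STATE_DIM))
    F[P_SL, V_SL] = np.eye(3)
    F[V_SL, TH_SL] = -R_nb @ skew(f_body)
    F[V_SL, BA_SL] = -R_nb
    F[TH_SL, TH_SL] = -skew(omega_body)
    F[TH_SL, BG_SL] = -np.eye(3)
    return np.eye(ERROR_STATE_DIM) + F * dt


def propagate(state: NominalState, P: np.ndarray, model: FilterModel,
              accel: np.ndarray, gyro: np.ndarray, t: float,
              dt: float) -> tuple[NominalState, np.ndarray, np.ndarray]:
    """One IMU step: integrate the nominal state, propagate the covariance.

    Returns the new state, covariance and the gravity-free navigation-frame
    linear acceleration of this step. Rejects non-increasing timestamps.
    """
    if t <= state.t - 1e-12 and state.t > 0:
        raise ValueError("IMU timestamps must be strictly increasing")
    f_b = accel - state.b_a
    w_b = gyro - state.b_g
    R_nb = quat_to_matrix(state.q)

    a_nav = R_nb @ f_b + model.gravity      # gravity-free linear acceleration
    p_new = state.p + state.v * dt + 0.5 * a_nav * dt * dt
    v_new = state.v + a_nav * dt
    q_new = quat_multiply(state.q, quat_from_rotvec(w_b * dt))
    q_new = q_new / np.linalg.norm(q_new)

    Phi = error_transition_matrix(R_nb, f_b, w_b, dt)
    P_new = predict_covariance(P, Phi, model.Q)
    if np.max(np.abs(P_new - P_new.T)) > 1e-6 * (1 + np.max(np.abs(P_new))):
        warnings.warn("covariance lost symmetry; re-symmetrizing")
        P_new = 0.5 * (P_new + P_new.T)

    new_state = NominalState(q=q_new, v=v_new, p=p_new,
                             b_g=state.b_g.copy(), b_a=state.b_a.copy(), t=t)
    return new_state, P_new, a_nav


def gps_update(state: NominalState, P: np.ndarray, model: FilterModel,
               z: np.ndarray) -> tuple[NominalState, np.ndarray]:
    """GPS position update: gain, Joseph-form covariance, error injection.

    The estimated error state is folded into the nominal state and reset
    to zero, so the error mean stays at zero between updates.
    """
    K = kalman_gain(P, model.H, model.R)
    innovation = np.asarray(z, dtype=float) - state.p
    dx = K @ innovation
    P_new = joseph_update(P, K, model.H, model.R)

    q_new = quat_multiply(state.q, quat_from_rotvec(dx[TH_SL]))
    q_new = q_new / np.linalg.norm(q_new)
    new_state = NominalState(
        q=q_new,
        v=state.v + dx[V_SL],
        p=state.p + dx[P_SL],
        b_g=state.b_g + dx[BG_SL],
        b_a=state.b_a + dx[BA_SL],
        t=state.t,
    )
    return new_state, P_new


@dataclass
class NavSolution:
    """Fused trajectory at the IMU rate."""

    timestamps: np.ndarray          # (n,) s
    attitude: np.ndarray            # (n, 4) unit quaternions, scalar-last
    velocity: np.ndarray            # (n, 3) m/s ENU
    position: np.ndarray            # (n, 3) m ENU
    linear_acceleration: np.ndarray  # (n, 3) m/s^2, gravity-free, nav frame
    accel_tangential: np.ndarray    # (n,) m/s^2, signed d(speed)/dt, smoothed
    speed: np.ndarray               # (n,) m/s
    bias_gyro: np.ndarray           # (n, 3) estimated gyro bias
    bias_accel: np.ndarray          # (n, 3) estimated accelerometer bias
    cov_diag: np.ndarray            # (n, 15) error covariance diagonal
    gps_gap_intervals: list = field(default_factory=list)
    dead_reckoning: bool = False

    def to_frame(self):
        import pandas as pd
        q = self.attitude
        return pd.DataFrame({
            "t": self.timestamps,
            "qx": q[:, 0], "qy": q[:, 1], "qz": q[:, 2], "qw": q[:, 3],
            "vE": self.velocity[:, 0], "vN": self.velocity[:, 1],
            "vU": self.velocity[:, 2],
            "pE": self.position[:, 0], "pN": self.position[:, 1],
            "pU": self.position[:, 2],
            "aE": self.linear_acceleration[:, 0],
            "aN": self.linear_acceleration[:, 1],
            "aU": self.linear_acceleration[:, 2],
            "speed": self.speed, "a_tangential": self.accel_tangential,
        })


def tangential_acceleration(velocity: np.ndarray, acceleration: np.ndarray,
                            fs: float, smooth_hz: float = 5.0) -> np.ndarray:
    """Signed rate of change of speed: a . v_hat, optionally low-passed.

    The low-pass (zero phase) keeps the behavioural time scale and rejects
    the 6-10 Hz wingbeat vibration that leaks into the specific force.
    """
    spd = np.linalg.norm(velocity, axis=1)
    safe = np.maximum(spd, 1e-6)
    a_t = np.einsum("ij,ij->i", acceleration, velocity) / safe
    if smooth_hz and smooth_hz > 0 and smooth_hz < fs / 2:
        sos = signal.butter(4, smooth_hz, btype="low", fs=fs, output="sos")
        a_t = signal.sosfiltfilt(sos, a_t)
    return a_t


def initialize_from_gps(rec: MultimodalRecording, cfg: EskfConfig,
                        init_window_s: float = 2.0) -> NominalState:
    """Initial nominal state from the leading GPS fixes.

    Velocity comes from a least-squares line through the first couple of
    seconds of fixes (a two-fix difference would inherit ~sqrt(2)*sigma/dt
    of noise), yaw from that track direction, pitch/roll level, biases
    zero.
    """
    if rec.gps_t is None or rec.gps_t.size < 2:
        return NominalState(q=np.array([0.0, 0.0, 0.0, 1.0]),
                            v=np.zeros(3), p=np.zeros(3),
                            b_g=np.zeros(3), b_a=np.zeros(3))
    m = max(int(np.searchsorted(rec.gps_t, rec.gps_t[0] + init_window_s)), 2)
    tt = rec.gps_t[:m] - rec.gps_t[0]
    A = np.column_stack([np.ones(m), tt])
    coef, *_ = np.linalg.lstsq(A, rec.gps_enu[:m], rcond=None)
    p0, v0 = coef[0], coef[1]
    yaw_enu = np.pi / 2 - np.arctan2(v0[0], v0[1])
    q0 = quat_from_rotvec(np.array([0.0, 0.0, yaw_enu]))
    return NominalState(q=q0, v=v0.astype(float), p=p0.astype(float),
                        b_g=np.zeros(3), b_a=np.zeros(3))


def run_eskf(rec: MultimodalRecording, cfg: EskfConfig | None = None,
             model: FilterModel | None = None) -> NavSolution:
    """Run the full filter over a recording: one output tick per IMU sample.

    GPS fixes are applied as they become available; outages longer than
    ``cfg.gps_gap_s`` are recorded as flagged intervals, and a recording
    with no GPS at all is processed in dead-reckoning mode (flagged, with
    covariance growing unboundedly).
    """
    cfg = cfg or EskfConfig()
    dt = 1.0 / rec.fs_imu
    if model is None:
        model = FilterModel.from_config(cfg, dt)

    t_imu = rec.t_imu
    n = t_imu.size
    if n == 0:
        raise ValueError("empty IMU stream")

    state = initialize_from_gps(rec, cfg)
    P = np.diag(np.concatenate([
        np.full(3, cfg.p0_pos ** 2), np.full(3, cfg.p0_vel ** 2),
        np.full(3, cfg.p0_att ** 2), np.full(3, cfg.p0_bg ** 2),
        np.full(3, cfg.p0_ba ** 2),
    ]))

    have_gps = rec.gps_t is not None and rec.gps_t.size > 0
    gaps: list[tuple[float, float]] = []
    if have_gps:
        dts = np.diff(rec.gps_t)
        for i in np.nonzero(dts > cfg.gps_gap_s)[0]:
            gaps.append((float(rec.gps_t[i]), float(rec.gps_t[i + 1])))
        if rec.gps_t[0] > cfg.gps_gap_s:
            gaps.insert(0, (0.0, float(rec.gps_t[0])))
        if t_imu[-1] - rec.gps_t[-1] > cfg.gps_gap_s:
            gaps.append((float(rec.gps_t[-1]), float(t_imu[-1])))

    att = np.empty((n, 4))
    vel = np.empty((n, 3))
    pos = np.empty((n, 3))
    acc = np.empty((n, 3))
    bg = np.empty((n, 3))
    ba = np.empty((n, 3))
    cov = np.empty((n, ERROR_STATE_DIM))

    gps_i = 0
    for k in range(n):
        accel = rec.imu[k, :3]
        gyro = rec.imu[k, 3:]
        state, P, a_nav = propagate(state, P, model, accel, gyro,
                                    t=float(t_imu[k]), dt=dt)
        while have_gps and gps_i < rec.gps_t.size and \
                rec.gps_t[gps_i] <= t_imu[k] + 1e-9:
            state, P = gps_update(state, P, model, rec.gps_enu[gps_i])
            gps_i += 1
        att[k] = state.q
        vel[k] = state.v
        pos[k] = state.p
        acc[k] = a_nav
        bg[k] = state.b_g
        ba[k] = state.b_a
        cov[k] = np.diag(P)

    a_tan = tangential_acceleration(vel, acc, rec.fs_imu,
                                    smooth_hz=cfg.accel_smooth_hz)
    return NavSolution(
        timestamps=t_imu, attitude=att, velocity=vel, position=pos,
        linear_acceleration=acc, accel_tangential=a_tan,
        speed=np.linalg.norm(vel, axis=1), bias_gyro=bg, bias_accel=ba,
        cov_diag=cov, gps_gap_intervals=gaps,
        dead_reckoning=not have_gps,
    )


def gps_double_difference_acceleration(
        gps_t: np.ndarray, gps_enu: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Naive baseline: tangential acceleration from double-differentiated
    raw GPS positions. Returns (timestamps, tangential acceleration)."""
    v = np.gradient(gps_enu, gps_t, axis=0)
    a = np.gradient(v, gps_t, axis=0)
    spd = np.maximum(np.linalg.norm(v, axis=1), 1e-6)
    a_t = np.einsum("ij,ij->i", a, v) / spd
    return gps_t, a_t


def nav_from_truth(truth) -> NavSolution:
    """Wrap generator ground truth in a NavSolution (oracle plumbing)."""
    n = truth.t_imu.size
    return NavSolution(
        timestamps=truth.t_imu,
        attitude=truth.attitude.as_quat(),
        velocity=truth.true_velocity,
        position=truth.true_position,
        linear_acceleration=truth.true_acceleration,
        accel_tangential=truth.accel_tangential,
        speed=truth.speed,
        bias_gyro=np.zeros((n, 3)), bias_accel=np.zeros((n, 3)),
        cov_diag=np.zeros((n, ERROR_STATE_DIM)),
    )
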