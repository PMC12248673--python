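"""Synthetic multimodal flight recordings with planted neural structure.

The generator produces a ~2 km homing flight and the three synchronized
sensor streams the analysis pipeline consumes, together with the ground
truth needed for recovery tests:

* trajectory: a cruise at ~15 m/s with smooth Gaussian acceleration
  episodes (tangential acceleration excursions up to +/-6 m/s^2, marginal
  centred on 0) and a slow heading meander;
* IMU: body-frame specific force (gravity coupling included), wingbeat
  vibration on the z axis (fundamental + 2nd and 3rd harmonics), constant
  sensor biases and white noise; gyroscope from the true attitude rates;
* GPS: true ENU position at 10 Hz plus isotropic noise;
* LFP: per-channel 1/f background plus a 30-80 Hz gamma component whose
  power decreases linearly with tangential acceleration (``gamma_slope``)
  and whose across-channel shared fraction grows quadratically with
  acceleration (``coherence_quadratic``), organized in two electrode
  groups of four channels (2x4 array geometry); a wingbeat artifact
  proportional to the z-axis vibration contaminates every channel.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, signal
from scipy.spatial.transform import Rotation

from .config import GRAVITY, SimConfig
from .io import MultimodalRecording
from .segmentation import classify_state

__all__ = ["GroundTruth", "simulate_trajectory", "simulate_sensors",
           "simulate_lfp", "simulate"]


@dataclass
class GroundTruth:
    """Noise-free flight state and clean neural signal for recovery tests."""

    t_imu: np.ndarray                 # (n,) s at the IMU rate
    true_position: np.ndarray         # (n, 3) m ENU
    true_velocity: np.ndarray         # (n, 3) m/s
    true_acceleration: np.ndarray     # (n, 3) m/s^2, gravity-free
    accel_tangential: np.ndarray      # (n,) m/s^2, signed d(speed)/dt
    speed: np.ndarray                 # (n,) m/s
    attitude: Rotation                # body->nav rotations per IMU tick
    wingbeat_accel: np.ndarray        # (n,) m/s^2, z-axis vibration waveform
    window_starts: np.ndarray         # (m,) s
    true_state_labels: list[str]      # per window
    clean_lfp: np.ndarray | None = None   # (n_channels, n_lfp) uV
    meta: dict = field(default_factory=dict)

    def arrays(self) -> dict[str, np.ndarray]:
        out = {
            "t_imu": self.t_imu,
            "true_position": self.true_position,
            "true_velocity": self.true_velocity,
            "true_acceleration": self.true_acceleration,
            "accel_tangential": self.accel_tangential,
            "speed": self.speed,
            "attitude_quat": self.attitude.as_quat(),
            "wingbeat_accel": self.wingbeat_accel,
            "window_starts": self.window_starts,
        }
        if self.clean_lfp is not None:
            out["clean_lfp"] = self.clean_lfp
        return out


def _wingbeat_waveform(t: np.ndarray, f0: float, amp: float,
                       phase: float) -> np.ndarray:
    """Flap vibration: fundamental plus 2nd and 3rd harmonics."""
    w = 2 * np.pi * f0
    return amp * (np.sin(w * t + phase)
                  + 0.5 * np.sin(2 * w * t + 2 * phase)
                  + 0.25 * np.sin(3 * w * t + 3 * phase))


def _smooth_jitter(rng: np.random.Generator, t: np.ndarray, fs: float,
                   sigma: float, cutoff_hz: float = 0.4) -> np.ndarray:
    """Band-limited zero-mean perturbation emulating airflow buffeting."""
    if sigma <= 0:
        return np.zeros_like(t)
    white = rng.standard_normal(t.size)
    sos = signal.butter(2, cutoff_hz, btype="low", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, white)
    x -= x.mean()
    std = x.std()
    return x * (sigma / std) if std > 0 else x


def simulate_trajectory(cfg: SimConfig) -> GroundTruth:
    """Generate the true flight kinematics and per-window state labels.

    Tangential acceleration is a sum of Gaussian episodes whose signs are
    steered to keep speed inside ``[speed_min, speed_max]`` (so speed stays
    well above the 2 m/s flight threshold and the time-mean acceleration is
    bounded near zero), plus a small band-limited jitter. Raises if the
    duration is too short to contain all three flight states.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))
    fs = cfg.fs_imu
    n = int(round(cfg.duration_s * fs))
    t = np.arange(n) / fs

    # --- acceleration episodes ---
    a_tan = np.zeros(n)
    v_proj = cfg.cruise_speed
    t_next = rng.uniform(2.0, 5.0)
    n_episodes = 0
    while t_next < cfg.duration_s - 2.0:
        width = rng.uniform(0.5, 1.2)
        amp = np.abs(rng.normal(0.0, cfg.episode_amp))
        if cfg.episode_amp > 0:
            amp = float(np.clip(amp + 0.8, 0.8, 6.0))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        dv = sign * amp * np.sqrt(2 * np.pi) * width
        # steer episodes so the projected speed stays inside the band:
        # flip the sign when it would overshoot, then shrink the episode
        # if even the flipped excursion does not fit
        if not (cfg.speed_min < v_proj + dv < cfg.speed_max):
            sign, dv = -sign, -dv
        if not (cfg.speed_min < v_proj + dv < cfg.speed_max):
            headroom = (cfg.speed_max - v_proj) if dv > 0 \
                else (v_proj - cfg.speed_min)
            scale = max(0.8 * headroom / abs(dv), 0.0)
            width *= scale
            dv *= scale
            if width * cfg.fs_imu < 4:   # degenerate episode, skip it
                t_next += rng.uniform(3.0, 7.0)
                continue
        v_proj += dv
        a_tan += sign * amp * np.exp(-0.5 * ((t - t_next) / width) ** 2)
        n_episodes += 1
        t_next += rng.uniform(3.0, 7.0)
    a_tan += _smooth_jitter(rng, t, fs, cfg.accel_jitter)
    a_tan = np.clip(a_tan, -6.0, 6.0)

    speed = cfg.cruise_speed + integrate.cumulative_trapezoid(
        a_tan, t, initial=0.0)
    # consistency: tangential acceleration is exactly d(speed)/dt
    a_tan = np.gradient(speed, t)

    # --- heading and velocity vector ---
    psi0 = rng.uniform(0, 2 * np.pi)
    phi0 = rng.uniform(0, 2 * np.pi)
    omega_m = 2 * np.pi / cfg.meander_period_s
    psi = psi0 + cfg.heading_meander * np.sin(omega_m * t + phi0)
    psi_dot = cfg.heading_meander * omega_m * np.cos(omega_m * t + phi0)

    e_t = np.column_stack([np.sin(psi), np.cos(psi), np.zeros(n)])   # forward
    e_n = np.column_stack([np.cos(psi), -np.sin(psi), np.zeros(n)])  # rightward
    velocity = speed[:, None] * e_t
    acceleration = a_tan[:, None] * e_t + (speed * psi_dot)[:, None] * e_n
    position = np.column_stack([
        integrate.cumulative_trapezoid(velocity[:, i], t, initial=0.0)
        for i in range(3)
    ])
    position[:, 2] += 50.0  # cruise altitude

    # --- attitude: yaw along track, small pitch bob at the flap frequency ---
    pitch = cfg.pitch_amp * np.sin(2 * np.pi * cfg.wingbeat_hz * t + phi0)
    yaw_enu = np.pi / 2 - psi      # rotation about Up taking East to forward
    attitude = Rotation.from_euler(
        "zy", np.column_stack([yaw_enu, -pitch]))

    wb = _wingbeat_waveform(t, cfg.wingbeat_hz, cfg.wingbeat_amp, phi0)
    wb_phase = phi0

    # --- per-window state labels ---
    starts = []
    s0 = 0.0
    while s0 + cfg.window_s <= cfg.duration_s + 1e-9:
        starts.append(s0)
        s0 += cfg.step_s
    window_starts = np.array(starts)
    labels = []
    for s in window_starts:
        m = (t >= s - 1e-12) & (t < s + cfg.window_s - 1e-12)
        labels.append(classify_state(float(speed[m].mean()),
                                     float(a_tan[m].mean())))
    present = set(labels)
    if cfg.episode_amp > 0 and not {"acceleration", "steady",
                                    "deceleration"} <= present:
        raise ValueError(
            "duration too short: generated flight does not contain all "
            f"three states (got {sorted(present)}); increase duration_s"
        )

    return GroundTruth(
        t_imu=t, true_position=position, true_velocity=velocity,
        true_acceleration=acceleration, accel_tangential=a_tan, speed=speed,
        attitude=attitude, wingbeat_accel=wb, window_starts=window_starts,
        true_state_labels=labels,
        meta={"seed": cfg.seed, "n_episodes": n_episodes,
              "wb_phase": wb_phase},
    )


def _body_rates(attitude: Rotation, dt: float) -> np.ndarray:
    """Body-frame angular velocity from successive rotations (log map)."""
    rel = attitude[:-1].inv() * attitude[1:]
    w = rel.as_rotvec() / dt
    return np.vstack([w, w[-1]])


def simulate_sensors(truth: GroundTruth, cfg: SimConfig) -> MultimodalRecording:
    """Render the IMU and GPS streams from the true kinematics.

    The accelerometer measures specific force in the body frame —
    ``R^T (a_n - g_n)`` with gravity ``g_n = (0, 0, -9.81)`` — so a level
    bird at rest reads +g on the z axis. Wingbeat vibration, constant
    biases and white noise are added; GPS is the true position plus
    isotropic noise of std ``gps_sigma`` per axis.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    t = truth.t_imu
    dt = 1.0 / cfg.fs_imu
    g_n = np.array([0.0, 0.0, -GRAVITY])

    specific_force_nav = truth.true_acceleration - g_n
    f_body = truth.attitude.inv().apply(specific_force_nav)
    f_body[:, 2] += truth.wingbeat_accel
    f_body += np.asarray(cfg.accel_bias)
    f_body += cfg.accel_noise * rng.standard_normal(f_body.shape)

    omega_body = _body_rates(truth.attitude, dt)
    omega_body = omega_body + np.asarray(cfg.gyro_bias)
    omega_body += cfg.gyro_noise * rng.standard_normal(omega_body.shape)

    stride = int(round(cfg.fs_imu / cfg.fs_gps))
    gps_idx = np.arange(0, t.size, stride)
    gps_t = t[gps_idx]
    gps_enu = truth.true_position[gps_idx].copy()
    gps_enu += cfg.gps_sigma * rng.standard_normal(gps_enu.shape)

    lfp = np.zeros((cfg.n_channels, int(round(cfg.duration_s * cfg.fs_lfp))))
    rec = MultimodalRecording(
        lfp=lfp, fs_lfp=cfg.fs_lfp,
        imu=np.hstack([f_body, omega_body]), fs_imu=cfg.fs_imu,
        gps_t=gps_t, gps_enu=gps_enu, fs_gps=cfg.fs_gps,
        meta={"seed": cfg.seed, "frame": "ENU"},
    )
    rec.validate()
    return rec


def _unit_band_noise(rng: np.random.Generator, n: int, fs: float,
                     lo: float, hi: float) -> np.ndarray:
    """Unit-RMS band-pass-filtered white noise."""
    sos = signal.butter(4, [lo, hi], btype="band", fs=fs, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(n))
    return x / x.std()


def _pink_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-RMS 1/f-shaped background (flat below 1 Hz)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shape = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    spec *= shape
    x = np.fft.irfft(spec, n)
    return x / x.std()


def simulate_lfp(truth: GroundTruth, cfg: SimConfig,
                 rec: MultimodalRecording | None = None) -> MultimodalRecording:
    """Render the 8-channel LFP and store the clean signal on ``truth``.

    Per channel: 1/f background + gamma narrowband component. Gamma power
    follows ``1 + gamma_slope * a(t)`` (clipped at 5% with a warning when
    the planted slope would drive it negative). Channels 0-3 and 4-7 share
    one gamma source each whose mixing fraction is
    ``rho_base + coherence_quadratic * a(t)^2`` (capped at 0.85), plus a
    weak source common to all channels. A wingbeat artifact
    ``artifact_gain *`` z-vibration (fundamental + harmonics) is added to
    the recorded — but not the clean — signal.
    """
    import warnings

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    n = int(round(cfg.duration_s * cfg.fs_lfp))
    t = np.arange(n) / cfg.fs_lfp
    a = np.interp(t, truth.t_imu, truth.accel_tangential)

    lo, hi = 30.0, 80.0
    n_ch = cfg.n_channels
    groups = [np.arange(n_ch // 2), np.arange(n_ch // 2, n_ch)]

    power_factor = 1.0 + cfg.gamma_slope * a
    if np.any(power_factor < 0.05):
        warnings.warn("planted gamma slope clips power at the 5% floor")
    envelope = cfg.gamma_rms * np.sqrt(np.clip(power_factor, 0.05, None))

    rho_g = np.clip(cfg.rho_base + cfg.coherence_quadratic * a ** 2, 0.0, 0.85)
    rho_c = cfg.rho_common
    indep = np.sqrt(np.clip(1.0 - rho_g - rho_c, 0.0, None))

    s_common = _unit_band_noise(rng, n, cfg.fs_lfp, lo, hi)
    s_group = [_unit_band_noise(rng, n, cfg.fs_lfp, lo, hi) for _ in groups]

    clean = np.empty((n_ch, n))
    for gi, idx in enumerate(groups):
        for ch in idx:
            w = _unit_band_noise(rng, n, cfg.fs_lfp, lo, hi)
            gamma = envelope * (np.sqrt(rho_c) * s_common
                                + np.sqrt(rho_g) * s_group[gi]
                                + indep * w)
            background = cfg.background_rms * _pink_noise(rng, n, cfg.fs_lfp)
            clean[ch] = background + gamma

    # regenerate the exact vibration waveform at the LFP rate
    wb_lfp = _wingbeat_waveform(t, cfg.wingbeat_hz, cfg.wingbeat_amp,
                                float(truth.meta.get("wb_phase", 0.0)))
    artifact = cfg.artifact_gain * wb_lfp

    drift = 80.0 * np.sin(2 * np.pi * 0.05 * t) + 30.0  # baseline drift, uV
    lfp = clean + artifact[None, :] + drift[None, :]

    truth.clean_lfp = clean
    if rec is None:
        rec = simulate_sensors(truth, cfg)
    rec.lfp = lfp
    rec.validate()
    return rec


def simulate(cfg: SimConfig) -> tuple[MultimodalRecording, GroundTruth]:
    """Full generator: trajectory -> sensors -> LFP."""
    truth = simulate_trajectory(cfg)
    rec = simulate_sensors(truth, cfg)
    rec = simulate_lfp(truth, cfg, rec)
    return rec, truth
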