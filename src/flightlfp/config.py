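"""Configuration objects for simulation, fusion, and the end-to-end pipeline.

All tunable thresholds, band edges and window sizes live here so that a single
YAML file can reproduce a full analysis run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

#: Canonical analysis bands (Hz). Only the gamma band (30-80 Hz) is dictated by
#: the scientific question; the remaining edges are conventional LFP bands.
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 80.0),
}

GRAVITY = 9.81  # m/s^2, magnitude of local gravity


@dataclass
class SimConfig:
    """Parameters of the synthetic multimodal flight recording generator.

    The generator emulates a short homing flight (~2 km) with smooth
    acceleration episodes, head-mounted IMU streams with gravity coupling and
    wingbeat vibration, and an 8-channel LFP whose gamma-band power decreases
    linearly with tangential acceleration and whose inter-channel gamma
    coherence grows quadratically with acceleration (U-shape).
    """

    duration_s: float = 120.0
    seed: int = 0
    n_channels: int = 8
    fs_lfp: float = 1000.0
    fs_imu: float = 200.0
    fs_gps: float = 10.0

    # --- planted neural effects ---
    #: fractional change of gamma power per m/s^2 of tangential acceleration
    gamma_slope: float = -0.08
    #: growth of the shared-source fraction per (m/s^2)^2 (coherence U-shape)
    coherence_quadratic: float = 0.025
    #: shared-source fraction within an electrode group at zero acceleration
    rho_base: float = 0.15
    #: weak shared fraction common to all channels (cross-group floor)
    rho_common: float = 0.05
    #: RMS of the gamma narrowband component at zero acceleration (uV)
    gamma_rms: float = 20.0
    #: RMS of the broadband 1/f background (uV)
    background_rms: float = 40.0

    # --- wingbeat artifact ---
    wingbeat_hz: float = 8.0          # fundamental flap frequency (6-10 Hz)
    wingbeat_amp: float = 3.0         # z-axis vibration amplitude, m/s^2
    artifact_gain: float = 40.0       # uV of LFP artifact per m/s^2 of z accel
    pitch_amp: float = 0.06           # rad, head pitch oscillation at wingbeat

    # --- trajectory ---
    cruise_speed: float = 15.0        # m/s
    speed_min: float = 8.0            # steering bounds for episode signs
    speed_max: float = 22.0
    episode_amp: float = 3.0          # m/s^2, scale of acceleration episodes
    accel_jitter: float = 0.25        # m/s^2 RMS of slow airflow perturbation
    heading_meander: float = 0.35     # rad amplitude of slow heading wander
    meander_period_s: float = 45.0

    # --- sensor imperfections ---
    gps_sigma: float = 2.12           # m per axis (2.5 m CEP / 1.1774)
    accel_noise: float = 0.04         # m/s^2 per-sample white noise std
    gyro_noise: float = 0.001         # rad/s per-sample white noise std
    accel_bias: tuple[float, float, float] = (0.20, -0.15, 0.25)  # m/s^2
    gyro_bias: tuple[float, float, float] = (0.005, -0.003, 0.004)  # rad/s

    # --- state labelling windows (must match segmentation defaults) ---
    window_s: float = 1.0
    step_s: float = 0.5

    def validate(self) -> None:
        gamma_hi = DEFAULT_BANDS["gamma"][1]
        if min(self.fs_lfp, self.fs_imu, self.fs_gps) <= 0:
            raise ValueError("sampling rates must be positive")
        if self.fs_lfp < 2 * gamma_hi:
            raise ValueError(
                f"fs_lfp={self.fs_lfp} must be >= {2 * gamma_hi} Hz "
                "(twice the upper gamma edge)"
            )
        if self.gamma_slope > 0:
            raise ValueError("gamma_slope must be <= 0 (planted decreasing trend)")
        if self.coherence_quadratic < 0:
            raise ValueError("coherence_quadratic must be >= 0 (planted U-shape)")
        if self.duration_s < 10:
            raise ValueError("duration_s must be >= 10 s")
        if not (0 < self.wingbeat_hz < self.fs_imu / 2):
            raise ValueError("wingbeat_hz must lie below the IMU Nyquist rate")


@dataclass
class EskfConfig:
    """Noise model and initialization of the error-state Kalman filter.

    Defaults are derived from the configured MEMS-grade sensor noise and the
    stated 2.5 m CEP of the GPS module.
    """

    accel_noise: float = 0.04        # m/s^2 per-sample accelerometer noise std
    gyro_noise: float = 0.001        # rad/s per-sample gyroscope noise std
    accel_bias_walk: float = 1e-3    # m/s^2 / sqrt(s) bias random walk
    gyro_bias_walk: float = 1e-5     # rad/s / sqrt(s)
    gps_sigma: float = 2.12          # m per axis

    # initial 1-sigma uncertainties
    p0_pos: float = 3.0              # m
    p0_vel: float = 3.0              # m/s
    p0_att: float = 0.2              # rad
    p0_bg: float = 0.01              # rad/s
    p0_ba: float = 0.3               # m/s^2

    gps_gap_s: float = 1.0           # flag GPS outages longer than this
    #: cutoff of the zero-phase low-pass applied to the tangential
    #: acceleration (behavioural time-scale, below the 6-10 Hz wingbeat);
    #: 0 disables smoothing
    accel_smooth_hz: float = 5.0


@dataclass
class QcConfig:
    """Trial-level quality-control thresholds."""

    max_missing_fraction: float = 0.05
    max_pause_s: float = 5.0         # continuous time below the speed threshold
    speed_threshold: float = 2.0     # m/s
    max_deviation_ratio: float = 2.0  # cross-track deviation / chord length


@dataclass
class DenoiseConfig:
    """Band-pass + VMD + DTW reweighting parameters."""

    band: tuple[float, float] = (0.5, 200.0)
    n_modes: int = 10
    vmd_alpha: float = 2000.0
    vmd_tol: float = 1e-7
    vmd_max_iter: int = 300
    dtw_chunk_s: float = 2.0
    dtw_band_fraction: float = 0.1   # Sakoe-Chiba band, fraction of chunk
    mad_factor: float = 1.0          # flag modes below median - k*MAD
    corr_min: float = 0.1            # synchrony gate: min |r| with reference
    w_low: float = 0.1               # attenuation weight for flagged modes
    #: spectral protection edge (Hz): the subtracted artifact estimate is
    #: low-passed here so that mode tails cannot perturb bands above the
    #: wingbeat harmonics; 0 disables
    protect_above_hz: float = 30.0


@dataclass
class NetworkConfig:
    """Coherence-network construction parameters."""

    band: tuple[float, float] = DEFAULT_BANDS["gamma"]
    window_s: float = 2.0            # analysis window per network
    subwindow_s: float = 0.5         # Welch segment inside the window
    density: float = 0.30            # proportional binarization density


@dataclass
class PipelineConfig:
    """End-to-end run description (simulate -> fuse -> ... -> decode)."""

    sim: SimConfig = field(default_factory=SimConfig)
    eskf: EskfConfig = field(default_factory=EskfConfig)
    qc: QcConfig = field(default_factory=QcConfig)
    denoise: DenoiseConfig = field(default_factory=DenoiseConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    window_s: float = 1.0
    step_s: float = 0.5
    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )
    trend_order_psd: int = 1
    trend_order_clustering: int = 2
    bin_width: float = 0.5
    bin_range: tuple[float, float] = (-6.0, 6.0)
    min_bin_count: int = 5
    run_denoise: bool = True
    run_decode: bool = True
    decode_band: str = "gamma"
    decode_model: str = "svm"
    decode_folds: int = 10
    decode_repeats: int = 10


def _to_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def config_to_dict(cfg: Any) -> dict:
    return _to_jsonable(cfg)


def config_hash(cfg: Any) -> str:
    """Stable SHA-256 over the canonical JSON form of a config dataclass."""
    payload = json.dumps(config_to_dict(cfg), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def _from_dict(cls, data: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        val = data[f.name]
        if dataclasses.is_dataclass(f.type) or f.name in (
            "sim", "eskf", "qc", "denoise", "network",
        ):
            sub = {"sim": SimConfig, "eskf": EskfConfig, "qc": QcConfig,
                   "denoise": DenoiseConfig, "network": NetworkConfig}[f.name]
            val = _from_dict(sub, val)
        elif isinstance(val, list):
            val = tuple(val) if f.name != "bands" else val
        elif f.name == "bands" and isinstance(val, dict):
            val = {k: tuple(v) for k, v in val.items()}
        kwargs[f.name] = val
    return cls(**kwargs)


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    cfg = _from_dict(PipelineConfig, data)
    if isinstance(cfg.bands, dict):
        cfg.bands = {k: tuple(v) for k, v in cfg.bands.items()}
    return cfg


def save_pipeline_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)
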