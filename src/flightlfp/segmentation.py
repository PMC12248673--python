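"""Flight-state segmentation and trial-level quality control.

Windows of the fused navigation solution are labelled as acceleration,
steady or deceleration flight from window-mean speed and tangential
acceleration: a window counts as steady when speed exceeds 2 m/s and the
acceleration stays within the behaviourally stable zone of +/-0.5 m/s^2
(closed interval); above +0.5 m/s^2 it is acceleration, below -0.5 m/s^2
deceleration. Windows slower than 2 m/s are excluded from analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import QcConfig

SPEED_THRESHOLD = 2.0      # m/s, minimum flight speed for a valid window
ACCEL_THRESHOLD = 0.5      # m/s^2, half-width of the behaviourally stable zone

LABELS = ("acceleration", "steady", "deceleration", "excluded")


@dataclass
class FlightSegment:
    """One labelled analysis window."""

    start_s: float
    end_s: float
    label: str
    mean_speed: float
    mean_acceleration: float
    qc_flags: set[str] = field(default_factory=set)


def classify_state(
    speed: float,
    acceleration: float,
    speed_threshold: float = SPEED_THRESHOLD,
    accel_threshold: float = ACCEL_THRESHOLD,
) -> str:
    """Label a (speed, acceleration) pair with one flight state.

    Values exactly at +/-accel_threshold are steady (closed stable zone).
    NaN inputs yield ``"excluded"``.
    """
    if not (math.isfinite(speed) and math.isfinite(acceleration)):
        return "excluded"
    if speed <= speed_threshold:
        return "excluded"
    if acceleration > accel_threshold:
        return "acceleration"
    if acceleration < -accel_threshold:
        return "deceleration"
    return "steady"


def segment_series(
    t: np.ndarray,
    speed: np.ndarray,
    acceleration: np.ndarray,
    window_s: float = 1.0,
    step_s: float = 0.5,
    accel_threshold: float = ACCEL_THRESHOLD,
) -> list[FlightSegment]:
    """Slide a window over speed/acceleration series and label each window.

    Windows are ``[start, start + window_s)``; the last window ends at or
    before the final timestamp. Window means use all samples inside the
    half-open interval; NaN means produce excluded windows.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    t = np.asarray(t, dtype=float)
    if t.size == 0:
        return []
    segments: list[FlightSegment] = []
    dt = float(np.median(np.diff(t))) if t.size > 1 else 0.0
    t0, t1 = t[0], t[-1] + dt   # samples cover [t0, t_end)
    start = t0
    while start + window_s <= t1 + 1e-9:
        mask = (t >= start - 1e-12) & (t < start + window_s - 1e-12)
        if not mask.any():
            start += step_s
            continue
        with np.errstate(invalid="ignore"):
            ms = float(np.mean(speed[mask]))
            ma = float(np.mean(acceleration[mask]))
        label = classify_state(ms, ma, accel_threshold=accel_threshold)
        seg = FlightSegment(
            start_s=float(start),
            end_s=float(start + window_s),
            label=label,
            mean_speed=ms,
            mean_acceleration=ma,
        )
        if label == "excluded" and not (math.isfinite(ms) and math.isfinite(ma)):
            seg.qc_flags.add("nan_input")
        segments.append(seg)
        start += step_s
    return segments


def segment_recording(nav, window_s: float = 1.0, step_s: float = 0.5,
                      accel_threshold: float = ACCEL_THRESHOLD) -> list[FlightSegment]:
    """Label sliding windows of a :class:`~flightlfp.fusion.NavSolution`.

    GPS-outage intervals recorded on the navigation solution are propagated
    onto overlapping windows as a ``gps_gap`` QC flag.
    """
    segs = segment_series(
        nav.timestamps, nav.speed, nav.accel_tangential,
        window_s=window_s, step_s=step_s, accel_threshold=accel_threshold,
    )
    for lo, hi in getattr(nav, "gps_gap_intervals", []) or []:
        for seg in segs:
            if seg.start_s < hi and seg.end_s > lo:
                seg.qc_flags.add("gps_gap")
    return segs


def _longest_true_run(mask: np.ndarray, dt: float) -> float:
    run = best = 0
    for v in mask:
        run = run + 1 if v else 0
        best = max(best, run)
    return best * dt


def qc_trial(rec, nav, cfg: QcConfig | None = None) -> tuple[bool, set[str]]:
    """Trial-level quality control: data integrity and flight stability.

    Fails when any stream has a missing-sample fraction above threshold
    (``gps_gap``/``imu_gap``/``lfp_gap``), when speed stays below 2 m/s for
    longer than the pause threshold (``slow_flight``), or when the maximum
    cross-track deviation from the start-to-end chord exceeds the configured
    multiple of the chord length (``path_deviation``).
    """
    cfg = cfg or QcConfig()
    flags: set[str] = set()

    def missing_fraction(arr: np.ndarray) -> float:
        return float(np.mean(~np.isfinite(arr)))

    if rec.gps_enu is None or rec.gps_enu.size == 0 or \
            missing_fraction(rec.gps_enu) > cfg.max_missing_fraction:
        flags.add("gps_gap")
    if missing_fraction(rec.imu) > cfg.max_missing_fraction:
        flags.add("imu_gap")
    if missing_fraction(rec.lfp) > cfg.max_missing_fraction:
        flags.add("lfp_gap")

    dt = float(np.median(np.diff(nav.timestamps)))
    slow = np.asarray(nav.speed) < cfg.speed_threshold
    if _longest_true_run(slow, dt) > cfg.max_pause_s:
        flags.add("slow_flight")

    pos = np.asarray(nav.position)[:, :2]
    chord = pos[-1] - pos[0]
    chord_len = float(np.linalg.norm(chord))
    if chord_len > 1e-6:
        u = chord / chord_len
        rel = pos - pos[0]
        cross = np.abs(rel[:, 0] * u[1] - rel[:, 1] * u[0])
        if float(np.max(cross)) > cfg.max_deviation_ratio * chord_len:
            flags.add("path_deviation")

    return (len(flags) == 0), flags


def segments_to_frame(segments: list[FlightSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "start_s": [s.start_s for s in segments],
            "end_s": [s.end_s for s in segments],
            "label": [s.label for s in segments],
            "mean_speed": [s.mean_speed for s in segments],
            "mean_acc": [s.mean_acceleration for s in segments],
            "flags": [",".join(sorted(s.qc_flags)) for s in segments],
        }
    )


def write_segments(segments: list[FlightSegment], path: str | Path) -> None:
    """BED-like TSV export (start_s, end_s, label, means, flags)."""
    segments_to_frame(segments).to_csv(path, sep="\t", index=False)


def read_segments(path: str | Path) -> list[FlightSegment]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        flags = set() if (not isinstance(row.flags, str) or not row.flags) \
            else set(row.flags.split(","))
        out.append(FlightSegment(row.start_s, row.end_s, row.label,
                                 row.mean_speed, row.mean_acc, flags))
    return out
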