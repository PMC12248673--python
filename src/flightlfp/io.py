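"""Recording container and on-disk formats.

A :class:`MultimodalRecording` holds the three synchronously acquired
streams at their native rates: 8-channel LFP at 1000 Hz, six-axis IMU
(tri-axial accelerometer + gyroscope) at 200 Hz, and GPS fixes at 10 Hz.
There is no community standard for synchronized LFP+IMU+GPS, so the
container is a small documented HDF5 layout::

    /lfp            float64 (n_channels, n_samples)  [uV]
    /imu            float64 (n_samples, 6)  [ax ay az (m/s^2), gx gy gz (rad/s)]
    /gps/t          float64 (n_fixes,)  [s]
    /gps/enu        float64 (n_fixes, 3)  [m, East-North-Up]
    attrs: fs_lfp, fs_imu, fs_gps, seed, subject, trial

A CSV triplet export/import (lfp.csv, imu.csv, gps.csv) is provided for
interoperability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd


@dataclass
class MultimodalRecording:
    """Time-aligned LFP / IMU / GPS streams sharing one time origin (t=0)."""

    lfp: np.ndarray            # (n_channels, n_samples) uV
    fs_lfp: float
    imu: np.ndarray            # (n_samples, 6): accel xyz m/s^2, gyro xyz rad/s
    fs_imu: float
    gps_t: np.ndarray          # (n_fixes,) s
    gps_enu: np.ndarray        # (n_fixes, 3) m ENU
    fs_gps: float
    meta: dict = field(default_factory=dict)
    qc_flags: set = field(default_factory=set)

    @property
    def t_lfp(self) -> np.ndarray:
        return np.arange(self.lfp.shape[1]) / self.fs_lfp

    @property
    def t_imu(self) -> np.ndarray:
        return np.arange(self.imu.shape[0]) / self.fs_imu

    @property
    def duration_s(self) -> float:
        return self.lfp.shape[1] / self.fs_lfp

    def validate(self) -> None:
        if self.lfp.ndim != 2 or self.imu.ndim != 2 or self.imu.shape[1] != 6:
            raise ValueError("malformed stream shapes")
        if self.gps_t is not None and self.gps_t.size > 1 and \
                np.any(np.diff(self.gps_t) <= 0):
            raise ValueError("GPS timestamps must be strictly increasing")


def write_recording(rec: MultimodalRecording, path: str | Path,
                    truth=None) -> None:
    """Write the documented HDF5 layout (optionally with a /truth group)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("lfp", data=rec.lfp)
        f.create_dataset("imu", data=rec.imu)
        if rec.gps_t is not None and rec.gps_t.size:
            g = f.create_group("gps")
            g.create_dataset("t", data=rec.gps_t)
            g.create_dataset("enu", data=rec.gps_enu)
        f.attrs["fs_lfp"] = rec.fs_lfp
        f.attrs["fs_imu"] = rec.fs_imu
        f.attrs["fs_gps"] = rec.fs_gps
        for k, v in rec.meta.items():
            f.attrs[f"meta_{k}"] = v
        if truth is not None:
            tg = f.create_group("truth")
            for name, arr in truth.arrays().items():
                tg.create_dataset(name, data=arr)
            tg.attrs["labels"] = [s.encode() for s in truth.true_state_labels]


def read_recording(path: str | Path) -> MultimodalRecording:
    """Load a recording; a missing /gps group yields a ``gps_gap`` QC flag."""
    with h5py.File(path, "r") as f:
        lfp = f["lfp"][...]
        imu = f["imu"][...]
        flags = set()
        if "gps" in f:
            gps_t = f["gps/t"][...]
            gps_enu = f["gps/enu"][...]
        else:
            gps_t = np.empty(0)
            gps_enu = np.empty((0, 3))
            flags.add("gps_gap")
        meta = {k[5:]: f.attrs[k] for k in f.attrs if k.startswith("meta_")}
        rec = MultimodalRecording(
            lfp=lfp, fs_lfp=float(f.attrs["fs_lfp"]),
            imu=imu, fs_imu=float(f.attrs["fs_imu"]),
            gps_t=gps_t, gps_enu=gps_enu, fs_gps=float(f.attrs["fs_gps"]),
            meta=meta, qc_flags=flags,
        )
    rec.validate()
    return rec


def write_recording_csv(rec: MultimodalRecording, directory: str | Path) -> None:
    """CSV triplet export: lfp.csv, imu.csv, gps.csv (+ meta.csv)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    lfp_cols = {f"ch{i}": rec.lfp[i] for i in range(rec.lfp.shape[0])}
    pd.DataFrame({"t": rec.t_lfp, **lfp_cols}).to_csv(
        d / "lfp.csv", index=False, float_format="%.17g")
    imu_cols = ["ax", "ay", "az", "gx", "gy", "gz"]
    pd.DataFrame({"t": rec.t_imu,
                  **{c: rec.imu[:, i] for i, c in enumerate(imu_cols)}}
                 ).to_csv(d / "imu.csv", index=False, float_format="%.17g")
    pd.DataFrame({"t": rec.gps_t, "east": rec.gps_enu[:, 0],
                  "north": rec.gps_enu[:, 1], "up": rec.gps_enu[:, 2]}
                 ).to_csv(d / "gps.csv", index=False, float_format="%.17g")
    pd.DataFrame([{"fs_lfp": rec.fs_lfp, "fs_imu": rec.fs_imu,
                   "fs_gps": rec.fs_gps}]).to_csv(d / "meta.csv", index=False)


def read_recording_csv(directory: str | Path) -> MultimodalRecording:
    d = Path(directory)
    meta = pd.read_csv(d / "meta.csv").iloc[0]
    # round_trip parsing keeps the %.17g export lossless to the last ulp
    kw = {"float_precision": "round_trip"}
    lfp_df = pd.read_csv(d / "lfp.csv", **kw)
    ch_cols = [c for c in lfp_df.columns if c.startswith("ch")]
    imu_df = pd.read_csv(d / "imu.csv", **kw)
    gps_df = pd.read_csv(d / "gps.csv", **kw)
    rec = MultimodalRecording(
        lfp=lfp_df[ch_cols].to_numpy().T,
        fs_lfp=float(meta["fs_lfp"]),
        imu=imu_df[["ax", "ay", "az", "gx", "gy", "gz"]].to_numpy(),
        fs_imu=float(meta["fs_imu"]),
        gps_t=gps_df["t"].to_numpy(),
        gps_enu=gps_df[["east", "north", "up"]].to_numpy(),
        fs_gps=float(meta["fs_gps"]),
    )
    rec.validate()
    return rec
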