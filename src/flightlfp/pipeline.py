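"""End-to-end orchestration: simulate -> fuse -> segment -> denoise ->
spectral -> network -> stats -> decode, with a reproducibility manifest.

Each stage's deterministic outputs are hashed into the manifest so that a
re-run with the same configuration and seed is verifiably identical.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import decode as decode_mod
from . import denoise as denoise_mod
from . import fusion, network, segmentation, spectral, stats
from . import synthio
from .config import PipelineConfig, config_hash
from .io import MultimodalRecording

logger = logging.getLogger("flightlfp")


def _hash_array(*arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        a = np.ascontiguousarray(a)
        h.update(str(a.dtype).encode())
        h.update(str(a.shape).encode())
        h.update(a.tobytes())
    return h.hexdigest()


@dataclass
class PipelineResult:
    """Outputs of one full run plus the reproducibility manifest."""

    recording: MultimodalRecording
    truth: synthio.GroundTruth | None
    nav: fusion.NavSolution
    segments: list
    qc_pass: bool
    qc_flags: set
    denoised: MultimodalRecording | None
    band_profile: pd.DataFrame
    network_table: pd.DataFrame
    psd_trend: stats.TrendFit | None
    clustering_trend: stats.TrendFit | None
    state_comparison: stats.GroupComparison | None
    decoding: decode_mod.DecodingResult | None
    manifest: dict = field(default_factory=dict)


def run_pipeline(cfg: PipelineConfig,
                 recording: MultimodalRecording | None = None
                 ) -> PipelineResult:
    """Execute all stages in order; any stage failure raises with its name.

    When no recording is supplied one is simulated from ``cfg.sim``. The
    manifest records per-stage wall time and content hashes of the
    deterministic outputs, keyed by the configuration hash.
    """
    manifest: dict = {"config_hash": config_hash(cfg), "stages": {}}

    def stage(name):
        t0 = time.perf_counter()

        def done(**hashes):
            manifest["stages"][name] = {
                "seconds": round(time.perf_counter() - t0, 3), **hashes}
            logger.info("stage %s done in %.2fs", name,
                        time.perf_counter() - t0)
        return done

    truth = None
    done = stage("simulate")
    if recording is None:
        recording, truth = synthio.simulate(cfg.sim)
        done(lfp=_hash_array(recording.lfp), imu=_hash_array(recording.imu),
             gps=_hash_array(recording.gps_enu))
    else:
        done(lfp=_hash_array(recording.lfp))

    done = stage("fuse")
    nav = fusion.run_eskf(recording, cfg.eskf)
    done(accel=_hash_array(nav.accel_tangential))

    done = stage("segment")
    segments = segmentation.segment_recording(nav, cfg.window_s, cfg.step_s)
    # statistics and decoding run on non-overlapping windows: overlap leaks
    # shared samples between train/test folds and makes binned-trend CIs
    # anti-conservative
    analysis_segments = segmentation.segment_recording(
        nav, cfg.window_s, cfg.window_s) if cfg.step_s != cfg.window_s \
        else segments
    qc_pass, qc_flags = segmentation.qc_trial(recording, nav, cfg.qc)
    if not qc_pass:
        logger.warning("trial failed QC: %s", sorted(qc_flags))
    done(labels=_hash_array(np.array(
        [s.label for s in segments], dtype="U16")))

    denoised = None
    analysis_lfp = recording.lfp
    if cfg.run_denoise:
        done = stage("denoise")
        denoised, _ = denoise_mod.denoise_recording(recording, cfg.denoise)
        analysis_lfp = denoised.lfp
        done(lfp=_hash_array(denoised.lfp))

    done = stage("spectral")
    band_profile = spectral.band_profile_by_segments(
        analysis_lfp, recording.fs_lfp, analysis_segments, cfg.bands)
    done(table=_hash_array(band_profile["gamma"].to_numpy())
         if len(band_profile) else "empty")

    done = stage("network")
    net_table = network.network_by_state(
        analysis_lfp, recording.fs_lfp, analysis_segments, cfg.network)
    done(table=_hash_array(net_table["mean_clustering"].to_numpy())
         if len(net_table) else "empty")

    done = stage("stats")
    psd_trend = clustering_trend = comparison = None
    if len(band_profile):
        binned = stats.bin_by_acceleration(
            band_profile["gamma"].to_numpy(),
            band_profile["mean_acc"].to_numpy(),
            cfg.bin_range, cfg.bin_width, cfg.min_bin_count)
        if len(binned) >= cfg.trend_order_psd + 2:
            psd_trend = stats.polyfit_trend(binned, cfg.trend_order_psd)
        by_state = [band_profile.loc[band_profile.state == s, "gamma"].to_numpy()
                    for s in decode_mod.STATE_ORDER]
        if all(len(g) >= 3 for g in by_state):
            comparison = stats.compare_groups(*by_state)
    if len(net_table):
        binned = stats.bin_by_acceleration(
            net_table["mean_clustering"].to_numpy(),
            net_table["mean_acc"].to_numpy(),
            cfg.bin_range, cfg.bin_width, cfg.min_bin_count)
        if len(binned) >= cfg.trend_order_clustering + 2:
            clustering_trend = stats.polyfit_trend(
                binned, cfg.trend_order_clustering)
    done(psd_coeffs=_hash_array(psd_trend.coefficients)
         if psd_trend else "none")

    decoding = None
    if cfg.run_decode:
        done = stage("decode")
        X, y = decode_mod.make_dataset(
            analysis_lfp, recording.fs_lfp, analysis_segments,
            cfg.decode_band, cfg.bands, seed=cfg.sim.seed)
        decoding = decode_mod.cross_validate(
            X, y, cfg.decode_model, folds=cfg.decode_folds,
            repeats=cfg.decode_repeats, seed=cfg.sim.seed,
            band=cfg.decode_band)
        done(acc=_hash_array(decoding.fold_accuracies))

    manifest["manifest_hash"] = hashlib.sha256(
        repr(sorted(
            (k, tuple(sorted((kk, vv) for kk, vv in v.items()
                             if kk != "seconds")))
            for k, v in manifest["stages"].items()
        )).encode()).hexdigest()

    return PipelineResult(
        recording=recording, truth=truth, nav=nav, segments=segments,
        qc_pass=qc_pass, qc_flags=qc_flags, denoised=denoised,
        band_profile=band_profile, network_table=net_table,
        psd_trend=psd_trend, clustering_trend=clustering_trend,
        state_comparison=comparison, decoding=decoding, manifest=manifest,
    )
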