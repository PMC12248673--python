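"""Shared fixtures: synthetic recordings reused across the suite.

Heavy artifacts (ESKF runs, VMD denoising) are session-scoped so each is
computed once.
"""

from __future__ import annotations

import numpy as np
import pytest

from flightlfp import SimConfig, simulate
from flightlfp.denoise import denoise_recording
from flightlfp.fusion import nav_from_truth, run_eskf
from flightlfp.segmentation import segment_recording


@pytest.fixture(scope="session")
def flight60():
    """Default-parameter 60 s flight with truth and truth-based segments."""
    cfg = SimConfig(duration_s=60.0, seed=1)
    rec, truth = simulate(cfg)
    segs = segment_recording(nav_from_truth(truth),
                             window_s=1.0, step_s=1.0)
    return {"cfg": cfg, "rec": rec, "truth": truth, "segments": segs}


@pytest.fixture(scope="session")
def flight60_null():
    """60 s flight with both planted neural effects zeroed."""
    cfg = SimConfig(duration_s=60.0, seed=1, gamma_slope=0.0,
                    coherence_quadratic=0.0)
    rec, truth = simulate(cfg)
    segs = segment_recording(nav_from_truth(truth),
                             window_s=1.0, step_s=1.0)
    return {"cfg": cfg, "rec": rec, "truth": truth, "segments": segs}


@pytest.fixture(scope="session")
def flight120():
    """Default-parameter 120 s flight with a full ESKF navigation solution."""
    cfg = SimConfig(duration_s=120.0, seed=1)
    rec, truth = simulate(cfg)
    nav = run_eskf(rec)
    segs = segment_recording(nav, window_s=1.0, step_s=1.0)
    return {"cfg": cfg, "rec": rec, "truth": truth, "nav": nav,
            "segments": segs}


@pytest.fixture(scope="session")
def denoised40():
    """40 s default recording, denoised, with per-channel diagnostics."""
    cfg = SimConfig(duration_s=40.0, seed=1)
    rec, truth = simulate(cfg)
    clean, diags = denoise_recording(rec)
    return {"cfg": cfg, "rec": rec, "truth": truth, "clean": clean,
            "diags": diags}


@pytest.fixture(scope="session")
def denoised40_null():
    """Same flight without any wingbeat artifact in the LFP."""
    cfg = SimConfig(duration_s=40.0, seed=1, artifact_gain=0.0)
    rec, truth = simulate(cfg)
    clean, diags = denoise_recording(rec)
    return {"cfg": cfg, "rec": rec, "truth": truth, "clean": clean,
            "diags": diags}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
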