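"""Band-pass, VMD, DTW and mode-reweighting tests.

The DTW implementation is checked exactly against a full (unbanded)
pure-Python dynamic-programming table on small inputs.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flightlfp.config import DenoiseConfig
from flightlfp.denoise import (bandpass, dtw_distance, dtw_similarity,
                               flag_artifact_modes, reweight_and_reconstruct,
                               vmd_decompose, wingbeat_reference)

FS = 1000.0


def dtw_oracle(a, b):
    """Exhaustive DP table, no band, symmetric steps, |.| cost."""
    n, m = len(a), len(b)
    D = np.full((n + 1, m + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            D[i, j] = abs(a[i - 1] - b[j - 1]) + min(
                D[i - 1, j], D[i, j - 1], D[i - 1, j - 1])
    return D[n, m]


class TestBandpass:
    def test_dc_offset_removed(self):
        x = np.full(4000, 7.3)
        y = bandpass(x, 0.5, 200, FS)
        assert abs(y.mean()) < 1e-6

    def test_in_band_tone_preserved(self):
        t = np.arange(0, 4, 1 / FS)
        x = np.sin(2 * np.pi * 50 * t)
        y = bandpass(x, 0.5, 200, FS)
        assert abs(y[1000:-1000].std() / x[1000:-1000].std() - 1) < 0.05

    def test_drift_attenuated_tone_kept(self):
        t = np.arange(0, 20, 1 / FS)
        drift = 10 * np.sin(2 * np.pi * 0.1 * t)
        tone = np.sin(2 * np.pi * 40 * t)
        y = bandpass(drift + tone, 0.5, 200, FS)
        # residual drift power vs original, mid-section only
        sl = slice(5000, -5000)
        resid = y[sl] - tone[sl]
        assert 10 * np.log10(drift[sl].var() / resid.var()) >= 20
        assert abs(y[sl].std() / tone[sl].std() - 1) < 0.1

    def test_band_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass(np.zeros(100), 0.5, 600, FS)
        with pytest.raises(ValueError):
            bandpass(np.zeros(100), 10.0, 5.0, FS)


class TestVmd:
    def test_two_tone_center_frequencies(self):
        t = np.arange(0, 4, 1 / FS)
        x = np.sin(2 * np.pi * 10 * t) + 0.7 * np.sin(2 * np.pi * 60 * t)
        res = vmd_decompose(x, K=2, fs=FS)
        assert abs(res.center_frequencies[0] - 10) < 1.0
        assert abs(res.center_frequencies[1] - 60) < 1.0

    def test_zero_signal_zero_modes(self):
        res = vmd_decompose(np.zeros(1000), K=3, fs=FS)
        assert np.allclose(res.modes, 0.0)

    def test_reconstruction_error_small(self, rng):
        t = np.arange(0, 4, 1 / FS)
        x = (np.sin(2 * np.pi * 8 * t) + 0.5 * np.sin(2 * np.pi * 45 * t)
             + 0.05 * rng.standard_normal(t.size))
        res = vmd_decompose(x, K=6, fs=FS)
        rel = np.linalg.norm(res.modes.sum(0) - x) / np.linalg.norm(x)
        assert rel < 0.05

    def test_modes_sorted_by_center_frequency(self, rng):
        x = rng.standard_normal(4000)
        res = vmd_decompose(x, K=5, fs=FS)
        assert np.all(np.diff(res.center_frequencies) >= 0)

    def test_deterministic(self, rng):
        x = rng.standard_normal(2000)
        r1 = vmd_decompose(x, K=4, fs=FS)
        r2 = vmd_decompose(x, K=4, fs=FS)
        assert np.array_equal(r1.modes, r2.modes)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            vmd_decompose(np.zeros(1000), K=1)
        with pytest.raises(ValueError):
            vmd_decompose(np.zeros(30), K=10)


class TestDtw:
    def test_identical_series_distance_zero(self):
        a = np.sin(np.linspace(0, 6, 50))
        assert dtw_distance(a, a) == 0.0

    def test_matches_exhaustive_dp_exactly(self, rng):
        for _ in range(20):
            a = rng.standard_normal(rng.integers(5, 21))
            b = rng.standard_normal(rng.integers(5, 21))
            assert dtw_distance(a, b) == pytest.approx(dtw_oracle(a, b),
                                                       abs=1e-12)

    def test_shifted_copy_closer_than_noise(self, rng):
        a = np.sin(2 * np.pi * np.arange(200) / 25)
        shifted = np.roll(a, 2)
        noise = rng.standard_normal(200)
        assert dtw_distance(a, shifted, band=20) < \
            dtw_distance(a, noise, band=20)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-10, 10), min_size=2, max_size=15),
           st.lists(st.floats(-10, 10), min_size=2, max_size=15))
    def test_symmetric_and_nonnegative(self, xs, ys):
        a, b = np.asarray(xs), np.asarray(ys)
        d = dtw_distance(a, b)
        assert d >= 0
        assert d == pytest.approx(dtw_distance(b, a), rel=1e-12)

    def test_constant_series_maximally_dissimilar(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            d = dtw_similarity(np.ones(4000), np.sin(np.arange(4000.0)), FS)
        assert d == float("inf")

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            dtw_distance(np.empty(0), np.ones(3))


class TestReweight:
    def test_no_flagged_modes_passthrough(self, rng):
        x = rng.standard_normal(4000)
        vmd = vmd_decompose(x, K=4, fs=FS)
        ref = rng.standard_normal(4000)  # unrelated reference
        out, vmd = reweight_and_reconstruct(vmd, x, ref, FS)
        if not vmd.dtw_distances.min() == pytest.approx(0):
            assert np.array_equal(out, x) or np.allclose(out, x)

    def test_all_modes_flagged_refuses(self, rng):
        t = np.arange(0, 8, 1 / FS)
        wb = (np.sin(2 * np.pi * 8 * t) + 0.5 * np.sin(2 * np.pi * 16 * t)
              + 0.01 * rng.standard_normal(t.size))
        vmd = vmd_decompose(wb, K=2, fs=FS)
        cfg = DenoiseConfig(mad_factor=-100.0)  # cutoff above all distances
        with pytest.warns(UserWarning, match="refusing"):
            out, vmd = reweight_and_reconstruct(vmd, wb, wb, FS, cfg)
        assert "all_modes_flagged" in vmd.flags
        assert np.array_equal(out, wb)

    def test_flagging_is_low_outlier_rule(self):
        d = np.array([0.05, 0.55, 0.56, 0.60, 0.62, 0.65])
        flags = flag_artifact_modes(d, mad_factor=1.0)
        assert flags[0] and not flags[1:].any()
        assert not flag_artifact_modes(np.full(5, 0.5)).any()
        assert not flag_artifact_modes(np.full(3, np.inf)).any()


class TestOnSyntheticRecording:
    def test_artifact_modes_flagged_and_attenuated(self, denoised40):
        d = denoised40["diags"][0]
        flagged = d.weights < 1.0
        assert 1 <= flagged.sum() <= 4
        # flagged modes sit at the wingbeat fundamental/harmonics
        assert np.all(d.center_frequencies[flagged] < 30.0)
        assert np.all(d.reference_corr[flagged] > 0.1)

    def test_correlation_with_clean_improves(self, denoised40):
        cfg, rec = denoised40["cfg"], denoised40["rec"]
        truth, clean = denoised40["truth"], denoised40["clean"]
        for ch in range(rec.lfp.shape[0]):
            raw = bandpass(rec.lfp[ch], 0.5, 200, cfg.fs_lfp)
            c_raw = np.corrcoef(raw, truth.clean_lfp[ch])[0, 1]
            c_out = np.corrcoef(clean.lfp[ch], truth.clean_lfp[ch])[0, 1]
            assert c_out > c_raw

    def test_energy_bound(self, denoised40):
        cfg, rec = denoised40["cfg"], denoised40["rec"]
        clean = denoised40["clean"]
        for ch in range(rec.lfp.shape[0]):
            raw = bandpass(rec.lfp[ch], 0.5, 200, cfg.fs_lfp)
            assert clean.lfp[ch].var() <= 1.1 * raw.var()

    def test_null_artifact_passthrough(self, denoised40_null):
        cfg, rec = denoised40_null["cfg"], denoised40_null["rec"]
        clean = denoised40_null["clean"]
        for ch in range(rec.lfp.shape[0]):
            raw = bandpass(rec.lfp[ch], 0.5, 200, cfg.fs_lfp)
            rel = np.linalg.norm(clean.lfp[ch] - raw) / np.linalg.norm(raw)
            assert rel < 0.05

    def test_reference_is_zaxis_upsampled(self, denoised40):
        rec = denoised40["rec"]
        ref = wingbeat_reference(rec)
        assert ref.size == rec.lfp.shape[1]
        stride = int(rec.fs_lfp / rec.fs_imu)
        assert np.allclose(ref[::stride], rec.imu[:, 2])
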