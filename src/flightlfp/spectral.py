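"""Spectral characterization of flight LFP.

Welch power spectral density, power proportions over the five canonical
bands (delta/theta/alpha/beta/gamma, with gamma = 30-80 Hz), and a
continuous wavelet transform (analytic Morlet) for time-frequency maps.
Band proportions are the band-integrated power divided by the total power
over the union of the analysis bands, so the five proportions sum to one
per window; by default they are averaged across the 8 channels before any
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from scipy import integrate, signal

from .config import DEFAULT_BANDS

__all__ = ["welch_psd", "band_proportions", "band_profile_by_segments",
           "cwt", "CWTSpec"]


def welch_psd(x: np.ndarray, fs: float, window_s: float = 1.0,
              overlap: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch PSD with Hann windows.

    The integral of the returned density over frequency approximates the
    signal variance (Parseval consistency). Raises when the window is
    longer than the signal or carries fewer than 64 samples.
    """
    x = np.asarray(x, dtype=float)
    nperseg = int(round(window_s * fs))
    if nperseg < 64:
        raise ValueError("window_s * fs must be at least 64 samples")
    if nperseg > x.shape[-1]:
        raise ValueError("window longer than signal")
    noverlap = int(round(overlap * nperseg))
    freqs, psd = signal.welch(x, fs=fs, window="hann", nperseg=nperseg,
                              noverlap=noverlap, detrend="constant",
                              axis=-1)
    return freqs, psd


def band_proportions(freqs: np.ndarray, psd: np.ndarray,
                     bands: dict[str, tuple[float, float]] | None = None
                     ) -> dict[str, float]:
    """Fraction of power per band, relative to the union of all bands.

    Band-integrated power uses trapezoidal integration of the PSD over
    each (non-overlapping) band. Zero total power is undefined and raises.
    """
    bands = bands or DEFAULT_BANDS
    powers = {}
    for name, (lo, hi) in bands.items():
        mask = (freqs >= lo) & (freqs <= hi)
        if mask.sum() < 2:
            powers[name] = 0.0
            continue
        powers[name] = float(integrate.trapezoid(psd[..., mask],
                                                 freqs[mask], axis=-1))
    total = sum(powers.values())
    if total <= 0:
        raise ValueError("zero total power: proportions undefined")
    return {k: v / total for k, v in powers.items()}


def band_profile_by_segments(lfp: np.ndarray, fs: float, segments,
                             bands: dict[str, tuple[float, float]] | None = None,
                             welch_window_s: float = 0.5,
                             channel_average: bool = True) -> pd.DataFrame:
    """Per-window band-power proportions for labelled flight segments.

    For each non-excluded segment, the PSD of the windowed LFP is
    estimated per channel (Welch, 50% overlap) and proportions are
    averaged across channels (or emitted per channel when
    ``channel_average`` is False). Returns a tidy frame with one row per
    window (and channel): window_start, state, mean_acc, one column per
    band.
    """
    bands = bands or DEFAULT_BANDS
    rows = []
    for seg in segments:
        if seg.label == "excluded":
            continue
        i0 = int(round(seg.start_s * fs))
        i1 = int(round(seg.end_s * fs))
        win = lfp[:, i0:i1]
        if win.shape[1] < int(welch_window_s * fs):
            continue
        freqs, psd = welch_psd(win, fs, window_s=welch_window_s)
        props = np.empty((win.shape[0], len(bands)))
        for ch in range(win.shape[0]):
            p = band_proportions(freqs, psd[ch], bands)
            props[ch] = [p[b] for b in bands]
        if channel_average:
            mean_p = props.mean(axis=0)
            rows.append({"window_start": seg.start_s, "state": seg.label,
                         "mean_acc": seg.mean_acceleration,
                         **dict(zip(bands, mean_p))})
        else:
            for ch in range(win.shape[0]):
                rows.append({"window_start": seg.start_s, "state": seg.label,
                             "mean_acc": seg.mean_acceleration, "channel": ch,
                             **dict(zip(bands, props[ch]))})
    return pd.DataFrame(rows)


@dataclass
class CWTSpec:
    """Continuous wavelet transform coefficients and their frequency map."""

    scales: np.ndarray
    translations: np.ndarray     # s
    coefficients: np.ndarray     # (n_scales, n_times), complex
    mother_wavelet: str
    frequencies: np.ndarray      # Hz, monotone decreasing in scale

    @property
    def energy(self) -> np.ndarray:
        return np.abs(self.coefficients) ** 2


def frequencies_to_scales(freqs: np.ndarray, fs: float,
                          wavelet: str = "cmor1.5-1.0") -> np.ndarray:
    fc = pywt.central_frequency(wavelet)
    return fc * fs / np.asarray(freqs, dtype=float)


def cwt(x: np.ndarray, scales: np.ndarray, fs: float,
        wavelet: str = "cmor1.5-1.0") -> CWTSpec:
    """Analytic-Morlet CWT with 1/sqrt(a) normalization.

    Scales mapping to frequencies above Nyquist are dropped with a
    warning.
    """
    import warnings

    scales = np.asarray(scales, dtype=float)
    if np.any(scales <= 0):
        raise ValueError("scales must be positive")
    freqs = pywt.scale2frequency(wavelet, scales) * fs
    keep = freqs <= fs / 2 + 1e-9
    if not keep.all():
        warnings.warn("dropping scales mapping above Nyquist")
        scales, freqs = scales[keep], freqs[keep]
    coeffs, _ = pywt.cwt(np.asarray(x, dtype=float), scales, wavelet,
                         sampling_period=1.0 / fs)
    return CWTSpec(
        scales=scales,
        translations=np.arange(len(x)) / fs,
        coefficients=coeffs,
        mother_wavelet=wavelet,
        frequencies=freqs,
    )
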