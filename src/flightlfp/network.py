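"""Gamma-band coherence networks and clustering-coefficient topology.

Magnitude-squared coherence between channel pairs,

    C_xy(f) = |G_xy(f)|^2 / (G_xx(f) G_yy(f)),

is estimated by Welch-averaged cross-spectra (coherence from a single
segment is identically 1, so several averaging segments per window are
mandatory), band-averaged over 30-80 Hz, binarized by proportional
density thresholding, and summarized by the local clustering coefficient

    CC_i = 2 E_i / (d_i (d_i - 1)),

where d_i is the degree of node i and E_i the number of edges realized
among its neighbours; CC_i = 0 when d_i < 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .config import NetworkConfig

__all__ = ["CoherenceNetwork", "NetworkMetrics", "coherence_spectra",
           "coherence_matrix", "binarize", "clustering", "network_by_state"]


@dataclass
class CoherenceNetwork:
    """Band-averaged channel-by-channel coherence for one analysis window."""

    matrix: np.ndarray            # (n_ch, n_ch), symmetric, unit diagonal
    band: tuple[float, float]
    adjacency: np.ndarray | None = None
    undefined_channels: set = field(default_factory=set)
    window_start: float | None = None
    state: str | None = None


@dataclass
class NetworkMetrics:
    degree: np.ndarray            # d_i per node
    neighbor_edges: np.ndarray    # E_i per node
    clustering_coeff: np.ndarray  # CC_i per node
    mean_clustering: float


def coherence_spectra(x: np.ndarray, fs: float, nperseg: int,
                      noverlap: int | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs magnitude-squared coherence via one STFT per channel.

    Returns (freqs, coh) with coh of shape (n_ch, n_ch, n_freqs). Hann
    windows, 50% overlap by default, matching scipy's Welch conventions.
    """
    x = np.asarray(x, dtype=float)
    if noverlap is None:
        noverlap = nperseg // 2
    freqs, _, Z = signal.stft(x, fs=fs, window="hann", nperseg=nperseg,
                              noverlap=noverlap, boundary=None, padded=False)
    # Z: (n_ch, n_freq, n_seg); Welch cross-spectra = segment-mean of Zx Zy*
    G = np.einsum("afs,bfs->abf", Z, np.conj(Z))
    auto = np.einsum("aaf->af", G).real
    denom = auto[:, None, :] * auto[None, :, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        coh = np.abs(G) ** 2 / denom
    return freqs, coh


def coherence_matrix(lfp_window: np.ndarray, fs: float,
                     band: tuple[float, float] = (30.0, 80.0),
                     subwindow_s: float = 0.5) -> CoherenceNetwork:
    """Band-averaged coherence matrix for one multichannel window.

    Requires enough samples for at least two averaging segments; silent
    (zero-variance) channels are flagged undefined and their rows/columns
    set to NaN (diagonal stays 1 elsewhere).
    """
    x = np.asarray(lfp_window, dtype=float)
    n_ch, n = x.shape
    nperseg = int(round(subwindow_s * fs))
    if n < 2 * nperseg:
        raise ValueError("window too short for coherence averaging")
    freqs, coh = coherence_spectra(x, fs, nperseg)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    mat = coh[:, :, mask].mean(axis=2)

    undefined = {ch for ch in range(n_ch) if x[ch].std() < 1e-12}
    for ch in undefined:
        mat[ch, :] = np.nan
        mat[:, ch] = np.nan
    idx = np.arange(n_ch)
    mat[idx, idx] = 1.0
    mat = 0.5 * (mat + mat.T)
    return CoherenceNetwork(matrix=mat, band=band,
                            undefined_channels=undefined)


def binarize(matrix: np.ndarray, density: float = 0.30,
             rule: str = "proportional",
             threshold: float | None = None) -> np.ndarray:
    """Binary adjacency from a symmetric coherence matrix.

    ``proportional`` keeps the strongest ``density`` fraction of
    off-diagonal pairs (ties at the cutoff are all kept, so the realized
    density can slightly exceed the request); ``absolute`` keeps pairs
    above ``threshold``. NaN entries never form edges.
    """
    m = np.asarray(matrix, dtype=float)
    n = m.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = m[iu]
    if rule == "absolute":
        if threshold is None:
            raise ValueError("absolute rule needs a threshold")
        keep = np.isfinite(vals) & (vals > threshold)
    elif rule == "proportional":
        finite = vals[np.isfinite(vals)]
        k = int(round(density * finite.size))
        if k <= 0 or finite.size == 0:
            keep = np.zeros_like(vals, dtype=bool)
        else:
            cutoff = np.sort(finite)[::-1][min(k, finite.size) - 1]
            # zero coherence never forms an edge, even when the cutoff
            # itself is zero (empty-graph degenerate case)
            keep = np.isfinite(vals) & (vals >= cutoff) & (vals > 0)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    adj = np.zeros((n, n), dtype=int)
    adj[iu[0][keep], iu[1][keep]] = 1
    adj = adj + adj.T
    return adj


def clustering(adjacency: np.ndarray) -> NetworkMetrics:
    """Local clustering coefficients CC_i = 2 E_i / (d_i (d_i - 1)).

    E_i counts edges among the neighbours of node i; nodes of degree < 2
    have CC_i = 0. The network mean is taken over all nodes.
    """
    A = np.asarray(adjacency)
    if not np.array_equal(A, A.T) or np.any(np.diag(A) != 0):
        raise ValueError("adjacency must be symmetric with zero diagonal")
    n = A.shape[0]
    deg = A.sum(axis=1)
    # E_i = number of closed triangles through i / ... = (A^3)_ii / 2
    tri = np.diag(A @ A @ A) / 2.0
    cc = np.zeros(n)
    valid = deg >= 2
    cc[valid] = 2.0 * tri[valid] / (deg[valid] * (deg[valid] - 1))
    return NetworkMetrics(
        degree=deg.astype(int),
        neighbor_edges=tri.astype(int),
        clustering_coeff=cc,
        mean_clustering=float(cc.mean()),
    )


def network_by_state(lfp: np.ndarray, fs: float, segments,
                     cfg: NetworkConfig | None = None) -> pd.DataFrame:
    """One coherence network + clustering metrics per labelled segment.

    Each 1 s analysis window is extended symmetrically to ``cfg.window_s``
    (2 s by default) so that >= 6 Welch segments are averaged. Excluded
    or QC-flagged windows are skipped and counted.
    """
    cfg = cfg or NetworkConfig()
    n_samples = lfp.shape[1]
    half = cfg.window_s / 2.0
    rows = []
    skipped = 0
    for seg in segments:
        if seg.label == "excluded" or seg.qc_flags:
            skipped += 1
            continue
        center = 0.5 * (seg.start_s + seg.end_s)
        i0 = int(round((center - half) * fs))
        i1 = i0 + int(round(cfg.window_s * fs))
        if i0 < 0 or i1 > n_samples:
            skipped += 1
            continue
        net = coherence_matrix(lfp[:, i0:i1], fs, band=cfg.band,
                               subwindow_s=cfg.subwindow_s)
        net.window_start = seg.start_s
        net.state = seg.label
        net.adjacency = binarize(net.matrix, density=cfg.density)
        metrics = clustering(net.adjacency)
        iu = np.triu_indices(net.matrix.shape[0], k=1)
        rows.append({
            "window_start": seg.start_s,
            "state": seg.label,
            "mean_acc": seg.mean_acceleration,
            "mean_coherence": float(np.nanmean(net.matrix[iu])),
            "mean_clustering": metrics.mean_clustering,
            "mean_degree": float(metrics.degree.mean()),
        })
    df = pd.DataFrame(rows)
    df.attrs["skipped_windows"] = skipped
    return df
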