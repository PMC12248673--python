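"""Minimal figure export: coherence heatmaps and binned trend fits."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_coherence_heatmap(matrix, path, title="Gamma-band coherence"):
    fig, ax = plt.subplots(figsize=(4, 3.4))
    im = ax.imshow(matrix, vmin=0, vmax=1, cmap="jet")
    ax.set_xlabel("channel")
    ax.set_ylabel("channel")
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="coherence")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_trend(fit, path, xlabel="acceleration (m/s$^2$)", ylabel="metric"):
    fig, ax = plt.subplots(figsize=(4.2, 3.2))
    ax.scatter(fit.bin_centers, fit.bin_means, s=18, color="tab:blue")
    ax.plot(fit.bin_centers, fit.fitted, color="tab:red")
    ax.plot(fit.bin_centers, fit.ci_band[:, 0], "--", color="tab:red",
            lw=0.8)
    ax.plot(fit.bin_centers, fit.ci_band[:, 1], "--", color="tab:red",
            lw=0.8)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
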