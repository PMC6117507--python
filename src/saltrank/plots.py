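"""Diagnostic plots: NRD curve, class histograms, binned posterior."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_nrd", "plot_histograms", "plot_posterior_bins",
           "plot_line_result"]


def plot_nrd(curve, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.band_centers, curve.nrd, lw=1.2)
    ax.axhline(0, color="gray", lw=0.6)
    ax.set_xlabel("wavelength (nm)")
    ax.set_ylabel("normalized reflectance difference")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_histograms(hc, hs, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    edges = np.linspace(0, 1, hc.b + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    ax.bar(centers, hc.counts, width=1 / hc.b, alpha=0.6,
           label=f"control (m={hc.mean:.2f})")
    ax.bar(centers, hs.counts, width=1 / hs.b, alpha=0.6,
           label=f"salt (m={hs.mean:.2f})")
    ax.set_xlabel("similarity to salt endmember")
    ax.set_ylabel("pixel count")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_posterior_bins(posterior, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    nbins = len(posterior)
    centers = (np.arange(nbins) + 0.5) / nbins
    ax.plot(centers, posterior, "o-", label="P(salt | bin)")
    ax.plot(centers, 1 - np.asarray(posterior), "s--", label="P(control | bin)")
    ax.axhline(0.5, color="gray", lw=0.6)
    ax.set_xlabel("similarity bin")
    ax.set_ylabel("posterior probability")
    ax.set_ylim(-0.05, 1.05)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_line_result(result, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    plot_nrd(result.nrd, out_dir / "nrd.png")
    plot_histograms(result.hist_control, result.hist_salt,
                    out_dir / "histograms.png")
    plot_posterior_bins(result.posterior_bins, out_dir / "posterior_bins.png")
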