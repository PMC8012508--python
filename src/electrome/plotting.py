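"""Report figures: signal panels, histograms, ACF, multiscale entropy,
accuracy bars.

All functions return the matplotlib Figure and optionally save it; saved
files carry no timestamps so that re-running a pipeline with the same
seed reproduces them byte-for-byte.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

from .complexity import ComplexityProfile
from .descriptive import ACFResult, histogram
from .io import Recording
from .spectral import cwt_scalogram, fft_spectrum

__all__ = [
    "plot_histogram",
    "plot_acf",
    "plot_signal_panel",
    "plot_multiscale",
    "plot_accuracy_bars",
    "save_figure",
]


def save_figure(fig, path) -> None:
    meta = {"Date": None} if str(path).endswith(".svg") else None
    fig.savefig(path, dpi=120, metadata=meta)
    plt.close(fig)


def plot_histogram(rec: Recording, bins=101, path=None):
    edges, counts = histogram(rec, bins=bins)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.stairs(counts, edges, fill=True, alpha=0.7)
    ax.set_xlabel("ΔV (µV)")
    ax.set_ylabel("count")
    fig.tight_layout()
    if path is not None:
        save_figure(fig, path)
    return fig


def plot_acf(acfres: ACFResult, path=None):
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(acfres.lags, acfres.acf, lw=1)
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xlabel("lag (samples)")
    ax.set_ylabel("autocorrelation")
    fig.tight_layout()
    if path is not None:
        save_figure(fig, path)
    return fig


def plot_signal_panel(rec: Recording, path=None, scalogram_scales: int = 48):
    """Time series, FFT amplitude spectrum (log-linear), and CWT scalogram."""
    fig, axes = plt.subplots(3, 1, figsize=(7, 8))
    axes[0].plot(rec.times, rec.samples, lw=0.4)
    axes[0].set_xlabel("time (s)")
    axes[0].set_ylabel("ΔV (µV)")

    spec = fft_spectrum(rec)
    axes[1].semilogx(spec.freqs[1:], spec.values[1:], lw=0.6)
    axes[1].set_xlabel("frequency (Hz)")
    axes[1].set_ylabel("amplitude (µV)")

    sg = cwt_scalogram(rec, n_scales=scalogram_scales)
    mesh = axes[2].pcolormesh(
        sg.times, sg.frequencies, sg.magnitude, shading="auto", cmap="viridis"
    )
    axes[2].set_yscale("log")
    axes[2].set_xlabel("time (s)")
    axes[2].set_ylabel("frequency (Hz)")
    fig.colorbar(mesh, ax=axes[2], label="|CWT|")
    fig.tight_layout()
    if path is not None:
        save_figure(fig, path)
    return fig


def plot_multiscale(
    profiles: Mapping[str, Sequence[ComplexityProfile]], path=None
):
    """Mean multiscale-entropy curves per class with standard-error bars."""
    fig, ax = plt.subplots(figsize=(5.5, 4))
    for label, profs in profiles.items():
        vals = np.vstack([p.values for p in profs])
        scales = profs[0].scales
        mean = vals.mean(axis=0)
        se = vals.std(axis=0, ddof=1) / np.sqrt(vals.shape[0]) if vals.shape[0] > 1 else None
        if se is not None:
            ax.errorbar(scales, mean, yerr=se, label=label, capsize=2, lw=1)
        else:
            ax.plot(scales, mean, label=label, lw=1)
    ax.set_xlabel("scale s")
    ax.set_ylabel("entropy (nats)")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        save_figure(fig, path)
    return fig


def plot_accuracy_bars(summary, path=None):
    """Bar chart of mean accuracy per model, one group per comparison."""
    fig, ax = plt.subplots(figsize=(8, 4))
    comparisons = list(summary.index)
    models = list(summary.columns)
    x = np.arange(len(comparisons), dtype=float)
    width = 0.9 / max(len(models), 1)
    for j, model in enumerate(models):
        ax.bar(x + j * width, summary[model].to_numpy(), width=width, label=model)
    ax.set_xticks(x + 0.45 - width / 2)
    ax.set_xticklabels(comparisons, rotation=20, ha="right", fontsize=7)
    ax.set_ylabel("accuracy (%)")
    ax.axhline(50.0, color="k", lw=0.5, ls="--")
    ax.legend(fontsize=6, ncols=2)
    fig.tight_layout()
    if path is not None:
        save_figure(fig, path)
    return fig
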