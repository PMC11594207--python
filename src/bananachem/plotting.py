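"""Diagnostic plots for the wavelength selectors."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .varselect import CarsTrace, FrogTrace  # noqa: E402

__all__ = ["plot_cars_trace", "plot_frog_probabilities"]


def plot_cars_trace(trace: CarsTrace, path: str | Path) -> None:
    """Two-panel CARS diagnostic: retained-variable count and RMSECV vs run,
    with the best run marked."""
    runs = range(1, len(trace.kept_count_per_run) + 1)
    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(6, 5))
    ax1.plot(runs, [len(s) for s in trace.subset_per_run], lw=1)
    ax1.set_ylabel("sampled variables")
    ax2.plot(runs, trace.rmsecv_per_run, lw=1)
    ax2.axvline(trace.best_run + 1, color="tab:red", ls="--", lw=1)
    ax2.set_xlabel("sampling run")
    ax2.set_ylabel(trace.criterion)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_frog_probabilities(trace: FrogTrace, wavelengths, path: str | Path) -> None:
    """Selection probability per band with the threshold line."""
    fig, ax = plt.subplots(figsize=(6, 3.2))
    ax.vlines(wavelengths, 0, trace.selection_probability, lw=1)
    ax.axhline(trace.threshold, color="tab:red", ls="--", lw=1)
    ax.set_xlabel("wavelength (nm)")
    ax.set_ylabel("selection probability")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
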