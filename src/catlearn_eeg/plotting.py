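"""Optional figure output (PNG): learning curves, cluster ERPs, decoding."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .decoding import TimecourseResult


def plot_learning_curves(group_curves: pd.DataFrame, path: str | Path) -> None:
    """Group-mean accuracy per training block, one line per category."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for category, sub in group_curves.groupby("category"):
        ax.errorbar(sub["block"], sub["mean_accuracy"], yerr=sub["se_accuracy"],
                    marker="o", capsize=3, label=category)
    ax.axhline(1 / 3, color="gray", linestyle=":", label="chance")
    ax.set(xlabel="training block", ylabel="accuracy", ylim=(0, 1.02))
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_cluster_waveforms(times_ms: np.ndarray,
                           waveforms: dict[str, np.ndarray],
                           cluster: str, window_ms: tuple[float, float],
                           path: str | Path) -> None:
    """Distinct vs similar cluster-average waveforms with the search window."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for condition in ("distinct", "similar"):
        key = f"{cluster}/{condition}"
        if key in waveforms:
            ax.plot(times_ms, waveforms[key], label=condition)
    ax.axvspan(*window_ms, color="gold", alpha=0.25, label="search window")
    ax.axvline(0, color="k", linewidth=0.8)
    ax.axhline(0, color="k", linewidth=0.8)
    ax.set(xlabel="time (ms)", ylabel="amplitude (µV)", title=cluster)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_timecourse(result: TimecourseResult, path: str | Path) -> None:
    """Decoding accuracy over time with significant bins marked."""
    fig, ax = plt.subplots(figsize=(7, 4))
    centers = result.bin_start_times_ms + result.bin_duration_ms / 2
    ax.plot(centers, result.accuracy, marker=".", label=result.region or "whole scalp")
    sig = np.asarray(result.significant, dtype=bool)
    if sig.any():
        ax.scatter(centers[sig], np.full(sig.sum(), 0.42), marker="D", s=12,
                   color="tab:blue", label="p < %.2f" % result.alpha)
    ax.axhline(0.5, color="gray", linestyle=":")
    ax.set(xlabel="time (ms)", ylabel="classification accuracy", ylim=(0.35, 1.02))
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
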