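"""Trajectory plots: per-replicate grey lines with the across-replicate mean in black."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .engine import RunResult
from .model import N_CASTES


def _plot_band(ax, ticks, trajectories, ylabel, title):
    for traj in trajectories:
        ax.plot(ticks, traj, color="0.7", linewidth=0.6)
    ax.plot(ticks, np.mean(trajectories, axis=0), color="black", linewidth=1.4)
    ax.set_xlabel("tick")
    ax.set_ylabel(ylabel)
    ax.set_title(title)


def plot_liar_counts(results: list[RunResult], out_path, castes=(0, 1, 2)):
    """One panel per caste: liar counts over time for every replicate."""
    ticks = results[0].snapshot_ticks
    fig, axes = plt.subplots(len(castes), 1, figsize=(7, 3 * len(castes)), squeeze=False)
    for ax, caste in zip(axes.ravel(), castes):
        trajs = [r.liar_counts[:, caste] for r in results]
        _plot_band(ax, ticks, trajs, "liar count", f"Caste {caste} liars")
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)


def plot_signal_counts(results: list[RunResult], out_path):
    """3x3 grid: per-(caste, signal) agent counts over time."""
    ticks = results[0].snapshot_ticks
    fig, axes = plt.subplots(N_CASTES, N_CASTES, figsize=(12, 9))
    for caste in range(N_CASTES):
        for signal in range(N_CASTES):
            trajs = [r.counts[:, caste, signal] for r in results]
            _plot_band(
                axes[caste, signal], ticks, trajs, "count",
                f"caste {caste}, signal {signal}",
            )
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)


def plot_mean_resources(results: list[RunResult], out_path):
    """3x3 grid: per-(caste, signal) mean resources over time."""
    ticks = results[0].snapshot_ticks
    fig, axes = plt.subplots(N_CASTES, N_CASTES, figsize=(12, 9))
    for caste in range(N_CASTES):
        for signal in range(N_CASTES):
            trajs = [r.mean_resources[:, caste, signal] for r in results]
            _plot_band(
                axes[caste, signal], ticks, trajs, "mean resources",
                f"caste {caste}, signal {signal}",
            )
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)
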