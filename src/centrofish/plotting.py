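"""Report figures: line-profile traces, time-course recovery, and
peak-position summaries."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

_CHANNEL_COLORS = {"marker": "tab:green", "rna": "tab:purple",
                   "protein": "tab:orange", "dna": "tab:blue"}


def plot_profile(profile, ax=None, channels=None):
    """One centrosome's line profile; x is signed µm (negative = spindle)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    for name in channels or profile.values:
        v = profile.values[name]
        scale = np.nanmax(v) or 1.0
        ax.plot(profile.positions, v / scale,
                color=_CHANNEL_COLORS.get(name), label=name)
    ax.axvline(0, color="k", lw=0.5)
    ax.set_xlabel("position along spindle→astral axis (µm)")
    ax.set_ylabel("normalized intensity")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_timecourse(result, ax=None):
    """Mean ± SD enrichment against washout time, onset marked."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3))
    t = result.timepoints
    mean = [result.mean[x] for x in t]
    sd = [result.sd[x] for x in t]
    ax.errorbar(t, mean, yerr=sd, marker="o", capsize=3,
                color=_CHANNEL_COLORS.get(result.channel, "k"))
    if result.onset is not None:
        ax.axvline(result.onset, ls="--", color="r",
                   label=f"onset {result.onset:g} h")
        ax.legend(frameon=False, fontsize=8)
    ax.set_xlabel("time after washout (h)")
    ax.set_ylabel(f"{result.channel} enrichment (photons)")
    return ax


def plot_peak_positions(records, channels=("rna", "protein", "marker"),
                        ax=None, rng=None):
    """Per-centrosome peak positions by channel (signed µm), jittered."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    rng = rng or np.random.default_rng(0)
    for i, name in enumerate(channels):
        vals = [r.peak_position[name] for r in records
                if name in r.peak_position]
        x = i + rng.uniform(-0.15, 0.15, len(vals))
        ax.scatter(x, vals, s=12, alpha=0.6,
                   color=_CHANNEL_COLORS.get(name))
        ax.hlines(np.mean(vals), i - 0.25, i + 0.25, color="k")
    ax.axhline(0, color="k", lw=0.5, ls=":")
    ax.set_xticks(range(len(channels)), channels)
    ax.set_ylabel("peak position (µm; − spindle, + astral)")
    return ax


def save_report(records, result, out_dir, profiles=None):
    """Write the summary panels (and optional per-centrosome profiles)."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ax = plot_peak_positions(records)
    ax.figure.savefig(out_dir / "peak_positions.png", dpi=150,
                      bbox_inches="tight")
    plt.close(ax.figure)
    if result is not None:
        ax = plot_timecourse(result)
        ax.figure.savefig(out_dir / "timecourse.png", dpi=150,
                          bbox_inches="tight")
        plt.close(ax.figure)
    for i, prof in enumerate(profiles or []):
        ax = plot_profile(prof)
        ax.figure.savefig(out_dir / f"profile_{i:03d}.png", dpi=150,
                          bbox_inches="tight")
        plt.close(ax.figure)
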