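"""Basic plots: accuracy/evidence time courses and scalp maps.

Thin matplotlib wrappers for quick inspection and reports; figures save to
SVG/PNG via the standard ``savefig``.
"""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .decode import DecodingResult
from .montage import ChannelLayout


def plot_timecourse(result: DecodingResult, ax=None, label: str | None = None,
                    color=None):
    """Participant-mean accuracy over time with +/- SEM shading and chance."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.2))
    pt = result.participant_timecourse()
    mean = pt.mean(axis=0)
    sem = pt.std(axis=0, ddof=1) / np.sqrt(pt.shape[0]) if pt.shape[0] > 1 else 0
    t = result.times_ms
    line, = ax.plot(t, mean, label=label or result.scheme.target, color=color)
    ax.fill_between(t, mean - sem, mean + sem, alpha=0.25, color=line.get_color())
    ax.axhline(result.chance, ls="--", lw=0.8, color="gray")
    ax.axvline(0, ls=":", lw=0.8, color="gray")
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("accuracy")
    ax.legend(frameon=False)
    return ax


def plot_evidence(times_ms, bf, threshold: float = 10.0, ax=None, label=None):
    """log10 Bayes-factor time course with the evidence threshold."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.2))
    ax.plot(times_ms, np.log10(bf), label=label)
    ax.axhline(np.log10(threshold), ls="--", lw=0.8, color="gray")
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("log10 BF")
    if label:
        ax.legend(frameon=False)
    return ax


def plot_scalp_map(values, layout: ChannelLayout, ax=None, cmap="RdBu_r",
                   label_channels: bool = False):
    """Per-channel values on the flattened montage (e.g. searchlight means)."""
    values = np.asarray(values, float)
    if values.shape != (len(layout),):
        raise ValueError("one value per channel required")
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    x, y = layout.pos2d[:, 0], layout.pos2d[:, 1]
    vmax = np.abs(values - values.mean()).max() or 1.0
    sc = ax.scatter(x, y, c=values, s=120, cmap=cmap,
                    vmin=values.mean() - vmax, vmax=values.mean() + vmax,
                    edgecolors="k", linewidths=0.5)
    if label_channels:
        for xi, yi, name in zip(x, y, layout.names):
            ax.annotate(name, (xi, yi), fontsize=5, ha="center", va="center")
    ax.set_aspect("equal")
    ax.axis("off")
    plt.colorbar(sc, ax=ax, shrink=0.7)
    return ax
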