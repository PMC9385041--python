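"""Simple curve figures for the two spatial statistics."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_gx(curves, labels=None, mean_sd=None, ax=None):
    """Gx curves (fraction vs distance); optionally a mean +/- SD band."""
    ax = ax or plt.gca()
    for i, c in enumerate(curves):
        ax.plot(c.distance_um, c.fraction, alpha=0.6,
                label=None if labels is None else labels[i])
    if mean_sd is not None:
        x, m, sd = mean_sd
        ax.plot(x, m, "k-", lw=2, label="mean")
        ax.fill_between(x, np.clip(m - sd, 0, 1), np.clip(m + sd, 0, 1),
                        color="k", alpha=0.2)
    ax.set_xlabel("distance to nearest microsphere (μm)")
    ax.set_ylabel("cumulative fraction of hypoxic voxels")
    ax.set_ylim(0, 1.02)
    if labels is not None or mean_sd is not None:
        ax.legend(frameon=False, fontsize=8)
    return ax


def plot_intensity(curves, labels=None, mean_sd=None, ax=None):
    """Hypoxic-intensity curves (fraction vs sphere radius)."""
    ax = ax or plt.gca()
    for i, c in enumerate(curves):
        ax.plot(c.radius_um, c.fraction, alpha=0.6,
                label=None if labels is None else labels[i])
    if mean_sd is not None:
        x, m, sd = mean_sd
        ax.plot(x, m, "k-", lw=2, label="mean")
        ax.fill_between(x, np.clip(m - sd, 0, 1), np.clip(m + sd, 0, 1),
                        color="k", alpha=0.2)
    ax.set_xlabel("radius around microsphere (μm)")
    ax.set_ylabel("hypoxic volume fraction")
    if labels is not None or mean_sd is not None:
        ax.legend(frameon=False, fontsize=8)
    return ax
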