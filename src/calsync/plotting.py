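"""Figures: active-period raster with participation trace, and the
participation-rate histogram of detected events."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .config import H_BOUNDARY, SYNC_THRESHOLD
from .events import NetworkEvent


def plot_raster(raster: np.ndarray, frame_rate_hz: float,
                labels: np.ndarray | None = None,
                path: str | Path | None = None):
    """Active-period plot (cells x time) over its participation-rate trace.

    Marker-positive cells, when labelled, are drawn on top in magenta and
    the rest in black, mirroring the conventional two-colour raster.
    """
    raster = np.asarray(raster, dtype=bool)
    n_cells, n_frames = raster.shape
    t = np.arange(n_frames) / frame_rate_hz

    order = np.arange(n_cells)
    if labels is not None:
        order = np.concatenate([np.flatnonzero(labels),
                                np.flatnonzero(~np.asarray(labels))])

    fig, (ax0, ax1) = plt.subplots(
        2, 1, sharex=True, figsize=(8, 5),
        gridspec_kw={"height_ratios": [3, 1]})
    for row, cell in enumerate(order):
        on = np.flatnonzero(raster[cell])
        if on.size:
            color = ("m" if labels is not None and labels[cell] else "k")
            ax0.plot(t[on], np.full(on.size, row), "|", ms=3, color=color)
    ax0.set_ylabel("cell")
    ax0.set_ylim(-1, n_cells)

    participation = raster.mean(axis=0)
    ax1.plot(t, participation, "k", lw=0.8)
    ax1.axhline(SYNC_THRESHOLD, color="grey", ls=":", lw=0.8)
    ax1.axhline(H_BOUNDARY, color="grey", ls="--", lw=0.8)
    ax1.set_ylabel("participation")
    ax1.set_xlabel("time (s)")
    ax1.set_ylim(0, 1)

    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_participation_histogram(events: list[NetworkEvent],
                                 path: str | Path | None = None,
                                 duration_min: float | None = None):
    """Histogram of per-event participation rates (H/L boundary marked)."""
    rates = [e.participation_rate for e in events]
    fig, ax = plt.subplots(figsize=(4, 3))
    weights = None
    if duration_min:
        weights = np.full(len(rates), 1.0 / duration_min)
    ax.hist(rates, bins=np.arange(0, 1.05, 0.05), color="0.4",
            weights=weights)
    ax.axvline(H_BOUNDARY, color="r", ls="--", lw=0.8)
    ax.axvline(SYNC_THRESHOLD, color="r", ls=":", lw=0.8)
    ax.set_xlabel("participation rate")
    ax.set_ylabel("events/min" if duration_min else "events")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
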