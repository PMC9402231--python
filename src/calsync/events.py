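"""Synchronous network-event detection, H/L classification, and rate stats.

A frame belongs to a synchronous event when more than 20% of identified
cells are simultaneously active; maximal suprathreshold runs (optionally
bridged across single-frame dropouts) are the events.  Each event's
participation rate — the fraction of all cells active on at least one of
its frames — classifies it: H above 60%, L between 20% and 60%, "sub"
below (detected by the frame criterion but too small to enter either
class).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .config import H_BOUNDARY, SYNC_THRESHOLD, DetectionConfig


@dataclass
class NetworkEvent:
    """One contiguous synchronous period (frames are half-open)."""

    onset_frame: int
    offset_frame: int
    participation_rate: float       # union definition (authoritative)
    peak_participation: float       # max simultaneous fraction
    event_class: str | None = None  # "H", "L" or "sub"

    def duration_s(self, frame_rate_hz: float) -> float:
        return (self.offset_frame - self.onset_frame) / frame_rate_hz


@dataclass
class EventRateSummary:
    """Per-recording event frequencies by class."""

    h_per_min: float
    l_per_min: float
    n_events: dict = field(default_factory=dict)
    duration_min: float = 0.0


def participation_timecourse(raster: np.ndarray) -> np.ndarray:
    """Fraction of cells active on each frame."""
    raster = np.asarray(raster, dtype=bool)
    if raster.ndim != 2 or raster.shape[0] == 0:
        raise ValueError("raster must be (n_cells, n_frames) with >= 1 cell")
    return raster.mean(axis=0)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open (start, stop) pairs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.astype(int), [0]))))
    return list(zip(idx[0::2].tolist(), idx[1::2].tolist()))


def _merge_runs(runs: list[tuple[int, int]], merge_gap: int,
                ) -> list[tuple[int, int]]:
    if not runs:
        return []
    merged = [list(runs[0])]
    for start, stop in runs[1:]:
        if start - merged[-1][1] <= merge_gap:
            merged[-1][1] = stop
        else:
            merged.append([start, stop])
    return [tuple(r) for r in merged]


def detect_network_events(participation: np.ndarray,
                          sync_threshold: float = SYNC_THRESHOLD,
                          merge_gap: int = 1,
                          min_duration_frames: int = 1,
                          raster: np.ndarray | None = None,
                          ) -> list[NetworkEvent]:
    """Maximal runs of frames with participation strictly above threshold.

    Runs separated by at most ``merge_gap`` subthreshold frames are merged
    (single-frame dropouts at 4 Hz are sampling artifacts). When the raster
    is supplied, each event's participation rate is the union fraction of
    cells active on any of its frames; otherwise the peak simultaneous
    fraction stands in. Classes are left unset.
    """
    participation = np.asarray(participation, dtype=float)
    if not 0 < sync_threshold < 1:
        raise ValueError("sync_threshold must lie in (0, 1)")
    if participation.ndim != 1:
        raise ValueError("participation must be one value per frame")
    if np.any((participation < 0) | (participation > 1)):
        raise ValueError("participation values must lie in [0, 1]")

    runs = _merge_runs(_runs(participation > sync_threshold), merge_gap)
    events = []
    for start, stop in runs:
        if stop - start < min_duration_frames:
            continue
        peak = float(participation[start:stop].max())
        if raster is not None:
            union = float(np.asarray(raster, dtype=bool)[:, start:stop]
                          .any(axis=1).mean())
        else:
            union = peak
        events.append(NetworkEvent(onset_frame=int(start),
                                   offset_frame=int(stop),
                                   participation_rate=union,
                                   peak_participation=peak))
    return events


def classify_event(participation_rate: float) -> str:
    """H above 60%, L from 20% to 60% inclusive, "sub" below 20%."""
    rate = float(participation_rate)
    if not 0.0 < rate <= 1.0:
        raise ValueError("participation rate must lie in (0, 1]")
    if rate > H_BOUNDARY:
        return "H"
    if rate >= SYNC_THRESHOLD:
        return "L"
    return "sub"


def classify_events(events: list[NetworkEvent]) -> list[NetworkEvent]:
    """Assign a class to every event in place; returns the list."""
    for e in events:
        e.event_class = classify_event(e.participation_rate)
    return events


def event_frequencies(events: list[NetworkEvent], duration_min: float,
                      ) -> EventRateSummary:
    """Events per minute by class; sub-band events count toward neither rate."""
    if duration_min <= 0:
        raise ValueError("duration must be positive")
    counts = {"H": 0, "L": 0, "sub": 0}
    for e in events:
        cls = e.event_class or classify_event(e.participation_rate)
        counts[cls] += 1
    return EventRateSummary(h_per_min=counts["H"] / duration_min,
                            l_per_min=counts["L"] / duration_min,
                            n_events=counts, duration_min=duration_min)


def events_to_frame(events: list[NetworkEvent], frame_rate_hz: float,
                    ) -> pd.DataFrame:
    """Events as a tidy table with onsets/offsets in seconds."""
    rows = [{
        "onset_s": e.onset_frame / frame_rate_hz,
        "offset_s": e.offset_frame / frame_rate_hz,
        "participation_rate": e.participation_rate,
        "peak_participation": e.peak_participation,
        "event_class": e.event_class or classify_event(e.participation_rate),
    } for e in events]
    return pd.DataFrame(rows, columns=["onset_s", "offset_s",
                                       "participation_rate",
                                       "peak_participation", "event_class"])


class NetworkEventDetector(BaseEstimator):
    """Estimator wrapper: raster in, classified events and rates out.

    Fitted attributes: ``participation_`` (per frame), ``events_``
    (classified :class:`NetworkEvent` list) and ``summary_``
    (:class:`EventRateSummary`).
    """

    def __init__(self, sync_threshold: float = SYNC_THRESHOLD,
                 merge_gap: int = 1, min_duration_frames: int = 1):
        self.sync_threshold = sync_threshold
        self.merge_gap = merge_gap
        self.min_duration_frames = min_duration_frames

    @classmethod
    def from_config(cls, cfg: DetectionConfig) -> "NetworkEventDetector":
        return cls(sync_threshold=cfg.sync_threshold, merge_gap=cfg.merge_gap,
                   min_duration_frames=cfg.min_duration_frames)

    def fit(self, X: np.ndarray, y=None, *, frame_rate_hz: float = 4.0,
            ) -> "NetworkEventDetector":
        X = np.asarray(X, dtype=bool)
        self.participation_ = participation_timecourse(X)
        events = detect_network_events(self.participation_,
                                       sync_threshold=self.sync_threshold,
                                       merge_gap=self.merge_gap,
                                       min_duration_frames=self.min_duration_frames,
                                       raster=X)
        self.events_ = classify_events(events)
        duration_min = X.shape[1] / frame_rate_hz / 60.0
        self.summary_ = event_frequencies(self.events_, duration_min)
        self.frame_rate_hz_ = float(frame_rate_hz)
        return self

    def to_frame(self) -> pd.DataFrame:
        if not hasattr(self, "events_"):
            raise RuntimeError("NetworkEventDetector is not fitted")
        return events_to_frame(self.events_, self.frame_rate_hz_)


@dataclass
class GroupComparison:
    """One-way ANOVA plus Tukey-Kramer pairwise comparisons."""

    anova_f: float
    anova_p: float
    group_stats: pd.DataFrame       # mean, sem, n per group
    pairwise: pd.DataFrame          # group_a, group_b, p_value, statistic


def compare_groups(rates: dict[str, np.ndarray]) -> GroupComparison:
    """Compare per-animal event rates across groups.

    One-way ANOVA over all groups followed by the Tukey-Kramer test (the
    unequal-n honest-significant-difference procedure) for every pair.
    """
    if len(rates) < 2:
        raise ValueError("need at least two groups")
    names = list(rates)
    arrays = [np.asarray(rates[g], dtype=float) for g in names]
    for g, a in zip(names, arrays):
        if a.ndim != 1 or len(a) < 2:
            raise ValueError(f"group {g!r} needs >= 2 observations")
        if not np.isfinite(a).all():
            raise ValueError(f"group {g!r} contains non-finite rates")

    f_stat, p_val = stats.f_oneway(*arrays)
    tukey = stats.tukey_hsd(*arrays)

    group_stats = pd.DataFrame({
        "group": names,
        "n": [len(a) for a in arrays],
        "mean": [a.mean() for a in arrays],
        "sem": [a.std(ddof=1) / np.sqrt(len(a)) for a in arrays],
    }).set_index("group")

    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rows.append({"group_a": names[i], "group_b": names[j],
                         "statistic": float(tukey.statistic[i, j]),
                         "p_value": float(tukey.pvalue[i, j])})
    pairwise = pd.DataFrame(rows, columns=["group_a", "group_b", "statistic",
                                           "p_value"])
    return GroupComparison(anova_f=float(f_stat), anova_p=float(p_val),
                           group_stats=group_stats, pairwise=pairwise)
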