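"""Configuration dataclasses shared across the simulation and analysis stages.

Every threshold that affects a result lives here, serialisable to/from JSON so
that a run can be reproduced from its manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

#: ΔF/F activity criterion: a cell counts as active on a frame when its
#: ΔF/F is at least this fraction.
DETECTION_DFF: float = 0.05

#: Fraction of cells that must be simultaneously active for a frame to belong
#: to a synchronous network event (strict ``>``).
SYNC_THRESHOLD: float = 0.20

#: Participation-rate boundary between highly synchronous (H) and less
#: correlated (L) events (strict ``>`` for H).
H_BOUNDARY: float = 0.60


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass
class SimulationConfig:
    """Conditions for one synthetic spontaneous-activity recording.

    Defaults reproduce the control condition: 10-minute sessions imaged at
    4 Hz, ~100 identified layer-2/3 cells, H events at 1.70/min with >60%
    of cells participating and L events at 2.16/min with 20-60%
    participating.
    """

    n_cells: int = 100
    duration_s: float = 600.0
    frame_rate_hz: float = 4.0
    rate_h: float = 1.70            # H events per minute
    rate_l: float = 2.16            # L events per minute
    participation_h: tuple[float, float] = (0.65, 0.95)
    participation_l: tuple[float, float] = (0.25, 0.55)
    kernel_rise_s: float = 0.2
    kernel_decay_s: float = 1.0
    transient_amplitude: float = 0.15   # peak ΔF/F of a transient (3x criterion)
    event_duration_s: tuple[float, float] = (0.5, 2.0)
    min_gap_s: float = 1.0          # enforced gap between event support windows
    contamination_r: float = 0.7
    noise_sd: float = 0.02          # per-frame cell noise, ΔF/F units
    drift_amplitude: float = 0.05   # slow shared drift, ΔF/F units
    drift_period_s: float = 150.0
    baseline_f0: float = 100.0      # arbitrary fluorescence units
    labeled_fraction: float = 0.3   # fraction of marker-positive (FP635+) cells
    seed: int = 0

    def validate(self) -> None:
        _check(self.n_cells >= 5, "n_cells must be >= 5")
        _check(self.duration_s > 0 and self.frame_rate_hz > 0,
               "duration and frame rate must be positive")
        n = self.duration_s * self.frame_rate_hz
        _check(abs(n - round(n)) < 1e-9,
               "duration_s x frame_rate_hz must be a whole number of frames")
        _check(self.rate_h >= 0 and self.rate_l >= 0, "event rates must be >= 0")
        lo, hi = self.participation_h
        _check(H_BOUNDARY < lo <= hi <= 1.0,
               f"participation_h band must lie in ({H_BOUNDARY}, 1.0]")
        lo, hi = self.participation_l
        _check(SYNC_THRESHOLD <= lo <= hi <= H_BOUNDARY,
               f"participation_l band must lie in [{SYNC_THRESHOLD}, {H_BOUNDARY}]")
        _check(0.0 <= self.contamination_r < 1.0, "contamination_r must be in [0, 1)")
        _check(self.noise_sd >= 0 and self.drift_amplitude >= 0,
               "noise and drift amplitudes must be >= 0")
        _check(self.kernel_rise_s > 0 and self.kernel_decay_s > self.kernel_rise_s,
               "kernel decay must exceed rise; both positive")
        _check(self.transient_amplitude > DETECTION_DFF,
               "transient amplitude must exceed the detection criterion")
        d0, d1 = self.event_duration_s
        _check(0 < d0 <= d1, "event_duration_s must be an increasing positive pair")
        _check(0.0 <= self.labeled_fraction <= 1.0, "labeled_fraction in [0, 1]")
        _check(self.baseline_f0 > 0, "baseline_f0 must be positive")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate_hz))


#: Event-rate presets (H/min, L/min) for the three experimental groups:
#: unmanipulated controls, constitutive activity suppression (Kir2.1 ON),
#: and suppression released from P6 onward (Dox from P6).
SCENARIO_RATES: dict[str, tuple[float, float]] = {
    "control": (1.70, 2.16),
    "kir_on": (0.21, 0.62),
    "kir_off_p6": (0.66, 2.01),
}


def scenario_config(name: str, **overrides: Any) -> SimulationConfig:
    """A :class:`SimulationConfig` with the event rates of a named group."""
    if name not in SCENARIO_RATES:
        raise KeyError(f"unknown scenario {name!r}; one of {sorted(SCENARIO_RATES)}")
    rate_h, rate_l = SCENARIO_RATES[name]
    return SimulationConfig(rate_h=rate_h, rate_l=rate_l, **overrides)


@dataclass
class FilterSettings:
    """Temporal filters applied to raw fluorescence traces.

    ``highcut_period_s`` is the period of the Butterworth low-pass -3 dB
    cutoff (1 s -> 1 Hz); ``lowcut_period_s`` parameterises the Gaussian
    smoother whose output is subtracted to remove slow baseline (sigma =
    period / 2*pi, placing its -3 dB point near 1/period Hz).
    """

    highcut_period_s: float = 1.0
    butterworth_order: int = 10
    lowcut_period_s: float = 120.0

    def validate(self) -> None:
        _check(self.butterworth_order >= 1, "butterworth_order must be >= 1")
        _check(0 < self.highcut_period_s < self.lowcut_period_s,
               "highcut period must be positive and below the lowcut period")


@dataclass
class ProcessingConfig:
    """Trace preprocessing: filtering, neuropil correction, ΔF/F, activity."""

    filters: FilterSettings = field(default_factory=FilterSettings)
    baseline_quantile: float = 0.5
    baseline_window_s: float = 1.0
    min_baseline_frames: int = 40
    f0_method: str = "rolling_percentile"   # or "global_percentile"
    f0_percentile: float = 10.0
    f0_window_s: float = 60.0
    f0_stride: int = 8
    dff_threshold: float = DETECTION_DFF

    def validate(self) -> None:
        self.filters.validate()
        _check(0 < self.baseline_quantile < 1, "baseline_quantile in (0, 1)")
        _check(self.min_baseline_frames >= 2, "min_baseline_frames >= 2")
        _check(0 < self.f0_percentile < 100, "f0_percentile in (0, 100)")
        _check(self.f0_method in ("rolling_percentile", "global_percentile"),
               "unknown f0_method")
        _check(self.dff_threshold > 0, "dff_threshold must be positive")


@dataclass
class DetectionConfig:
    """Synchronous-event detection over the binary activity raster."""

    sync_threshold: float = SYNC_THRESHOLD
    merge_gap: int = 1              # frames; runs this close are one event
    min_duration_frames: int = 1

    def validate(self) -> None:
        _check(0 < self.sync_threshold < 1, "sync_threshold in (0, 1)")
        _check(self.merge_gap >= 0, "merge_gap >= 0")
        _check(self.min_duration_frames >= 1, "min_duration_frames >= 1")


@dataclass
class SectionSpec:
    """Layout of a synthetic coronal-section image for densitometry.

    The left half of the image is the projection side (callosal axon
    termination zone); the right half is the electroporated side. Bands are
    (top_row, bottom_row, mean_intensity) half-open row intervals.
    """

    image_size: tuple[int, int] = (1024, 1024)
    layer_bands: dict[str, tuple[int, int, float]] = field(
        default_factory=lambda: {
            "layers1_3": (80, 280, 60.0),
            "layer5": (420, 540, 45.0),
            "wm": (700, 800, 80.0),
        })
    electroporated_wm_intensity: float = 120.0
    background_intensity: float = 10.0
    gain: float = 1.0
    noise_sd: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        h, w = self.image_size
        _check(h > 0 and w > 0, "image_size must be positive")
        _check(self.background_intensity >= 0, "background intensity >= 0")
        _check(self.electroporated_wm_intensity >= 0, "wm intensity >= 0")
        _check(self.gain > 0, "gain must be positive")
        _check(self.noise_sd >= 0, "noise_sd >= 0")
        prev_bottom = -1
        for name, (top, bottom, inten) in sorted(self.layer_bands.items(),
                                                 key=lambda kv: kv[1][0]):
            _check(0 <= top < bottom <= h, f"band {name!r} outside image rows")
            _check(inten >= 0, f"band {name!r} intensity must be >= 0")
            _check(top > prev_bottom, f"band {name!r} overlaps the previous band")
            prev_bottom = bottom - 1


@dataclass
class RunConfig:
    """One reproducible multi-group experiment (simulate → process → detect)."""

    groups: dict[str, SimulationConfig] = field(
        default_factory=lambda: {"control": SimulationConfig()})
    n_recordings: int = 5
    processing: ProcessingConfig = field(default_factory=ProcessingConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    seed: int = 0

    def validate(self) -> None:
        _check(len(self.groups) >= 1, "at least one group")
        _check(self.n_recordings >= 1, "n_recordings >= 1")
        for cfg in self.groups.values():
            cfg.validate()
        self.processing.validate()
        self.detection.validate()


# ---------------------------------------------------------------------------
# JSON (de)serialisation

_TUPLE_FIELDS = {"participation_h", "participation_l", "event_duration_s",
                 "image_size"}


def to_dict(cfg: Any) -> dict:
    return dataclasses.asdict(cfg)


def _from_dict(cls, data: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if f.name == "filters" and isinstance(v, dict):
            v = FilterSettings(**v)
        elif f.name == "layer_bands" and isinstance(v, dict):
            v = {k: tuple(b) for k, b in v.items()}
        elif f.name in _TUPLE_FIELDS and isinstance(v, (list, tuple)):
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


def simulation_config_from_dict(d: dict) -> SimulationConfig:
    return _from_dict(SimulationConfig, d)


def processing_config_from_dict(d: dict) -> ProcessingConfig:
    return _from_dict(ProcessingConfig, d)


def detection_config_from_dict(d: dict) -> DetectionConfig:
    return _from_dict(DetectionConfig, d)


def section_spec_from_dict(d: dict) -> SectionSpec:
    return _from_dict(SectionSpec, d)


def run_config_from_dict(d: dict) -> RunConfig:
    groups = {name: simulation_config_from_dict(g)
              for name, g in d.get("groups", {}).items()}
    cfg = RunConfig(
        groups=groups or {"control": SimulationConfig()},
        n_recordings=int(d.get("n_recordings", 5)),
        processing=processing_config_from_dict(d.get("processing", {})),
        detection=detection_config_from_dict(d.get("detection", {})),
        seed=int(d.get("seed", 0)),
    )
    return cfg


def load_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def dump_json(obj: Any, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o: Any):
    import numpy as np

    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")
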