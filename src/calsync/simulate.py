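"""Ground-truth-labelled synthetic recordings and histology sections.

The recording generator emulates spontaneous network activity in the
developing visual cortex as seen through bulk-loaded calcium imaging:
Poisson-timed network events of two classes (H: >60% of cells participate;
L: 20-60%), calcium-kernel-shaped transients, shared out-of-focus neuropil
contamination with a known ratio ``r``, slow drift carried by the neuropil,
and per-frame shot noise.  The hidden schedule is returned as
:class:`GroundTruth` so that every downstream stage can be scored against
what was actually generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import DETECTION_DFF, SectionSpec, SimulationConfig

#: Entry margin on the ΔF/F criterion when recording an event's ground-truth
#: active window: frames where the noise-free transient is >= 1.2x the 5%
#: criterion. The margin absorbs filter droop and baseline-estimation error
#: in the analysis pipeline without touching the criterion itself.
ACTIVE_MARGIN = 1.2

#: Support windows (transient >= 0.6x criterion) of distinct events must be
#: separated by ``min_gap_s``; this keeps decay tails from bridging events.
SUPPORT_MARGIN = 0.6


@dataclass
class Recording:
    """Apparent per-cell and per-cell-surround fluorescence traces."""

    cell_traces: np.ndarray        # (n_cells, n_frames), arbitrary units
    surround_traces: np.ndarray    # (n_cells, n_frames)
    frame_rate_hz: float
    labels: np.ndarray | None = None   # marker-positive flags (e.g. FP635+)

    def __post_init__(self) -> None:
        self.cell_traces = np.asarray(self.cell_traces, dtype=float)
        self.surround_traces = np.asarray(self.surround_traces, dtype=float)
        if self.cell_traces.shape != self.surround_traces.shape:
            raise ValueError("cell and surround traces must share shape")
        if not (np.isfinite(self.cell_traces).all()
                and np.isfinite(self.surround_traces).all()):
            raise ValueError("traces must be finite")

    @property
    def n_cells(self) -> int:
        return self.cell_traces.shape[0]

    @property
    def n_frames(self) -> int:
        return self.cell_traces.shape[1]

    @property
    def duration_min(self) -> float:
        return self.n_frames / self.frame_rate_hz / 60.0


@dataclass
class TrueEvent:
    """One scheduled network event and its ground-truth active window."""

    onset_frame: int               # first frame of the suprathreshold window
    offset_frame: int              # half-open end of that window
    drive_onset_s: float           # scheduled drive interval (boxcar input)
    drive_offset_s: float
    event_class: str               # "H" or "L"
    participants: np.ndarray       # cell indices
    participation: float           # |participants| / n_cells

    @property
    def n_participants(self) -> int:
        return int(len(self.participants))


@dataclass
class GroundTruth:
    """Hidden state of one simulated recording."""

    events: list[TrueEvent]
    true_r: np.ndarray                 # per-cell contamination ratio
    shared_neuropil_trace: np.ndarray  # fluorescence units
    true_cell_traces: np.ndarray       # noise/contamination-free cell traces
    seed: int

    def count(self, event_class: str) -> int:
        return sum(e.event_class == event_class for e in self.events)


def transient_step_response(t: np.ndarray, duration_s: float,
                            rise_s: float, decay_s: float) -> np.ndarray:
    """Difference-of-exponentials kernel convolved with a unit boxcar.

    The kernel g(s) = exp(-s/tau_d) - exp(-s/tau_r) is driven by a boxcar of
    length ``duration_s`` starting at t=0; the closed-form response rises over
    the drive interval and decays with tau_d afterwards. Peak-normalised.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)

    def ramp(tt: np.ndarray, tau: float) -> np.ndarray:
        # integral of exp(-s/tau) over the overlap of [0, duration] with [0, tt]
        r = np.zeros_like(tt)
        rising = (tt >= 0) & (tt < duration_s)
        r[rising] = tau * (1.0 - np.exp(-tt[rising] / tau))
        after = tt >= duration_s
        r[after] = tau * (np.exp(duration_s / tau) - 1.0) * np.exp(-tt[after] / tau)
        return r

    out = ramp(t, decay_s) - ramp(t, rise_s)
    # The true peak falls shortly after the drive offset (where the kernel's
    # leading and trailing edges balance); locate it on a fine grid.
    tt = np.linspace(0.0, duration_s + 3.0 * decay_s, 4096)
    peak = float(np.max(ramp(tt, decay_s) - ramp(tt, rise_s)))
    return out / peak


def _event_template(duration_s: float, cfg: SimulationConfig,
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Frame-sampled transient for one event plus its threshold windows.

    Returns (values, active_window, support_window) where values[k] is the
    ΔF/F contribution k frames after the drive onset frame, and the windows
    are boolean masks over those frames.
    """
    dt = 1.0 / cfg.frame_rate_hz
    tail_s = duration_s + 8.0 * cfg.kernel_decay_s
    n = int(np.ceil(tail_s / dt)) + 1
    t = np.arange(n) * dt
    vals = cfg.transient_amplitude * transient_step_response(
        t, duration_s, cfg.kernel_rise_s, cfg.kernel_decay_s)
    active = vals >= ACTIVE_MARGIN * DETECTION_DFF
    support = vals >= SUPPORT_MARGIN * DETECTION_DFF
    return vals, active, support


def _window_bounds(mask: np.ndarray, base: int) -> tuple[int, int]:
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError("transient never crosses the detection criterion; "
                         "increase transient_amplitude")
    return base + int(idx[0]), base + int(idx[-1]) + 1


def _draw_participants(rng: np.random.Generator, cfg: SimulationConfig,
                       band: tuple[float, float]) -> tuple[np.ndarray, float]:
    lo, hi = band
    p = rng.uniform(lo, hi)
    k = int(round(p * cfg.n_cells))
    k = int(np.clip(k, int(np.ceil(lo * cfg.n_cells)),
                    int(np.floor(hi * cfg.n_cells))))
    if not (lo <= k / cfg.n_cells <= hi):
        raise ValueError(
            f"participation band {band} admits no whole number of cells "
            f"out of {cfg.n_cells}")
    cells = rng.choice(cfg.n_cells, size=k, replace=False)
    return np.sort(cells), k / cfg.n_cells


def simulate_recording(config: SimulationConfig,
                       ) -> tuple[Recording, GroundTruth]:
    """Simulate one session; returns the recording and its hidden schedule.

    Event counts per class are Poisson with mean rate x duration; onsets are
    placed uniformly at random and re-drawn (rejection) whenever two events'
    support windows would come closer than ``min_gap_s``, so ground-truth
    classes stay unambiguous.  In the noise-free limit the printed neuropil
    correction inverts the construction exactly.
    """
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_frames = cfg.n_frames
    dt = 1.0 / cfg.frame_rate_hz

    duration_min = cfg.duration_s / 60.0
    n_h = rng.poisson(cfg.rate_h * duration_min)
    n_l = rng.poisson(cfg.rate_l * duration_min)

    mean_dur = 0.5 * sum(cfg.event_duration_s)
    tail = 8.0 * cfg.kernel_decay_s
    expected_busy = ((cfg.rate_h + cfg.rate_l) * duration_min
                     * (mean_dur + tail + cfg.min_gap_s))
    if expected_busy > 0.9 * cfg.duration_s:
        raise ValueError("event rates too high for the recording duration: "
                         "expected event occupancy exceeds the frame budget")

    classes = ["H"] * n_h + ["L"] * n_l
    rng.shuffle(classes)

    gap_frames = int(np.ceil(cfg.min_gap_s / dt))
    placed: list[dict] = []
    occupied: list[tuple[int, int]] = []   # support windows, frames

    for cls in classes:
        band = cfg.participation_h if cls == "H" else cfg.participation_l
        participants, frac = _draw_participants(rng, cfg, band)
        for _ in range(5000):
            dur = rng.uniform(*cfg.event_duration_s)
            vals, active, support = _event_template(dur, cfg)
            latest = n_frames - len(vals)
            if latest <= 0:
                raise ValueError("recording too short for a single event")
            onset_frame = int(rng.integers(0, latest))
            s0, s1 = _window_bounds(support, onset_frame)
            if all(s1 + gap_frames <= o0 or o1 + gap_frames <= s0
                   for o0, o1 in occupied):
                a0, a1 = _window_bounds(active, onset_frame)
                occupied.append((s0, s1))
                placed.append(dict(cls=cls, participants=participants,
                                   frac=frac, onset_frame=onset_frame,
                                   vals=vals, dur=dur,
                                   active=(a0, a1)))
                break
        else:
            raise ValueError("could not place events without overlap; "
                             "rates too high for the recording duration")

    placed.sort(key=lambda e: e["onset_frame"])

    # --- assemble traces -------------------------------------------------
    dff = np.zeros((cfg.n_cells, n_frames))
    events: list[TrueEvent] = []
    for e in placed:
        k0 = e["onset_frame"]
        k1 = min(k0 + len(e["vals"]), n_frames)
        dff[np.ix_(e["participants"], np.arange(k0, k1))] += e["vals"][:k1 - k0]
        a0, a1 = e["active"]
        events.append(TrueEvent(
            onset_frame=a0, offset_frame=min(a1, n_frames),
            drive_onset_s=k0 * dt, drive_offset_s=k0 * dt + e["dur"],
            event_class=e["cls"], participants=e["participants"],
            participation=e["frac"]))

    f0 = cfg.baseline_f0
    true_cell = f0 * (1.0 + dff)

    t = np.arange(n_frames) * dt
    phase = rng.uniform(0.0, 2.0 * np.pi)
    drift = cfg.drift_amplitude * np.sin(2.0 * np.pi * t / cfg.drift_period_s
                                         + phase)
    # Shared neuropil: spatial average of all cells' transients (event-locked
    # out-of-focus signal) riding the slow drift.
    neuropil = f0 * (1.0 + dff.mean(axis=0) + drift)

    true_r = np.full(cfg.n_cells, cfg.contamination_r)
    # Surround averages ~4x the pixels of a soma -> half the per-frame noise.
    surround = neuropil + f0 * (cfg.noise_sd / 2.0) * rng.standard_normal(
        (cfg.n_cells, n_frames))
    apparent = (true_cell
                + true_r[:, None] * (neuropil - neuropil.mean())
                + f0 * cfg.noise_sd * rng.standard_normal((cfg.n_cells,
                                                           n_frames)))

    labels = rng.random(cfg.n_cells) < cfg.labeled_fraction

    rec = Recording(cell_traces=apparent, surround_traces=surround,
                    frame_rate_hz=cfg.frame_rate_hz, labels=labels)
    truth = GroundTruth(events=events, true_r=true_r,
                        shared_neuropil_trace=neuropil,
                        true_cell_traces=true_cell, seed=cfg.seed)
    return rec, truth


# ---------------------------------------------------------------------------
# Histology fixtures


@dataclass
class SectionGeometry:
    """Measurement boxes matching a simulated section (half-open row/col)."""

    layer13_proj: tuple[int, int, int, int]
    wm_proj: tuple[int, int, int, int]
    background_proj: tuple[int, int, int, int]
    wm_electro: tuple[int, int, int, int]
    background_electro: tuple[int, int, int, int]
    bands: dict[str, tuple[int, int, float]] = field(default_factory=dict)


def simulate_section(spec: SectionSpec) -> tuple[np.ndarray, SectionGeometry]:
    """Layered axon-density image: projection side left, electroporated right.

    The image is ``gain * (structure + noise)`` so that a gain change scales
    every pixel identically (emulating detector gain / laser power).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    half = w // 2

    base = np.full((h, w), float(spec.background_intensity))
    for top, bottom, inten in spec.layer_bands.values():
        base[top:bottom, :half] = inten
    wm_top, wm_bottom, _ = spec.layer_bands["wm"]
    base[wm_top:wm_bottom, half:] = spec.electroporated_wm_intensity

    noise = spec.noise_sd * rng.standard_normal((h, w))
    image = spec.gain * (base + noise)

    l13_top, l13_bottom, _ = spec.layer_bands["layers1_3"]
    bg_bottom = wm_top - 20
    bg_top = max(bg_bottom - 100, 0)
    # Background boxes sit in unlabeled cortex adjacent to the WM band.
    for name, (t0, b0, _i) in spec.layer_bands.items():
        if name != "wm" and t0 <= bg_top < b0:
            bg_top, bg_bottom = b0 + 5, min(b0 + 105, wm_top - 5)

    def cols(side: str) -> tuple[int, int]:
        if side == "proj":
            return int(0.1 * half), int(0.9 * half)
        return half + int(0.1 * half), half + int(0.9 * half)

    c0, c1 = cols("proj")
    e0, e1 = cols("electro")
    geom = SectionGeometry(
        layer13_proj=(l13_top, l13_bottom, c0, c1),
        wm_proj=(wm_top, wm_bottom, c0, c1),
        background_proj=(bg_top, bg_bottom, c0, c1),
        wm_electro=(wm_top, wm_bottom, e0, e1),
        background_electro=(bg_top, bg_bottom, e0, e1),
        bands=dict(spec.layer_bands),
    )
    return image, geom


def simulate_expression_cells(n_cells: int = 12,
                              ratios: np.ndarray | None = None,
                              red_level: float = 40.0,
                              background: float = 2.0,
                              noise_sd: float = 1.0,
                              cell_px: int = 16,
                              seed: int = 0,
                              ) -> tuple[np.ndarray, list[tuple[int, int, int, int]],
                                         np.ndarray]:
    """Two-channel image of cells with known green/red intensity ratios.

    Returns (image[2, H, W], per-cell boxes, true ratios). Fixture for
    expression-ratio quantification of co-electroporated reporters.
    """
    rng = np.random.default_rng(seed)
    if ratios is None:
        ratios = rng.uniform(0.1, 1.2, size=n_cells)
    ratios = np.asarray(ratios, dtype=float)
    n_cells = len(ratios)

    per_row = int(np.ceil(np.sqrt(n_cells)))
    pitch = cell_px * 3
    side = per_row * pitch + pitch
    img = np.full((2, side, side), background)
    boxes = []
    for i, ratio in enumerate(ratios):
        r0 = pitch // 2 + (i // per_row) * pitch
        c0 = pitch // 2 + (i % per_row) * pitch
        img[1, r0:r0 + cell_px, c0:c0 + cell_px] = red_level
        img[0, r0:r0 + cell_px, c0:c0 + cell_px] = ratio * red_level
        boxes.append((r0, r0 + cell_px, c0, c0 + cell_px))
    img += noise_sd * rng.standard_normal(img.shape)
    return img, boxes, ratios
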