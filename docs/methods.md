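# Methods

This note documents the models, parameter choices and numerical decisions
behind `calsync`, in the order data flows through the package.

## Synthetic recordings

`simulate_recording` emulates a bulk-loaded calcium-imaging session in
developing visual cortex: `n_cells` somata (default 100) imaged at
`frame_rate_hz` (default 4 Hz) for `duration_s` (default 600 s).

**Event schedule.** Network events of two classes arrive as independent
Poisson processes: H events at `rate_h` (default 1.70/min) with a per-event
participation fraction drawn uniformly from `participation_h` (default
0.65–0.95), and L events at `rate_l` (default 2.16/min) from
`participation_l` (default 0.25–0.55). The default rates are the control
condition; `scenario_config` also provides the activity-suppressed
("kir_on": 0.21/0.62) and suppression-released ("kir_off_p6": 0.66/2.01)
conditions. Per-class counts are drawn first (so their means are exactly
rate × duration) and onsets are placed uniformly with rejection: a redraw
whenever two events' *support windows* (see below) would come within
`min_gap_s` (default 1 s). Rejection rather than merging keeps ground-truth
classes unambiguous for recovery tests. Event drive durations are uniform
on `event_duration_s` (default 0.5–2 s); the literature does not constrain
event durations, so this range is a free, exposed choice.

**Transients.** Each participating cell receives the same transient: a
difference-of-exponentials kernel (rise 0.2 s, decay 1.0 s) driven by a
boxcar spanning the event's drive interval, peak-normalised to
`transient_amplitude` (default ΔF/F = 0.15, three times the 5% activity
criterion, so detection is unambiguous at default noise). A boxcar drive —
rather than a single onset impulse — makes the scheduled duration visible
in the trace and lets long events stay suprathreshold throughout.

**Ground-truth windows.** An event's recorded `(onset_frame, offset_frame)`
is the span where its noise-free transient is ≥ 1.2 × the 5% criterion.
The 20% entry margin absorbs the small peak attenuation of the analysis
filters and rolling-baseline error, so "ground-truth active frames" are
frames the ideal pipeline must mark active. The wider support window
(≥ 0.6 × criterion) is what the placement gap is enforced on, so calcium
decay tails cannot bridge two events into one detected run. Both margins
derive from the kernel decay constant (the tail from 0.15 to 0.05 lasts
ln 3 × 1 s ≈ 1.1 s).

**Contamination and noise.** The shared neuropil trace is the spatial
average of all cells' transients (out-of-focus contamination is
event-locked — the reason rigid correction matters here) riding a slow
sinusoid (`drift_amplitude` 0.05 ΔF/F, `drift_period_s` 150 s, random
phase). The apparent cell trace is

    F_apparent = F_true + r · (neuropil − mean(neuropil)) + f0 · ε_cell

with `r = contamination_r` (default 0.7) and per-frame Gaussian noise of
standard deviation `noise_sd` (default 0.02 ΔF/F — plausible for
soma-averaged bulk-dye imaging at 4 Hz). The surround trace is the neuropil
plus independent noise at `noise_sd / 2`, since an annulus averages roughly
four times the pixels of a soma. Drift deliberately enters *only* through
the neuropil term, so with `noise_sd = 0` the printed correction formula
inverts the construction exactly — the basis of the round-trip tests.

**What the generator does not emulate.** Per-cell amplitude and kernel
heterogeneity, correlated (non-shared) neuropil structure, motion artifacts,
photobleaching, cell-size-dependent noise, and any spatial layout. Passing
recovery tests therefore demonstrate correctness of the analysis under the
stated statistical model, not robustness to every property of real data.

## Trace processing

**Filters.** "Cutoff 1 s" is mapped to a −3 dB Butterworth low-pass at
1 Hz (order 10, applied forward–backward with `sosfiltfilt`, so the
effective attenuation doubles and the phase is exactly zero — event onsets
are not shifted). "Cutoff 2 min" is mapped to a Gaussian smoother with
σ = 120 s / 2π ≈ 19.1 s whose output is subtracted; that places the
smoother's −3 dB point near 1/120 Hz. Both mappings are configurable.

**Quiet-frame mask.** The activity score is a 1 s moving average of the
|band-passed| trace; a frame is "quiet" when both the cell's and its
surround's scores are at or below their `baseline_quantile` (default
median). Rectification keeps the mask indifferent to the phase of residual
slow drift, which would otherwise bias the mask toward drift troughs and
attenuate the fitted ratio. A minimum of 40 quiet frames is enforced. A
relative slack of 1e−9 × the trace scale breaks numerical ties so an
event-free recording yields an all-frames mask.

**Contamination ratio.** `r` is the closed-form least-squares slope of the
mean-centred cell on the mean-centred surround over quiet frames, computed
on *high-cut-only* traces: the shared slow drift is retained deliberately,
because on quiet frames it is the main identifiable common signal. The fit
degrades gracefully: with default noise the recovered `r` is attenuated by
a few percent (plus a small negative selection bias because the mask
conditions on the cell's own score); the residual contamination this leaves
is an order of magnitude below the activity criterion.

**ΔF/F.** F₀ is the 10th percentile of the corrected trace over a rolling
60 s window (whole-trace percentile as fallback), evaluated on a lightly
smoothed copy (σ = 1 s): a low percentile of raw per-frame noise sits
~1.3 σ below the true baseline and would shift every ΔF/F value upward by
~2% otherwise. The rolling percentile is computed at strided centres
(default every 8 frames) with linear interpolation — a deliberate
approximation whose error is far below the 5% criterion. Because the
rolling F₀ tracks slow baseline, it performs the low-cut role in the ΔF/F
path; the explicit Gaussian low-cut remains available and tested as a
stand-alone operation. NaN frames are rejected with an error rather than
imputed — silent data loss would corrupt participation rates.

**Activity.** A frame is active when ΔF/F ≥ `dff_threshold` (default 0.05,
inclusive). Thresholding is instantaneous (no onset statistic), and
correction precedes ΔF/F.

## Event analysis

Frames with participation strictly >20% form events; runs separated by at
most `merge_gap` subthreshold frames (default 1 frame = 0.25 s at 4 Hz)
are merged, since single-frame dropouts at this frame rate are sampling
artifacts. The per-event participation rate is the *union* fraction — cells
active on at least one event frame — which is less sensitive to frame rate
than the peak simultaneous fraction (also computed and reported). Class
boundaries mirror the printed rule: H strictly >60%; L inclusive 20–60%;
below 20% an event detected by the frame criterion is labelled "sub" and
excluded from both rates. Participation denominators use all identified
cells regardless of marker label. Group comparisons use `scipy.stats`
one-way ANOVA and the Tukey–Kramer HSD procedure.

## Histology

Box densitometry is the arithmetic mean over half-open rectangles supplied
as geometry JSON (boxes are placed manually in practice; the generator
emits matching geometry — no anatomy detection is attempted). The
normalised projection intensity is (layer − background) / (electroporated
WM − its background), invariant to global gain and offset by construction;
a non-positive denominator raises an error flagging failed labeling. Line
scans average each row of a 900 × 900 crop (row 0 = pia); widths are in
pixels unless a pixel size is supplied. For arborization widths, the
30-pixel "kernel size" is interpreted as the full ±3 σ support of a
Gaussian (σ = 5 px); binarisation uses a scale-adaptive histogram threshold
(Otsu by default, configurable) in place of blinded manual binarisation,
for reproducibility. Rows whose positive fraction exceeds 0.5 are grouped
into bands and the two tallest bands are returned in depth order; smoothing
moves each 50%-crossing by at most ~1.3 σ, which bounds the width error.
Multi-page TIFFs are maximum-intensity projected (mean optional); input
images are assumed tilt-adjusted.

## Reproducibility

All randomness flows from one root seed through `SeedSequence`-derived
per-(group, recording) seeds; identical configurations reproduce
byte-identical tables (floats are written at fixed precision). Every run
writes a manifest with the effective settings, seeds, package versions and
SHA-256 hashes of all outputs.

## Problem sizes

Recovery ensembles use 100 recordings of 100 cells × 10 min per condition
(the acceptance script and acceptance tests); unit and property tests use
smaller sessions (20–50 cells, 1–5 min) with the same statistical
structure. The contamination-ratio oracle compares 1000 random instances
against a 1e−4-step grid minimiser.
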