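# calsync

Analysis toolkit for spontaneous network activity in the developing cerebral
cortex as recorded by in vivo two-photon calcium imaging, paired with
fluorescence densitometry of callosal axon projections in brain sections.
It is aimed at labs studying activity-dependent circuit development who need
the trace-processing and event-classification conventions of that literature
as tested, scriptable code — together with a ground-truth synthetic-data
generator so every stage can be validated without raw recordings.

## What it computes

**Trace processing.** Somatic fluorescence traces are band-pass filtered
(zero-phase Butterworth low-pass, order 10, cutoff 1 s; Gaussian low-cut,
cutoff 2 min) and corrected for out-of-focus neuropil contamination:

    F_corrected(t) = F_apparent(t) − r · [F_surround(t) − mean(F_surround)]

where the contamination ratio *r* is fitted per cell by least squares over
quiet frames t_base (no obvious spontaneous activity):

    F_cell[t_base] − mean(F_cell[t_base]) = r · (F_surround[t_base] − mean(F_surround[t_base]))

ΔF/F is computed against a rolling-percentile baseline F₀, and a cell is
*active* on a frame when ΔF/F ≥ 5%.

**Event analysis.** Frames on which >20% of identified cells are
simultaneously active form synchronous network events (maximal runs,
single-frame gaps bridged). Each event's participation rate — the fraction
of all cells active during the event — classifies it as **H** (highly
synchronous, >60%) or **L** (less correlated, 20–60%); rates are reported
in events/min, and groups are compared by one-way ANOVA with Tukey–Kramer
post-hoc tests.

**Histology.** Projection strength from section images: mean intensity in
annotated boxes, background-subtracted and normalised by the
background-subtracted white-matter signal on the electroporated side (a
gain- and offset-invariant ratio); depth line-scan profiles; arborization
band widths after Gaussian smoothing and automatic binarisation; and
per-cell green/red expression ratios from two-channel images.

**Synthetic data.** `simulate_recording` generates Poisson-timed H/L events
with configurable participation bands, difference-of-exponential calcium
transients, shared event-locked neuropil contamination with a known ratio,
slow drift and frame noise — returning the hidden schedule (`GroundTruth`)
for recovery testing. `simulate_section` builds layered axon-density images
with matching measurement-box geometry.

## Worked example

```python
from calsync import (scenario_config, simulate_recording,
                     process_recording, NetworkEventDetector)

cfg = scenario_config("control", seed=3)      # 100 cells, 10 min at 4 Hz
recording, truth = simulate_recording(cfg)
processed = process_recording(recording)      # filter, correct, ΔF/F, raster
events = NetworkEventDetector().fit(processed.raster, frame_rate_hz=4.0)
s = events.summary_
print(f"true  H {truth.count('H')}, L {truth.count('L')}")
print(f"found H {s.n_events['H']} ({s.h_per_min:.2f}/min), "
      f"L {s.n_events['L']} ({s.l_per_min:.2f}/min)")
```

prints

```
true  H 10, L 26
found H 10 (1.00/min), L 26 (2.60/min)
```

i.e. the ten-minute session contained 10 highly synchronous and 26 less
correlated ground-truth events, and the full pipeline recovered every one
with the correct class. The same flow is available from the shell:

```sh
calsync simulate-recording --out run/sim --seed 3
calsync process --recording run/sim/recording.csv --out run/proc
calsync detect --raster run/proc/raster.csv --out run/det --plot
calsync run-all --out run/full --seed 3      # multi-group + ANOVA/Tukey
```

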