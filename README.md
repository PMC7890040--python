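# dcvfusion

Quantitative analysis of dense-core-vesicle (DCV) fusion in single
neurons imaged with pH-sensitive fusion reporters (NPY-pHluorin,
BDNF-pHluorin).

Neuropeptides are released from DCVs, and pHluorin makes individual
release events visible: the probe is quenched in the acidic vesicle
lumen and lights up the instant a vesicle fuses with the plasma
membrane.  A recording consists of a baseline window, an electrical
stimulation window during which fusion events appear as brief
fluorescent puncta, and an NH₄Cl superfusion at the end that
neutralizes every vesicle lumen and reveals the entire labeled vesicle
pool.  `dcvfusion` turns such a time-lapse movie into per-event and
per-cell quantification tables:

* **Detection.** Candidate fusion sites are local maxima of the
  per-pixel temporal standard deviation (SD) of the stimulation window
  — transient events produce high SD regardless of local brightness,
  so dim neurites are not under-represented.  Maxima are selected by
  topographic prominence (the "SNR" knob, on a 0–255 scale), placed as
  non-redundant square ROIs (two retained ROIs may share at most ⅓ of
  their area), and each ROI's event start is the first frame *f* during
  stimulation with

  `F(f) > rolling_mean(f−1) + k · rolling_SD(f−1)`

  computed on the raw-movie ROI trace with a trailing window.  ROIs
  that never cross are discarded.
* **Event metrics.** Start time `(FusionStart − 1)/F` (imaging
  frequency *F*), peak ΔF/F₀ relative to the baseline-window mean F₀,
  duration as the time above `F₀ + 2·SD₀`, and distances to the nearest
  synapse and nearest other event.
* **Pool estimation.** The NH₄Cl window yields a baseline-subtracted
  maximum projection; the package reports three pool sizes: `raw_pool`
  (punctum count), `fused_corrected` (total above-background intensity
  ÷ mean integrated fusion-event intensity) and `puncta_corrected`
  (total ÷ median intensity of isolated single puncta).  The release
  fraction is `n_events / pool`.
* **Synapse mask.** A synapsin-marker image is turned into a binary
  mask (morphological opening + Triangle auto-threshold) and events are
  classified synaptic/extra-synaptic by distance to the mask.
* **QC.** Exclusion criteria (no NH₄ response, focus drift, saturation
  outside the soma, many pre-stimulation bright vesicles) are attached
  as flags, never silent deletions.
* **Simulation.** A synthetic-movie generator renders the whole
  phenomenology — neurite arbor, quenched ~3 px puncta, stimulus-locked
  events of 1.5–3 ΔF/F₀ with exponential decay, the NH₄Cl step, uneven
  illumination, Poisson–Gaussian noise — with exact ground truth, so
  every pipeline stage is tested against known answers.

## Worked example

```python
from dcvfusion import (DetectionParams, build_events, default_scenarios,
                       detect_fusion_events, estimate_pool,
                       release_fraction, simulate_movie)

scenario = default_scenarios(seed=1)["clean"]      # 60 events, 150 vesicles
movie, truth, marker = simulate_movie(scenario)

params = DetectionParams()
rois, traces = detect_fusion_events(movie, scenario.paradigm, params)
events = build_events(rois, traces, scenario.paradigm)
pool = estimate_pool(movie, scenario.paradigm, params, fusion_events=events)

print(f"{len(events)} fusion events detected ({len(truth.events)} planted)")
first = events[0]
print(f"first event {first.roi.label}: t = {first.start_time_s:.1f} s, "
      f"peak dF/F0 = {first.peak_dff:.2f}, duration = {first.duration_frames} frames")
print(f"pool estimates: raw = {pool.raw_pool}, "
      f"puncta-corrected = {pool.puncta_corrected:.0f}")
print(f"release fraction (puncta) = {release_fraction(len(events), pool, 'puncta'):.3f}")
```

prints

```
60 fusion events detected (60 planted)
first event 0000-100: t = 49.5 s, peak dF/F0 = 2.88, duration = 17 frames
pool estimates: raw = 150, puncta-corrected = 146
release fraction (puncta) = 0.411
```

All 60 planted events are recovered; the label `0000-100` encodes ROI
"0000" with its fusion start at frame 100, i.e. `(100−1)/2 Hz = 49.5 s`
into the recording.  The peak ΔF/F₀ of 2.88 sits in the physiological
1.5–3 range, and the three pool estimates bracket the 150 simulated
vesicles.  The release fraction is high because desk-scale scenes carry
a deliberately small pool.

## Command line

```
dcvfusion simulate --scenario clean --seed 7 --out data/
dcvfusion detect data/clean.tif --config data/config.yaml
dcvfusion pool data/clean.tif --config data/config.yaml
dcvfusion synapse-mask data/clean_synapse.tif --radius 2
dcvfusion collect data/ --config data/config.yaml --synaptic
```

`collect` writes the two result tables, `vesicle_parameters.csv` (one
row per fusion event) and `pool_values.csv` (one row per cell).  The
config file carries the acquisition paradigm (frame rate, baseline
frames, stimulation window, NH₄Cl onset frame) and the detection
thresholds; frame timing is never read from TIFF metadata.

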