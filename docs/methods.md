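# Methods

This note documents the analysis model implemented by `dcvfusion`, the
choices made where the original workflow leaves the design open, and
what the synthetic-data tests do and do not demonstrate.

## Acquisition model

A recording is a single-channel T×H×W stack with a frame rate `F`
(default paradigm: 2 Hz), a quiet baseline, one or more electrical
stimulation blocks, a post-stimulus window, and NH₄Cl superfusion at
the end.  The reference paradigm is 30 s baseline, 16 trains of 50 APs
at 50 Hz delivered every 1.5 s (24 s = 48 frames; the stimulation-window
*parameter* is rounded up to the closest multiple of 10, i.e. 50
frames), 26 s of post-stimulus recording, and NH₄Cl from frame 160.
All frame indices in files and labels are 1-based (`(FusionStart−1)/F`
converts to seconds); in-memory arrays are 0-based, converted only at
the I/O boundary.  Frame rate and paradigm always come from the config
file — TIFF metadata dialects are too inconsistent to trust.

## Normalization

Two options, used only to build the localization image (traces and
amplitudes are always measured on the raw movie so ΔF/F₀ stays
physically interpretable):

* **Baseline subtraction** — subtract the per-pixel mean of the first
  `baseline_frames` frames.  Output is kept signed; detection in this
  mode is exactly invariant to a global additive offset.
* **B&W opening** — per frame: maximum filter, then minimum filter
  (square neighborhood of side `2r+1`), then a unit-sum Gaussian blur
  with σ = r, reflect padding.  The max→min order follows the reference
  description verbatim even though classical grayscale opening is
  min→max; the oracle tests pin this order.  σ = r adopts the "same
  radius" convention the workflow states for the synapse mask.  Applied
  per frame (whether the reference applies it per frame or to a
  projection is unstated; per-frame is assumed and documented).

Because detection runs on the *temporal SD* of the movie, static
structure cancels and a smooth multiplicative illumination field only
rescales local SD values.  With the default prominence (60/255) the
detector tolerates the simulator's default ±10 % illumination field
with no measured loss of recall; stronger gradients shrink the
prominence of events in dim regions proportionally.

## Detection

1. **SD projection.** Per-pixel sample SD (n−1 denominator) over the
   stimulation window; multiple stimulation blocks produce one
   projection each, combined by pixel-wise maximum (the cheaper variant
   of per-block detection; candidate search is not re-run per block).
2. **Prominence maxima.** The SD image is min-max rescaled to 0–255
   (8-bit "SNR" semantics) and local maxima are selected by topographic
   prominence — height above the highest saddle toward a higher
   maximum, computed with a union-find persistence sweep; plateau
   maxima collapse to their centroid, score ties break by (row, col).
3. **ROI placement.** Greedy in descending score; a candidate is
   rejected if its square ROI would share more than `max_overlap_px`
   pixels (default: ⌊area/3⌋) with an accepted ROI.  ROIs are numbered
   "0000", "0001", … in acceptance order.
4. **Event start.** On the raw-movie ROI mean trace, the first frame in
   [stim start, NH₄ onset) exceeding `rolling_mean + k·rolling_SD`,
   with a *trailing* window of `baseline_frames` frames so an event
   cannot inflate its own threshold (window alignment is unstated in
   the reference; causal is the conservative choice).  ROIs with no
   crossing are dropped and the survivors renumbered.

Searching through the post-stimulus period (up to NH₄ onset) is a
deliberate widening: late events can still cross the trace threshold
even though the SD projection only covers stimulation.

**Default thresholds.** Min-max rescaling has one sharp consequence: on
a movie with *no* events the SD image is pure estimation noise and the
rescale stretches that noise across the full 0–255 range, so prominence
alone cannot control false positives.  The defaults therefore form a
two-stage gate: prominence 60 keeps the candidate list short, and a
cleaning threshold of 5 rolling SDs on the trace (a per-frame
false-crossing probability of ~10⁻⁵ over the ~100-frame search window
and a few hundred candidates) keeps the expected number of null-movie
false positives below one, while genuine events exceed the trace gate
by an order of magnitude.  In baseline-subtraction mode an additional
conjunctive per-pixel gate applies (site must reach `mean + k·SD` of
the normalized movie, default k = 3); the interaction of "SNR" and
"detection threshold" is not fully specified in the reference, so the
two are simply both enforced.

## Event metrics

F₀ and SD₀ are the mean and sample SD of the ROI trace over the
baseline window.  Duration counts consecutive frames above
`F₀ + duration_sd·SD₀` from the start frame (the return-to-baseline
rule is this package's choice — the reference names the ingredients but
not the rule; `duration_sd` defaults to 2 and is exposed).  Amplitude
is `(peak − F₀)/F₀` with the peak searched over the duration window;
events still above threshold at NH₄ onset are capped and flagged
`persistent` rather than discarded (dequenching would contaminate the
decay).  ROIs with F₀ ≤ 0 are flagged invalid and excluded from ΔF/F₀
statistics.  "Fusion intensity" is reported as peak ΔF/F₀; an integral
(`integral_dff`) is also emitted since the reference does not define
which is meant.

## Pool estimation

The NH₄ projection is the per-pixel maximum over the NH₄ window minus
the per-pixel baseline mean.  The soma — identified as the largest
connected dequenching component above the projection's Triangle
threshold, dilated — is excluded from counting and from integrated
intensities: its diffuse somatic response contains no resolvable single
vesicles and would otherwise inflate every estimate.  The reference
names three pool numbers but gives no formulas; the reconstructions
(each isolated in one function so alternates can be swapped) are:

* `raw_pool` — count of prominence maxima outside the soma, using the
  configured SNR or, when SNR = 0, an automatic prominence of
  `mean + 3·SD` of the projection background (pixels below the Triangle
  threshold; falls back to whole-image statistics when the split does
  not isolate a background, and is floored at 1).  The mean+3·SD rule
  is a heuristic — the reference does not state its statistic.
* `fused_corrected` — total above-background projection intensity ÷
  mean integrated intensity of the detected fusion events (each
  re-centred on its local ΔF maximum, integrated over the same window
  size used for puncta, at its peak frame).
* `puncta_corrected` — total ÷ median integrated intensity of isolated
  single puncta, defined as puncta within ±50 % of the modal punctum
  intensity (histogram mode), which excludes multi-vesicle clusters.

"Above background" is literal: the background mean of the projection is
subtracted before integrating, because a maximum over noisy frames
carries a positive bias that would otherwise leak into the totals but
not into the single-frame event units.

Saturation QC counts pixels at the bit-depth maximum during the NH₄
window outside the soma.  For this specific check the soma proxy comes
from the smoothed *baseline* image (largest component above the
median/max midpoint): a saturated patch would dominate the NH₄
projection's own intensity scale and corrupt the projection-based mask,
defeating the check.  Float movies carry no bit depth and report zero.

## Synapse mask

The marker image is duplicated and inverted, morphologically opened
(minimum filter, maximum filter, Gaussian blur, all of radius ≈ the
synapse size in pixels), the opened image subtracted from the inverted
one, and the difference thresholded with the Triangle rule on a 256-bin
histogram of the 0–255 rescaled image.  This chain segments marker
images whose synapses are *darker* than the background; which operand
("original") the subtraction uses is ambiguous in the reference, so
`subtract_from="raw"` exposes the alternative reading.  The manual
"delete extra objects" step is replaced by an area filter
(`min_area`/`max_area`).  Events are synaptic when their center lies
within `tolerance_px` (default 1 px) of the mask, by Euclidean distance
transform.

## Synthetic data

The generator renders: a soma disk and a dilated random-walk neurite
arbor over a faint background; quenched vesicle puncta (Gaussian σ = 1
px → ~3 px diameter) at 5 % of their dequenched brightness; fusion
events with an instantaneous rise and exponential decay (τ = 2 s)
confined to the stimulation window (plus an optional tail, default 0 —
the SD projection covers only stimulation, so tail events would be
invisible to it by construction); an NH₄Cl step dequenching every
vesicle within 2 frames plus a diffuse somatic response; a smooth
multiplicative illumination field (default ±10 %); and Poisson noise
followed by Gaussian read noise (σ = 4), cast to 16 bit.  Defaults are
the reference study conditions: 2 Hz, 30-frame baseline parameter,
stimulation frames 61–108, NH₄ at frame 160, 200 frames, amplitudes
uniform in 1.5–3 ΔF/F₀, 60 events among 150 vesicles on a 256×256
field.  The pool is desk-scaled (real neurons carry 1 400–18 000
labeled DCVs; 150 keeps every punctum resolvable at this field size).
Programmed ΔF/F₀ is defined as what a 3×3-ROI measurement reports (the
convention of the reference intensity traces), so the peak-pixel
amplitude is scaled by the punctum profile's inverse ROI-mean fraction.

Not emulated: photobleaching, stage drift, vesicle trafficking during
NH₄ (an off-by-default random-walk hook exists), kiss-and-run kinetics,
and overlapping events closer than the ROI size.  Passing tests
therefore demonstrate correctness of the algorithms under the stated
noise and geometry model, not robustness to motion or bleaching — the
workflow's QC criteria exclude such recordings rather than correct
them.

## Numerical conventions

Sample SDs use the n−1 denominator throughout.  Filters use reflect
padding.  Min-max rescale maps a flat image to zero.  Maxima ties break
by (row, col); plateau maxima report their rounded centroid.  ROI
squares are clipped at image borders (overlap counting uses the clipped
footprints).  The rolling window requires `stim_start_frame >
baseline_frames` so statistics exist before the search begins.  All
randomness in the simulator derives from one `numpy` generator seeded
by the scenario, making every render bit-reproducible.

## Problem sizes used in the tests

The suite runs the full default scene (256×256×200, 60 events) once for
detection/pool acceptance, a null scene for the false-positive bound, a
well-separated and a clustered 150-vesicle scene for pool recovery, ten
192×192 seeds for release- and synaptic-fraction statistics, and
96×96 scenes for batch/QC plumbing.  Oracle-equivalence checks run ≥200
random cases per primitive on ≤16×16 inputs.

## File formats

Movies and masks are plain multi-page TIFF; ROI sets, traces, and the
two result tables are CSV.  ROI labels follow `ROIID-EventStart` (4
digits from "0000", dash, 1-based start frame); the CSV dialect stores
the ROI size explicitly since the reference files leave it implicit.
ImageJ ROI-zip import/export is not provided; the CSV dialect is the
interchange format.
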