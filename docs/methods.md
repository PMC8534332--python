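# Methods

This note records the measurement conventions, algorithms and design
choices behind `nervetrack`, and what the synthetic benchmark does and
does not establish about real data.

## Coordinate and unit conventions

Masks are 2-D binary grids; `x` is the column index (rightward), `y` the
row index (downward), 0-based.  Anatomical direction (e.g. +x toward the
scaphoid side, −x ulnar; +y palmar) varies with probe orientation, so it
is carried only as free-text `axis_labels` metadata and never interpreted
by the geometry code.  Physical units come from a single scale,
`px_per_cm` (> 0, user-supplied — it depends on the ultrasound depth
setting and has no sensible default): areas divide by `px_per_cm²`,
lengths by `px_per_cm`, circularity is dimensionless.  The effective
sampling interval is `Δt = frame_step / fps`, with defaults 4 / 38 s⁻¹ ≈
0.105 s, the usual dynamic-wrist acquisition and frame-picking settings.

## Morphology

CSA and centroid are the zeroth and first moments of the mask — exact
integer/rational quantities with no estimator choices.  Two conventions
are worth stating:

- **Connectivity** is 8-connected foreground / 4-connected background
  throughout (component labeling, border following, region selection).
- **Holes** (e.g. hypoechoic fascicles misclassified inside the nerve)
  are *not* filled by default: the area counts mask pixels literally and
  the perimeter traces the outer border only.  `fill_holes=True` flips
  both at once, so area and perimeter always describe the same region.

### Perimeter estimation

The boundary is obtained by Moore-neighborhood border following with
Jacob's stopping criterion; vertices are foreground pixel centers.  The
raw Freeman chain length (axial step 1, diagonal √2) overestimates smooth
digital contours by ≈ 5% on average over orientations — squared through
`4πA/p²`, that alone would push a perfect disc's circularity down to
≈ 0.91 and a triangle's to ≈ 0.55.  The default length therefore uses the
classical Kulpa calibration, 0.948 per axial and 1.340 per diagonal step,
which is the raw chain rescaled by the isotropic average bias.  Measured
on rasterized references: disc (r = 60) circularity 1.01, equilateral
triangle (side 300) 0.616 vs the analytic π√3/9 ≈ 0.605.
`corner_correction=False` gives the uncalibrated chain sum for
comparison with tools that report it.

Residual limitations of any pixel-center chain estimator, documented
rather than corrected:

- orientation-dependent bias up to ~3% remains on long straight edges;
- small components give unstable lengths — components below
  `min_area = 5 px` are flagged invalid instead of measured;
- pixel *replication* (k-fold block upscaling) lengthens the measured
  contour by more than k, because the blocky boundary genuinely is a
  longer curve.  Scale covariance holds in the physically meaningful
  sense: the same continuous shape rasterized at k-times finer pitch
  measures k-times the perimeter within ~1–3% and the same circularity
  within ~2–4% (tested).  Metrics are therefore comparable across
  devices/depth settings, but not across naive pixel-replication resizes.

Pixelated small shapes can have circularity > 1 (a 3×3 block: 4π·9/64 ≈
1.77 with the raw chain); no clipping is applied.

## Post-processing of model output

Exactly one median nerve is present per frame (bifid variants are out of
scope), so multi-region predictions are resolved by two rules: keep the
largest 8-connected region (semantic output), or take the candidate with
the highest confidence score and keep its largest block (instance
output).  Ties — equal areas or equal scores — break deterministically by
the lexicographically smallest foreground pixel `(row, col)`; score ties
prefer the larger candidate first.  Empty predictions become invalid
frames: their metrics row is NaN and they score IoU 0 unless
`skip_invalid` excludes them from the per-video average (counting them is
the default, so failed frames penalize the average rather than silently
disappearing).  The known failure mode of the largest-area rule — a frame
where the true nerve is not the largest region — is not special-cased;
the rule is applied as stated.  No temporal smoothing across frames is
attempted.

## Phase analysis

The centroid-x trace over a flexion/extension cycle is biphasic; its
turning points are the phase boundaries.  The automatic detector:

1. bridge NaN (invalid-frame) gaps linearly, smooth with a centered
   moving average (`window_frames = 5`);
2. find alternating local maxima/minima with prominence ≥
   `prominence_frac = 0.10` of the total centroid-x range
   (`scipy.signal.find_peaks`); the sequence endpoints count as turning
   points, since recordings start and end at cycle boundaries;
3. merge runs shorter than `min_phase_s = 0.2 s` into their neighbors by
   dropping the less salient bounding extremum;
4. snap each turning point to the extremum of a lightly (3-point)
   smoothed trace within half a smoothing window.  Step 4 matters: the
   wide smoothing of step 1 rounds the waveform vertices and would
   otherwise shift boundaries by ±1 frame, systematically clipping the
   ramps (a ~10–20% downward bias on recovered modulation amplitudes);
   the light smoothing in the snap keeps it from chasing single-frame
   measurement noise instead.

A phase is labeled `flexion` when its net centroid-x change is negative
(ulnar drift under the usual probe orientation), `extension` otherwise;
labels strictly alternate by construction.  An annotated mode bypasses
the detector entirely and takes manually separated intervals, which is
the workflow the detector replaces.

Durations are histogrammed with fixed 0.03 s bins starting at 0 (the bin
width is configurable; it matches the granularity at which such duration
ranges are conventionally reported).  D90/D50 are the contiguous bin runs
containing the modal bin with counts ≥ 90% / 50% of the modal count —
isolated distant bins above threshold are excluded, so each range is a
single interval; D90 ⊆ D50 and both contain the mode by construction.

Each phase's metric trace is mapped affinely onto normalized time
`[0, 1]` and linearly interpolated at `u_k = k/29` (30 points; endpoints
are copied exactly, and affine traces are reproduced exactly).  No
smoothing precedes resampling.  Interior invalid gaps of ≤ 2 consecutive
frames are linearly bridged; longer gaps (or invalid endpoints)
disqualify the phase from pooling, to avoid interpolating across
segmentation failures.  Pooling needs ≥ 2 qualifying phases and reports
per-grid-point mean and sample SD (n−1).  The per-frame centroid offset
is the Euclidean deviation from the centroid at the start of the
*enclosing flexion phase*, so extension phases are referenced to the
flexion phase that opened their cycle (an extension with no preceding
flexion falls back to its own start).

Profile comparison reports `|mean_a − mean_b| / max(|mean_b|, ε)` per
grid point (b is the reference) and its average over the grid.

## Evaluation

Per-frame IoU is `|A∩B| / |A∪B|`; two empty masks score 1 (nothing to
segment, nothing segmented — the contract must be total, though the
generator never produces an empty truth frame), one empty mask scores 0.
The per-video score is the average over all sampled frames; invalid
prediction frames count as 0 unless explicitly skipped.

## Synthetic benchmark

The generator emulates the statistical structure of dynamic-ultrasound
nerve masks so the pipeline is testable end to end without clinical data.

**Shape.**  Star-convex polar curve `r(θ) = r₀(1 + m·cos 3(θ−θ₀))`: the
three-fold term interpolates circle (m = 0, circularity 1) → rounded
triangle (circularity ≈ 0.55 at the family limit m = 0.6).  Per frame,
`m` is solved from the target circularity (Brent's method on the analytic
circularity, which is independent of r₀) and `r₀` from the target area
`πr₀²(1 + m²/2)`; the mask is the set of pixel centers inside the curve.
Rasterization error at the default size (~1200 px area): CSA within
~0.7%, centroid within ~0.15 px, measured circularity within ~0.03 of
the programmed value.  Requested circularities outside ≈ [0.55, 1] raise.

**Kinematics and defaults.**  A normalized activation `s(t)` ramps 0→1
linearly over each flexion phase and 1→0 over extension.  Defaults encode
the emulated study conditions: 38 fps, frame step 4, 5 cycles; flexion
duration ~N(0.68 s, 0.08 s), extension ~N(0.48 s, 0.04 s), truncated at
0.3 s — these are realism defaults centered on typical modal durations,
not claims; base CSA 0.12 cm² with signed modulation −0.12 (12% shrink at
peak flexion; the sign is exposed because the deformation direction
varies between subjects); centroid excursion 0.10 cm along −x plus
0.02 cm along y; circularity 0.62 with signed amplitude −0.03 (less round
at peak flexion).  Drawn durations are rounded to the frame grid
(multiples of Δt ≈ 0.105 s), so every phase boundary — and hence the
activation extremes — is actually sampled by a frame; without this the
sampled sequence would systematically miss the programmed extremes and no
estimator reading only the frames could recover the programmed amplitude.
Generation is a pure function of `(spec, seed)`.

**Degradation.**  Boundary jitter displaces the mask edge by a smooth
Gaussian random field (σ = 3 px correlation) of configurable RMS
amplitude (default 2 px), applied through the signed distance transform;
a fraction of frames (default 5%) gets triple jitter, mimicking
motion-blurred frames.  Distractor blobs (default: 15% of nerve area,
strictly smaller by construction, ≥ 3 px away — mimicking the nearby
flexor-tendon look-alike) appear with probability 0.1/frame in the
semantic output; splits (probability 0.02) cut the nerve along a random
line.  Instance-style output carries 3 scored candidates per frame
(nerve + 2 distractors); scores are each candidate's true IoU against
ground truth plus N(0, 0.05) noise clipped to [0, 1] — so the nerve
candidate almost always, but not always, ranks first.  No B-mode texture
is rendered: the pipeline consumes masks, not grayscale images.

**What passing does and does not show.**  The benchmark establishes
correctness of the measurement and analysis chain: exact moments, a
calibrated contour length, phase boundaries recovered within 2 frames for
≥ 95% of phases, and programmed motion parameters (−0.12 CSA modulation,
0.10 cm excursion) read back within ±0.02 / ±0.01 cm averaged over 20
seeds under default noise.  It does not validate any segmentation model,
and real data differ in ways the generator does not emulate: correlated,
anisotropic boundary errors; distractors that touch or exceed the nerve
(where the largest-region rule fails by design); drift of the probe;
non-star-convex or bifid nerve shapes; and duration distributions beyond
truncated normals.  Per-video IoU numbers obtained on synthetic
degradations characterize the degradation model, not any clinical
segmentation performance.

## Problem sizes

Default sequences are 5 cycles ≈ 55–60 frames of 128 × 160 masks —
enough frames for ~10 phases per sequence while keeping a 20-seed
end-to-end recovery run around ten seconds.  Reference-shape checks use
a radius-60 disc and side-300 triangle, where rasterization residuals
are well below the asserted tolerances.
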