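# nervetrack

Post-segmentation analysis of median-nerve dynamics in dynamic ultrasound.

Dynamic sonography of the carpal tunnel records the median nerve while the
fingers flex and extend; how much the nerve's cross-section deforms and how
far it glides are candidate markers of carpal tunnel syndrome.  Automated
segmentation (deep-learning or otherwise) produces one binary mask per
frame — but the clinically interesting quantities come *after*
segmentation: per-frame morphology, motion-cycle phase structure, and
pooled temporal profiles.  `nervetrack` implements that downstream pipeline
as a tested, reusable library for anyone who has per-frame nerve masks
(model predictions or manual tracings) and wants the dynamics out of them.

## What it computes

For a binary mask `f(x, y) ∈ {0, 1}` on an `h × w` grid:

- **Cross-sectional area** — the zeroth moment, `CSA = Σₓ Σ_y f(x, y)`
  (a pixel count, converted to cm² via the image scale);
- **Centroid** — the first moments, `cx = Σ x·f(x,y) / CSA`,
  `cy = Σ y·f(x,y) / CSA`;
- **Perimeter** — arc length of the outer boundary polygon from
  8-connected border following, with corner-calibrated chain weights
  (0.948 axial / 1.340 diagonal) so that a rasterized disc measures its
  true circumference to ~1%;
- **Circularity** — `4π·CSA / p²`: 1 for a circle, ≈ 0.605 for an
  equilateral triangle (the shape a nerve cross-section resembles most of
  the time).

On top of the per-frame metrics:

- **Post-processing rules** that resolve multi-region predictions: keep the
  largest connected region (semantic output), or the highest-confidence
  candidate's largest block (instance output);
- **Phase analysis**: the centroid-x waveform is biphasic over each
  flexion/extension cycle; its turning points split the trace into phases.
  Phase durations are histogrammed and the **D90/D50** modal ranges
  (contiguous bins with ≥ 90% / 50% of the modal count) select phases of
  comparable length, which are resampled by linear interpolation onto a
  **30-point normalized-time grid** `u_k = k/29` and pooled into
  mean ± SD profiles;
- **Evaluation**: per-frame intersection-over-union against ground truth
  and the per-video average IoU;
- **Synthetic data**: a generator of moving, deforming nerve-mask sequences
  (star-convex `r(θ) = r₀(1 + m·cos 3θ)` shape family, ~1 s motion cycles
  at 38 fps sampled every 4th frame) with exact ground truth, plus
  degradation modes that mimic real model failures (boundary jitter,
  distractor blobs, region splits, scored candidate lists).

## Worked example

`examples/02_phase_profiles.py` generates a default synthetic sequence,
degrades it with realistic segmentation noise, and runs the full
metrics → phases → profiles pipeline:

```text
10 phases detected (5 flexion)
flexion   D90 0.63-0.66 s, D50 0.63-0.66 s
extension D90 0.42-0.45 s, D50 0.42-0.45 s

pooled over 5 flexion phases:
CSA profile start -> end: 0.1236 -> 0.1058 cm^2 (-14.4% modulation; programmed -12%)
terminal centroid offset: 0.089 cm (programmed excursion 0.10 cm along -x, 0.02 cm along y)
```

All ten programmed half-cycles are found; the duration ranges bracket the
programmed means (flexion ≈ 0.68 s, extension ≈ 0.48 s quantized to the
0.105 s frame grid); and the pooled profiles read back the programmed
12% flexion-phase area shrink and ≈ 1 mm centroid excursion to within the
single-sequence noise level (averaged over 20 seeds the estimates converge
to the programmed values — that check lives in `tests/test_acceptance.py`).
The other examples show morphology measurement against ground truth
(`01`) and IoU scoring before/after post-processing (`03`).

There is also a thin CLI over the same functions:

```bash
nervetrack simulate --seed 7 --out-dir sim/
nervetrack metrics --masks sim/pred.tif --meta sim/meta.yaml \
    --postprocess semantic --out metrics.csv
nervetrack phases --metrics metrics.csv --out phases.csv
nervetrack profiles --phases phases.csv --metrics metrics.csv --filter d90 --out profiles.csv
nervetrack evaluate --pred sim/pred.tif --truth sim/truth.tif \
    --meta sim/meta.yaml --postprocess semantic --out report.csv
```

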