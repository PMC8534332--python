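"""Split a motion trace into flexion/extension phases and pool profiles.

Works on a degraded (realistically noisy) prediction sequence: measure
morphology, detect the biphasic centroid waveform's turning points,
histogram phase durations (D90/D50 modal ranges), then resample each
phase onto the 30-point normalized-time grid and pool mean +/- SD
profiles.  The printed recovery numbers show the pipeline reading back
the motion parameters the generator programmed (CSA modulation -12%,
centroid excursion 0.10 cm).
"""

from nervetrack import (
    NoiseSpec,
    SimSpec,
    degrade,
    duration_histogram,
    generate_truth,
    pool_profiles,
    segment_phases,
    sequence_metrics,
)

truth = generate_truth(SimSpec(seed=7))
pred, _ = degrade(truth.sequence, NoiseSpec(seed=8))
records = sequence_metrics(pred, postprocess="semantic")

phases = segment_phases(records)
print(f"{len(phases)} phases detected "
      f"({sum(p.label == 'flexion' for p in phases)} flexion)")

for label in ("flexion", "extension"):
    hist = duration_histogram(phases, label)
    print(f"{label:9s} D90 {hist.d90_range_s[0]:.2f}-{hist.d90_range_s[1]:.2f} s, "
          f"D50 {hist.d50_range_s[0]:.2f}-{hist.d50_range_s[1]:.2f} s")

flexions = [p for p in phases if p.label == "flexion"]
csa = pool_profiles(flexions, "csa_cm2")
offset = pool_profiles(flexions, "centroid_offset_cm")
print(f"\npooled over {csa.n_phases} flexion phases:")
print(f"CSA profile start -> end: {csa.mean[0]:.4f} -> {csa.mean[-1]:.4f} cm^2 "
      f"({csa.mean[-1] / csa.mean[0] - 1:+.1%} modulation; programmed -12%)")
print(f"terminal centroid offset: {offset.mean[-1]:.3f} cm "
      f"(programmed excursion 0.10 cm along -x, 0.02 cm along y)")
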