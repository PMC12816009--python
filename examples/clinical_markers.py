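"""Hypnogram-derived clinical markers and prediction bias.

Computes the standard clinical summary of a night (total sleep time,
WASO, stage durations, REM latency, awakening and transition rates)
from a reference hypnogram, then from a noisy predicted hypnogram, and
prints the per-marker differences prediction minus reference — the
outcome a bias audit models across a cohort.
"""

from sleepeval import (
    ScorerNoiseModel,
    default_dynamics,
    marker_differences,
    simulate_hypnogram,
    simulate_scorers,
    sleep_markers,
    uniform_error_confusion,
)

reference = simulate_hypnogram(default_dynamics(n_epochs=960), seed=21)
predicted = simulate_scorers(
    reference,
    ScorerNoiseModel(
        base_confusion=uniform_error_confusion(0.90),
        transition_confusion=uniform_error_confusion(0.60),
    ),
    n_scorers=1,
    seed=22,
)[0]

ref_markers = sleep_markers(reference)
print("reference-night markers:")
print(f"  TST  {ref_markers.tst:6.1f} min   WASO {ref_markers.waso:6.1f} min   "
      f"REML {ref_markers.reml:6.1f} min")
print(f"  N1 {ref_markers.n1:5.1f}  N2 {ref_markers.n2:5.1f}  "
      f"N3 {ref_markers.n3:5.1f}  REM {ref_markers.rem:5.1f} min")
print(f"  awakenings/h {ref_markers.awh:5.2f}   transitions/h {ref_markers.trh:5.2f}   "
      f"sleep efficiency {ref_markers.sleep_efficiency:.2f}")

delta = marker_differences(predicted, reference)
print("\nprediction minus reference (positive = overestimated):")
for name, value in delta.as_dict().items():
    print(f"  {name:>16s}: {value:+8.2f}")
print("these per-recording deltas, pooled over a cohort, are the outcomes "
      "of the distributional bias audit.")
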