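# locopop

Population calcium-imaging analysis of self-paced locomotion on a running
wheel. The package takes, per daily session, a wheel-velocity trace (cm/s
at the imaging frame rate, ~25 Hz) and a standardized dF/F matrix
(neurons × frames, neuron identities matched across days) and computes the
full downstream analysis of an 8-day motor-learning experiment in the
dorsolateral striatum:

- **Movement-bout segmentation** — motion onsets are timepoints preceded by
  2 s of velocity < 0.09 cm/s and followed by 2 s in which velocity exceeds
  0.35 cm/s at least once; offsets mirror this (excursion above 0.30 cm/s
  before, all < 0.09 cm/s after); same-type events closer than 2 s keep
  only the earlier. Motion timepoints run from each onset until the
  centered 0.7 s mean velocity first drops below 0.09 cm/s.
- **Ca²⁺ event detection and activation typing** — per-neuron z-scored
  dF/F, 0.5 s moving average, consolidated peaks above 3 SD with rise rate
  above 0.4 SD/s, sharpened by event-triggered-average re-timing; neurons
  are typed *onset-only / offset-only / both / neither* by whether the
  bout-averaged peri-event trace (±2 s) crosses 3 SD.
- **Ensemble statistics** — per-bout binary activation vectors (> 3 SD in a
  2 s centered window); Jaccard similarity *J(A,B) = |A∩B| / |A∪B|*
  normalized to its mean over 1000 shuffles of the two vectors
  (chance ≈ 1); early→late ensemble fate overlap with a permutation null;
  the ±1/0 action-bias score; and an action-separability score (silhouette
  of onset vs offset bouts after PCA to 8 components and 2-D
  Chebyshev-metric t-SNE).
- **Velocity decoding and efficiency** — ordinary least squares from the
  population to velocity over 4 s peri-event windows, leave-one-bout-out
  cross-validated, scored as adjusted R² = 1 − (1−R²)(n−1)/(n−p−1);
  N-neuron information curves with supports chosen by LASSO at sparsity
  N ∈ {2,4,8,16,32,64,128}; and the efficiency score — the decoding R²
  interpolated at the day's active-neuron count, divided by that count.
- **Synthetic study generator** — multi-animal, 8-day datasets with planted
  bouts, GCaMP6-like transients, activation types, and day-by-day ensemble
  refinement (shrinking "both" population, rising bout-to-bout
  reliability), with complete ground truth for recovery testing.

The intended users are systems neuroscientists analyzing longitudinal
one-/two-photon imaging of head-fixed locomotion, and anyone who wants a
tested, seeded reference implementation of these statistics.

## Worked example

```python
import numpy as np
from locopop.synthgen import BehaviorParams, PopulationParams, generate_session
from locopop.behavior import detect_motion_events, session_summary
from locopop.events import (standardize_matrix, detect_calcium_events,
                            classify_activation_types)
from locopop.ensembles import activation_matrix, ensemble_similarity

session = generate_session(BehaviorParams(), PopulationParams(),
                           animal=0, day=1, master_seed=42)
bouts = detect_motion_events(session.velocity, session.frame_rate_hz)
mean_v, frac = session_summary(session.velocity, bouts.motion_mask)
print(f"day {session.day}: {len(bouts.onsets)} onsets, {len(bouts.offsets)} offsets")
print(f"mean velocity {mean_v:.3f} cm/s, fraction of time in motion {frac:.3f}")

z, valid = standardize_matrix(session.dff)
events = detect_calcium_events(z, session.frame_rate_hz)
print(f"{sum(len(e) for e in events)} Ca2+ events across {len(events)} neurons")

labels = classify_activation_types(z, bouts.onsets, bouts.offsets,
                                   session.frame_rate_hz, valid=valid)
for t in ("onset_only", "offset_only", "both", "neither"):
    print(f"  {t}: {np.mean(labels == t):.3f}")

acts, kept = activation_matrix(z, bouts.onsets, session.frame_rate_hz)
sim = ensemble_similarity(acts[0], acts[1], n_shuffles=1000, seed=0)
print(f"bouts 1 vs 2: Jaccard {sim.raw:.3f}, shuffle mean {sim.shuffle_mean:.3f}, "
      f"normalized {sim.normalized:.2f}")
```

prints

```
day 1: 19 onsets, 19 offsets
mean velocity 0.158 cm/s, fraction of time in motion 0.082
2890 Ca2+ events across 160 neurons
  onset_only: 0.150
  offset_only: 0.150
  both: 0.400
  neither: 0.300
bouts 1 vs 2: Jaccard 0.787, shuffle mean 0.330, normalized 2.38
```

All 19 planted bouts are found, the planted day-1 type fractions
(0.15/0.15/0.40/0.30) are recovered exactly on this seed, and the first
two onset ensembles overlap 2.4× more than chance — the bout-to-bout
reliability planted for day 1.

The same stages are available from the shell via the `locopop` command
(`simulate`, `detect-behavior`, `detect-events`, `classify-types`,
`encode`, `run-all`, ...); `locopop run-all --seed 0 --out results/` runs a
whole synthetic study and writes a JSON report plus tidy CSVs.

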