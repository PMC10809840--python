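# neowave

Waveform-level quantification of neonatal EEG seizure dynamics.

Neonatal seizures are usually detected from amplitude or spectral trends,
which miss how the *shape* of the epileptic oscillation evolves: waves grow
sharper as rhythmic input synchronizes, and become less sinusoidal toward
seizure termination.  `neowave` implements a complementary set of three
waveform measures on nonoverlapping 1-s epochs of bipolar EEG, together with
everything needed to take them from raw multichannel recordings plus
multi-rater annotations to group statistics and single-feature classifiers:

- **Complex envelope** — the per-epoch median of the analytic-signal
  magnitude `|x(t) + i H[x](t)|` (Hilbert transform); a robust amplitude
  trend.
- **Epileptic sharpness** — extrema are detected with an order-statistic
  filter (a sliding Tukey-weighted median forms an adaptive threshold track;
  intersections of the track with the signal bracket the extrema), then

      Sharpness = median_i [ (|x_peak − x_peak−7ms| + |x_peak − x_peak+7ms|) / 2 ]

  over the N detected extrema of a segment.  Offset-invariant, linear in
  amplitude, and scale-free in detection.
- **Degree of nonlinearity (DoN)** — with IF(t) = dθ/dt the instantaneous
  frequency from the unwrapped Hilbert phase and IF_z the segment's
  zero-crossing frequency (crossing count / 2·duration),

      DoN = std[ (IF − IF_z) / IF_z ].

  For an intrawave-modulated tone cos(ωt + ε sin ωt) this equals ε/√2,
  which the implementation recovers to a few tenths of a percent.

Comparators (five-band Hamming periodogram powers, the energy ratio
(β+γ)/(θ+α), RMS), annotation fusion across raters (a second is seizure at
level *k* if ≥ *k* of 3 raters agree), equal-thirds seizure staging
(start / middle / end), repeated-measures ANOVA with Tukey HSD and Box-Cox,
relative topography tables over the 18 longitudinal bipolar contacts, and
SVM/kNN/LR/NB classification of three schemes (seizure vs nonseizure,
onset vs nonseizure, end vs start stage) are all included.

A first-class synthetic-data module generates 18-channel, 256-Hz,
EDF-writable recordings with staged seizures — per-third amplitude gains,
spike-and-wave peakedness, rising intrawave modulation — and three noisy
raters, so the entire pipeline is testable without clinical data.

## Worked example

```python
import numpy as np
from neowave import (SynthConfig, generate_recording, generate_pure_tone,
                     preprocess, extract_features, EpochGrid, attach_labels,
                     degree_of_nonlinearity, complex_envelope)

# 1. analytic recovery on a modulated tone
tone = generate_pure_tone(freq=3.0, amplitude=2.0, fs=256.0, duration=4.0, eps=0.2)
don = degree_of_nonlinearity(tone.samples[0], fs=256.0)
env = complex_envelope(tone.samples[0][:256])
print(f"degree of nonlinearity: {don:.4f}  (theory eps/sqrt(2) = {0.2/np.sqrt(2):.4f})")
print(f"per-epoch median envelope: {env:.3f}")

# 2. one synthetic subject end to end, C4-P4 contact
cfg = SynthConfig(seed=1)                      # 120 s, two staged seizures
rec, ann = generate_recording(cfg)
rec = preprocess(rec)                          # clip->notch->high-pass->z->PCA
table = extract_features(rec, EpochGrid(1.0), channels=["C4-P4"],
                         features=("envelope", "sharpness", "don"))
table = attach_labels(table, ann, EpochGrid(1.0), fusion_level=3,
                      subject="subj001")
print(table.groupby(["feature", "period"])["value"].median().unstack().round(3))
```

prints

```
degree of nonlinearity: 0.1407  (theory eps/sqrt(2) = 0.1414)
per-epoch median envelope: 2.010
period     nonseizure  seizure
feature
don             0.328    0.508
envelope        0.667    1.679
sharpness       0.016    0.123
```

The modulated tone's nonlinearity matches ε/√2 within half a percent, the
envelope recovers the tone amplitude, and on the synthetic subject all three
measures are elevated during the annotated seizure seconds (values are in
z-units because recordings are standardized per channel).

## Command line

```sh
neowave synth   -c config.yaml          # write per-subject EDF + rater CSVs
neowave extract -c config.yaml          # preprocess + per-epoch feature table
neowave stats   -c config.yaml          # ANOVA, topography, classifier report
neowave all     -c config.yaml --force  # the whole pipeline
```

Every stage is driven by one YAML document and a single integer seed;
identical config + seed reproduces identical outputs byte for byte.
Exit codes: 0 ok, 2 config error, 3 data error.

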