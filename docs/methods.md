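# Methods

This note records the models, defaults, and numerical choices behind
`neowave`, and what its synthetic-data experiments do and do not show.

## Signal model and preprocessing

Recordings are uniformly sampled multichannel EEG in microvolts.  The
18-contact longitudinal bipolar montage (Fp1-F3 … Cz-Pz) is derived by
anode-minus-cathode subtraction when referential electrodes are present;
bipolar input is used as-is.

The preprocessing chain runs in a fixed order:

1. **Out-of-range correction** — samples with |x| > 200 µV are treated as
   invalid and replaced by shape-preserving (monotone, PCHIP) cubic
   interpolation over the surviving samples; invalid runs touching a record
   edge take the nearest valid value.  Channels more than half invalid are
   flagged unusable.
2. **Notch** — second-order IIR notch at 50 Hz.  The quality factor is not
   dictated by the design being followed; the default Q = 25 (−3 dB width
   2 Hz) is narrow enough to spare the gamma band and is configurable.
3. **High-pass** — 6th-order Butterworth, 1 Hz cutoff (single-pass −3 dB at
   the cutoff by the Butterworth definition).
4. **z-scoring** per channel with the population (1/N) standard deviation —
   stated so tests can be exact.  Feature values downstream are therefore in
   z-units.
5. **PCA denoising** — eigendecomposition of the channel covariance; the
   smallest leading set of components reaching 95% cumulative eigenvalue
   fraction is kept and back-projected to channel space, so per-channel
   features remain defined.  A strict component-space mode is deliberately
   not the default because all downstream results are reported per bipolar
   contact.

All filters are applied zero-phase (forward–backward).  Sharpness and the
degree of nonlinearity are waveform-shape measures; phase distortion would
corrupt exactly what they quantify.  The consequence — the magnitude
response acts twice, doubling stopband attenuation — is accepted and the
single-pass conventions above are the documented ones.

## Features (1-s nonoverlapping epochs, final partial epoch dropped)

**Complex envelope.**  Median of |analytic signal| per epoch; period-level
summaries average the per-epoch medians.  The word "power" in the feature's
common name notwithstanding, the quantity is the amplitude (median absolute
analytic signal), not its square.

**Epileptic sharpness.**  Extrema come from an order-statistic filter: a
Tukey-tapered window (default 64 samples = 0.25 s at 256 Hz, taper 0.5, so
at least one delta cycle fits per window) slides one sample at a time; the
weighted median of each trailing window forms an adaptive track that lags
the signal and intersects it only around turning points.  Maxima of
excursions above the track (and, by default, minima via the negated signal)
are the detected extrema; excursions touching a record edge have no
bracketing intersection and are dropped.  Detection is invariant to offsets
and positive rescaling.  Each extremum scores the mean absolute drop to the
signal exactly ±7 ms away — linearly interpolated between samples, keeping
the measure sampling-rate independent (nearest-sample mode available) — and
the segment's sharpness is the median score.  Extrema whose flanks fall
outside the segment are excluded; zero usable extrema yields NaN.

**Degree of nonlinearity.**  IF(t) is the central difference of the
unwrapped Hilbert phase; IF_z is the scalar zero-crossing frequency of the
segment (count / 2·duration).  DoN = std[(IF − IF_z)/IF_z] over interior
samples, excluding the first and last 0.1 s to suppress Hilbert edge
effects.  Negative IF samples (phase slips) are retained — they are part of
the phenomenon — but their fraction is tracked and a quality warning is
issued above 20%.  A per-segment scalar IF_z is used rather than a
per-sample track: the zero-crossing rate is the interwave reference against
which intrawave modulation is measured.  For cos(ωt + ε sin ωt) the analytic
IF is ω(1 + ε cos ωt)/2π, so DoN = ε/√2 over whole periods; the estimator
recovers this within ~3% for ε ≤ 0.4 at 256 Hz on 4-s segments.

**Comparators.**  Hamming-windowed periodogram powers in delta (1–4),
theta (4–9), alpha (9–13), beta (13–30) and gamma (>30 Hz); energy ratio
ER = (β+γ)/(θ+α); RMS.

Sharpness and DoN default to the same 1-s grid as the envelope; a per-stage
segment mode is available.

## Annotations, fusion, staging

Raters annotate on a fixed 1-s grid (CSV: one row per second, one column
per rater, 0/1; a header row is tolerated).  Fusion level *k* marks a
second as seizure when at least *k* of the 3 raters agree, so fused masks
are nested.  Maximal runs of seizure seconds form events; events of at
least 3 s are split into equal-thirds stages S1/S2/S3 with boundaries at
round(n/3) and round(2n/3) seconds — second resolution, because the
annotations carry no sub-second information.  Shorter events stay in the
seizure period but are excluded from stage analysis.  Epochs are labeled by
majority overlap.  Nonseizure is all non-annotated time; a matched-window
alternative was considered and rejected as the default since it discards
data without changing any of the contrasts studied here.

## Statistics

Observations for the ANOVA are per-subject × contact × condition means of
epoch features — aggregation before testing, so epoch counts do not inflate
degrees of freedom.  The repeated-measures structure uses the classical
univariate decomposition: each within-subject main effect is tested against
its own subject-interaction mean square, fixed-factor interactions against
the residual.  For two-level factors (e.g. period) this F test is exact
under any within-subject covariance — a property that matters here because
per-channel z-scoring anticorrelates the period means within a channel, and
a pooled-residual test was measurably anti-conservative (empirical size
~0.075 at nominal 0.05 over 1200 null cohorts; the classical decomposition
measures 0.053 over 900).  Box-Cox (maximum-likelihood λ, automatic
positivity shift recorded) is available for non-normal features; Tukey HSD
corrects pairwise comparisons.  Topography tables report
100·(F_cond − F_nonseizure)/F_nonseizure per contact, per fusion level, for
the whole seizure period and each stage.

## Classification

Observation unit: per-subject median of a feature over the epochs of each
class, by default at contact C4-P4 (globally the strongest contact in this
kind of analysis; any contact or the pooled table can be selected).
Schemes: (1) seizure vs nonseizure, (2) S1 vs nonseizure, (3) S3 vs S1.
Stratified 80/20 split, hyperparameters by stratified 5-fold CV on the 80%
(small logged grids: RBF-SVM C ∈ {0.1,1,10,100}, γ ∈ {scale,0.1,1};
kNN k ∈ {3,5,7}; LR C ∈ {0.01,…,10}; Gaussian NB has none), metrics on the
held-out 20%: accuracy, sensitivity, specificity, ROC/AUC from decision
scores, calibration from predicted probabilities in quantile bins.  All
randomness flows from one pipeline seed, embedded in every report.

## Synthetic data generator

The generator emulates the structure of a neonatal cot-side study — 18
bipolar channels at 256 Hz, per-second ternary rater masks — not its
physiology.

*Background*: a dominant slow delta rhythm (carrier 2.2 Hz whose
instantaneous frequency follows an Ornstein–Uhlenbeck walk, relative sd
0.15, τ = 3 s; amplitude slowly modulated, never near zero) plus a
band-limited (0.5–60 Hz) 1/f^α Gaussian noise floor at 0.05 relative RMS,
α = 1.  The rhythm-dominated construction is deliberate: the Hilbert-phase
instantaneous frequency of broadband noise is spike-ridden (phase slips at
envelope nulls), and a noise-dominated background would carry a higher DoN
than any seizure oscillation, inverting the contrast the pipeline is built
to measure.  Neonatal background EEG is in fact dominated by high-amplitude
slow activity; the noise floor weight and exponent remain configurable.

*Seizure events*: inside each annotated interval a coherent delta
oscillation (2.5 Hz, amplitude 37.5 µV against a 15 µV RMS background) is
added whose three equal thirds carry per-stage amplitude gains
g = (1.7, 2.2, 1.55) and intrawave modulation depths ε = (0.02, 0.15, 0.45).
The waveform is cos(θ + ε cos θ) with half-waves raised to the power
1 + 2·s and a peak-locked ~10 ms Gaussian transient of relative amplitude
1.0·s (spike-and-wave morphology), s = `sharpness_shape` ∈ [0, 1], default
0.5.  The cosine phase term gives DoN = ε/√2 like the sine variant but
leaves the phase rate at the extrema ≈ 1, so modulation depth does not
narrow the peaks: the sharpness and nonlinearity knobs act independently
(a sine-phase warp was tried first and coupled them).  The profile encodes
the dynamics under study: envelope maximal mid-seizure and decreasing
toward termination, waveform sharp throughout, nonlinearity rising at the
end.  Measured sharpness declines in the end stage as the waveform grows
irregular, mirroring the reported behaviour of sharp-wave measures late in
seizures.

*Raters*: each of 3 raters reproduces the ground-truth seconds with
Gaussian boundary jitter (sd 1 s, rounded) and a 10% per-event miss
probability — the simplest corruption that makes the fusion levels diverge.

*Cohorts*: per subject, overall seizure amplitude and background RMS take
independent mean-one lognormal factors (cv 0.2), and the per-stage gains
and modulation depths are jittered (cv 0.15 and 0.10): seizure progression
differs between neonates.  Without this, amplitude-borne stage contrasts
are deterministic and every stage classifier saturates; with it, the
end-vs-start scheme is won by the nonlinearity feature, as the real-data
analyses this package operationalizes report.

Recordings are written as EDF (16-bit, 1-s records, via the package's own
minimal writer; reading goes through MNE, which also serves as the
independent cross-check of the writer) and masks as CSV, so ingest is
exercised round-trip.

What passing tests on this generator do **not** show: robustness to
artifacts (ECG, movement), to tracé alternant or burst suppression, to
montage errors, or to the far larger morphological diversity of real
neonatal seizures.  The generator validates the measurement and inference
machinery, not clinical performance.

## Problem sizes in the shipped experiments

Pattern contrasts: 20 replicate cohorts × 20 subjects × 120-s recordings,
features taken at C4-P4, rater consensus (k = 3).  ANOVA calibration: 500
null cohorts (8 subjects, 2 channels, 40 s, seizure amplitude 0) for size;
100 cohorts at seizure gain 3 × background RMS, 20 subjects, for power.
These sizes give Monte-Carlo standard errors comfortably below the margins
being asserted while keeping a full run in minutes on one CPU; all counts
are parameters of `neowave.validation` and of `scripts/acceptance.py`.

## Known limitations

- The order-statistic extrema detector's window (0.25 s) is tuned to
  delta-range oscillations; much faster rhythms need a shorter window.
- Per-epoch DoN at 1-s epochs quantizes IF_z to 0.5 Hz steps; group medians
  absorb this, single-epoch values are noisy.
- The EDF writer covers the subset of EDF used here (integer sampling
  rates, 1-s records, µV signals); it is not a general-purpose exporter.
- Repeated-measures error terms for interactions use the highest-order
  residual; with more than two fixed factors this is an approximation.
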