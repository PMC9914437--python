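# Methods

This note documents the models, parameter choices and numerical rules the
package implements, what the synthetic data does and does not emulate, and
the design decisions taken where the procedure left room.

## Adaptive random audiometry

The stimulus space is the Cartesian grid of 8 frequencies (125, 250, 500,
1000, 2000, 4000, 8000, 12000 Hz) × 12 intensities (10–120 dB HL in 10 dB
steps) per ear: 96 tones per ear, 192 for a both-ear session.  The left
ear is always exhausted before the right.  Tones are drawn uniformly at
random from the remaining set; after each response the grid is pruned:

* heard at (f, I): all (f, I′ > I) on that ear are removed;
* unheard at (f, I): all (f, I′ < I) on that ear are removed.

Pruning never crosses frequencies or ears.  **Threshold recovery.**  For a
deterministic listener with threshold T(f), every presented tone at f with
I ≥ T(f) is heard and every tone with I < T(f) is not, so the set of heard
intensities at f always contains the smallest grid value ≥ T(f) that
survives pruning — which is exactly T(f) when T(f) lies on the grid.  The
audiogram (minimum heard intensity per frequency, `NR` when nothing was
heard) therefore equals the true audiogram under *any* presentation order.
The test suite checks this exhaustively over all 4! orders on a reduced
grid and over 100 seeded full-grid sessions.  The worst case — ascending
intensities at every frequency for a listener who hears nothing below the
top of the grid — presents all 96 tones; random order with pruning needs
about 70 trials per both-ear session in practice.

The simulated listener holds one threshold per (ear, frequency) in
[10, 130] dB; 130 encodes "never hears" (above the loudest grid tone).
With psychometric slope s = 0 the listener is deterministic with an
*inclusive* boundary (heard iff I ≥ T), chosen so grid thresholds are
recoverable exactly.  With s > 0, P(heard) = logistic((I − T)/s), i.e. 0.5
at threshold.  Tones are spaced by a configurable inter-stimulus interval
(default 2.0 s); button presses of heard trials are delayed by a truncated
normal (mean 0.45 s, sd 0.08 s, clipped to (0.05 s, window)) so the
response marker always lands inside the trial's analysis window.

## Synthetic EEG

The generator's task is to carry exactly the information the decoder is
supposed to find, in the recording geometry of the protocol (16 channels,
2000 Hz), not to be biophysically realistic.  Heard trials add a positive
Gaussian bump (peak latency 0.300 s, σ = 0.060 s) starting at tone onset;
the per-channel peak is `erp_amplitude_uv` × a channel profile of 1.0 on
channels 1–8, 0.5 on 9–13 and 0.0 on 14–16, giving the channel-ablation
experiments a ground truth (channels 14–16 are pure noise by
construction).  The waveform shape, latency and amplitudes are stated
assumptions — single-trial P300 morphology varies widely in real data —
and all are configurable.  Background noise is white Gaussian by default
(σ = 10 µV per channel) for testability; a 1/f ("pink") option spectrally
shapes the same noise to per-channel RMS σ.  Defaults put the 8 µV ERP
peak slightly below the broadband noise RMS; because the 1–12 Hz band-pass
removes most white-noise power while passing the ERP almost untouched, the
*post-filter* SNR is high and decoding on defaults is much easier than on
real recordings.  Passing end-to-end tests therefore demonstrates that the
pipeline is wired correctly and information flows where it should — not
that real-EEG accuracy would be attained.  The generator does not model
eye blinks, muscle artifacts, electrode geometry, drift, or
subject-to-subject variability.

Markers: S1/S3 at each left/right tone onset; S2/S4 at the button press of
a heard trial; S5 at the midpoint between a trial's window end and the
next onset (a known-silent moment).  With the default 2.0 s interval and
0.7 s window, an S5 epoch's tail overlaps the first ~50 ms of the next
trial's window — before any ERP energy (peak − 2σ = 180 ms), so silence
epochs remain effectively signal-free.  The generator rejects sessions
whose tones are packed tighter than the epoch window.

## Preprocessing and tokenization

Fixed order: 50 Hz notch (second-order IIR, Q = 30) → 1–12 Hz Butterworth
band-pass (order 4) → per-channel min-max normalization over the whole
recording into [0, 1] → rounding to 3 decimals (half-even, for
cross-language reproducibility).  Both filters run forward-backward by
default (zero phase), so the 300 ms ERP latency is not shifted.  Filter
family, order and Q are design choices exposed in `FilterSpec`; the band
edges and notch frequency are the protocol's.  Normalization granularity
(per channel, per recording) is likewise a choice: it makes every epoch of
a recording share one scale, and together with rounding it bounds the
token alphabet to the 1001-value grid 0.000…1.000 — the property the
featurizer depends on.  A constant channel maps to all zeros.

Epochs are 0.7 s forward windows (1400 samples at 2000 Hz) cut at each
stimulus or silence event from the *preprocessed* recording — long enough
to contain the full bump (0.3 s + 4σ ≈ 0.54 s) with margin.  Each epoch
becomes a document: values read channel 1 first, time order within a
channel, rendered as fixed-width "d.ddd" tokens, so a document has
channels × 1400 tokens and the count vector is a per-epoch value
histogram.  Because tokens are fixed-width decimals, lexicographic
vocabulary order equals numeric order.  TF is the raw count; idf is the
smoothed form ln((n+1)/(df+1)) + 1 (natural log, ≥ 1 for any occurring
term); rows are L2-normalized by default with a flag for the raw product.
The vocabulary is frozen on the corpus it was fit on; out-of-vocabulary
tokens at transform time are ignored.  A channel-tagged token variant
("c03:0.125") is available for ablations.  A numeric fast path
(`counts_from_epochs`) computes the same counts via `bincount` on grid
indices without materializing strings; its equivalence to the string path
is tested.

## Benchmark design

Classes: heard = positive.  The evaluation set interleaves heard stimuli,
unheard stimuli, and silence epochs; a single synthetic session is
naturally unheard-heavy (silences equal trials), so the assembly
downsamples the majority class (seeded) to a balanced set by default,
matching the near-balanced class ratios of published hearing-test EEG
benchmarks and making a chance accuracy of 0.5 the meaningful baseline.
The balanced event selection and the split seed are shared across channel
subsets, so a 16- vs 13- vs 8-channel comparison differs only in the
channels feeding the featurizer (each subset gets a fresh vocabulary).

Split: seeded shuffle, stratified 70/30.  Classifiers use library defaults
(scikit-learn; LightGBM for gradient-boosted trees) with fixed seeds —
no hyperparameter search.  Cross-validation is stratified k-fold with
k = 5 by default; k equal to the sample count switches to leave-one-out,
since singleton folds cannot be stratified.

Metrics from the confusion counts: error (FP+FN)/N, accuracy (TP+TN)/N,
recall TP/(TP+FN), precision TP/(TP+FP), specificity TN/(TN+FP), F1 as the
harmonic mean of precision and recall, and MCC with the standard
four-factor denominator.  Undefined ratios (e.g. precision of an
all-negative predictor) are reported as `None` and rendered "-"; an MCC
with a zero denominator is reported as 0.  Log loss clips probabilities at
1e-15.  AUC is the area under the ROC over all probability thresholds.
Report tables label the error column "MSE(%)" alongside accuracy — for 0/1
predictions mean squared error and classification error coincide.

## Problem sizes and seeding

The end-to-end tests use three simulated subjects (~300 balanced epochs)
per run, five seeds, and ERP amplitudes 0/8/25 µV; the acceptance script
uses a nine-subject cohort (~800 balanced epochs) and 100 recovery
sessions.  One global seed fans out to per-stage seeds through a CRC-32
stage-name hash (`stage_seed`), so sessions, recordings, splits and models
are each independently reproducible and every derived seed stays below
2³¹.

## Known limitations

* The synthetic ERP is a deterministic template; no amplitude/latency
  jitter across trials or subjects, so decoding difficulty is governed
  almost entirely by the amplitude/noise ratio.
* Per-recording min-max normalization is sensitive to a single extreme
  sample; robust (quantile) scaling is not implemented.
* Only stimulus- and silence-locked windows are featurized;
  response-locked windows are not used.
* BrainVision support covers unsegmented binary files (FLOAT_32 read/write,
  INT_16 read); EDF/BDF and segmented files are out of scope.
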