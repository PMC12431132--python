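# Methods

This note documents the models, the numerical choices, and the design
decisions behind `drowsyeeg`, and states precisely what the synthetic
benchmark does and does not show.

## Problem and pipeline

The task is binary vigilance classification — alert vs drowsy — from
scalp EEG. Drowsiness has a well-replicated spectral signature:
increased theta-band (4–7 Hz) power and attenuation of the posterior
alpha rhythm (8–12 Hz), superimposed on the 1/f background common to
all EEG. The pipeline turns each 30-s EEG window into a time–frequency
image and classifies it with a CNN feature extractor and an SVM head.
The 30-s window length reflects the slow, gradual character of
vigilance transitions; the C3/C4 electrode pair is a deliberate
minimal-montage choice (homologous central sites, redundant against
single-electrode failure).

## Synthetic vigilance EEG

The simulator is a phenomenological spectral model, not a biophysical
one. Each channel is a sum of band-limited oscillations plus shaped
noise:

- **Oscillations.** Per band (delta 0.5–4, theta 4–7, alpha 8–12, beta
  13–30 Hz), 8 sinusoids at frequencies drawn uniformly in the band
  with random phases, scaled so the band's RMS amplitude equals the
  configured level, and modulated by a slow (0.02–0.2 Hz) positive
  envelope of depth 0.3 — cheap, band-exact, and non-stationary the way
  real EEG is.
- **State contrast.** Default band RMS amplitudes in µV: alert =
  (delta 10, theta 5, alpha 20, beta 5); drowsy = (delta 12, theta 15,
  alpha 8, beta 4). These are literature-style magnitudes chosen once
  for a clear theta-up/alpha-down contrast; they are not fitted to any
  particular corpus.
- **Background.** 1/f ("pink") noise made by spectrally shaping white
  noise (amplitude ∝ f^(−1/2) above 0.5 Hz, flat below, no DC), RMS
  5 µV per channel.
- **Inter-subject variability.** Per-subject multiplicative band gains,
  log-normal with σ = 0.2, drawn once per subject and shared across
  that subject's sessions.
- **Channel structure.** C3 and C4 share their oscillatory sources and
  differ only in noise (homologous central electrodes are strongly
  correlated in practice); other channels draw independent sources.
- **Protocol.** 14 subjects × 3 sessions × 600 s at 512 Hz, channels
  Fz/Cz/C3/C4/Pz. The default state schedule is (alert, alert, drowsy)
  — the final session, after the longest sleep deprivation, is the
  drowsy one — which reproduces the 2:1 alert:drowsy session imbalance
  the evaluation protocol then rebalances. KSS is assigned 3 to alert
  and 7 to drowsy sessions by default (binarization at ≥ 4 makes any
  compliant mapping equivalent).

Everything is deterministic given the config seed: per-subject gains
and per-session signals derive from independent `SeedSequence` spawn
keys, so cohorts are reproducible bit-exactly and independent of call
order.

**Not modeled:** artifacts (EMG, ocular, line noise), sleep
microstructure (spindles, K-complexes), volume-conduction topography,
or realistic KSS ambiguity. Consequences are discussed under
*Limitations*.

## Preprocessing

- **Filter.** The [0.1, 30] Hz band-pass is realized as two
  windowed-sinc (Hamming) linear-phase FIR stages: a 4097-tap high-pass
  at 0.1 Hz and a 257-tap low-pass cutting at 33 Hz (so 30 Hz itself
  sits flat in the passband). A single-stage design with a true 0.1 Hz
  edge at 512 Hz would need the long tap count anyway; splitting keeps
  the low-pass cheap and the design legible. Measured single-pass
  response: within 1 dB of unity over [1, 25] Hz, ≥ 40 dB down from
  45 Hz, monotone roll-off below 0.1 Hz.
- **Zero-phase application.** Forward–backward filtering (no phase
  distortion of band timing in the scalograms), implemented as one FFT
  convolution with the taps' autocorrelation plus odd-reflection end
  padding — O(n log n) in signal length, equivalent to `filtfilt` for a
  FIR numerator. Filtering runs on the **full recording before
  segmentation**: a 0.1 Hz edge is meaningless inside a 30-s window.
  Edge transients within about one kernel length of the recording ends
  are accepted (steady-state suppression is what the contract
  measures).
- **Segmentation.** Non-overlapping 30-s windows per channel; the
  trailing remainder is dropped rather than padded (padding would
  fabricate signal). C3 and C4 windows are independent samples, not
  stacked channels.
- **KSS.** Ratings 0–9 accepted (0 included deliberately, although the
  standard scale starts at 1); label = 1 (drowsy) iff KSS ≥ 4.

## Continuous wavelet transform

The complex Morlet mother wavelet ψ(t) = (πB)^(−1/2) e^(2πiCt)
e^(−t²/B) with B = 2 and center frequency C = 6/2π (the common ω₀ = 6
Morlet; pseudo-frequency of scale l at rate fs is C·fs/l). The scale
grid is 64 geometric steps spanning 0.5–30 Hz — the filtered band.

The transform is computed exactly: FFT-based **linear** convolution of
the segment with the sampled, conjugated, time-reversed wavelet,
truncated at 6 envelope standard deviations (relative truncation error
~1e−8). Kernel FFTs are cached per (scales, segment length) since a
segment stack reuses them. This path matches direct numerical
evaluation of the defining inner-product sum to machine precision; the
tests assert ≤ 1e−3. Coefficients at segment edges are kept (no
cone-of-influence masking). A scale whose support exceeds the segment
raises an error (the 0.5 Hz scale needs ≥ ~12 s at 512 Hz; 30-s
segments are safe).

## Scalogram rendering

|W| (magnitude, not power — the conventional scalogram display) is
log-transformed and min–max normalized **per image**; the log floor is
proportional to the image maximum, so globally rescaled grids render
identically. Degenerate (constant) grids map to a flat mid-colormap
image. The normalized map goes through the fixed perceptually uniform
`viridis` colormap to RGB, time horizontal, low frequency at the
bottom, no axes burned in. Native raster 662×536; stored at 256×256;
the network input is a second bicubic resize to 64×64 (the double
resize keeps both documented resolutions meaningful). Resizes are plain
bicubic (Pillow), values clipped to [0, 1]. Long coefficient grids are
block-averaged along time to ~4× the target width before the bicubic
step — a pure speed optimization two orders of magnitude above the
target resolution.

## CNN models

A small, self-contained numpy implementation (im2col convolutions,
max pooling, inverted dropout, dense layers, Adam, binary cross-entropy
on logits) — deterministic given a seed, CPU-only, adequate for the
image sizes involved.

- **2-D family.** Depth-d model: d × [conv 3×3 ReLU ('same', stride 1)
  → maxpool 2×2 → dropout 0.25], flatten, dense 128 ReLU, dropout 0.5,
  1-unit sigmoid head. Depth 2 uses filter widths (16, 64); other
  depths follow a doubling ladder from 16 capped at 128 (depth 3 =
  (16, 32, 64), depth 5 = (16, 32, 64, 128, 128)). Depth 10 on 64×64
  inputs is reported infeasible (spatial collapse). Parameter counts
  are tested against closed-form layer arithmetic.
- **Training.** Adam (lr 0.001), batch 32, ≤ 50 epochs, early stopping
  on validation loss with patience 10 and best-weight restore. The
  validation split is a stratified, seeded 10% of the training
  partition. Per-epoch train/validation loss and accuracy are recorded.
- **Features.** The 128-d penultimate dense activations, post-ReLU,
  with dropout inactive at inference — a pure function of (weights,
  image). Repeated identical calls are bit-identical; the same image
  evaluated in a different batch context agrees to float32 rounding
  (BLAS accumulation order).
- **1-D baseline.** Raw filtered 30-s segments (15 360 samples),
  convolutional kernel sizes 64 and 32 (ReLU), dropout 0.5, lr 0.001,
  batch 32. Filter counts (16, 32), strides (4, 2) and pool 4 are this
  package's choices to keep the flatten manageable; inputs are scaled
  by a fixed 1/50 µV⁻¹ so amplitude information survives.

## SVM head

Features are standardized per dimension with training-set statistics
before the SVM (this is where "feature standardization" lives).
Kernels: linear, polynomial, RBF, sigmoid; the gamma convention is
k(x,x′) = exp(−γ‖x−x′‖²), so the default γ = 0.4 plugs in directly (a
bandwidth-σ reading would be a different convention; this one is the
package's documented choice). Defaults C = 1, γ = 0.4. Grid search:
stratified 5-fold CV on the training partition over C ∈ {0.01, 0.1, 1,
10, 100}, γ ∈ {0.05, 0.1, 0.2, 0.4, 0.8, 1.6}, degree ∈ {2, 3, 4},
best mean accuracy, ties broken toward smaller C then smaller γ.
Prediction takes the sign of the decision function (positive =
drowsy); a score of exactly 0 goes to class 0 — arbitrary but
documented and tested. The fitted head is checked against a brute-force
numerical solve of the soft-margin dual on small toys.

## Evaluation protocol

- **Positive class** is drowsy (1) throughout; sensitivity is the
  drowsy true-positive rate, specificity the alert true-negative rate.
  Metrics are percentages at full precision, rounded only for display
  (2 decimals, half-up). Zero-denominator ratios are reported as
  not-applicable, never NaN. ROC AUC by trapezoid; PR AUC by step-wise
  interpolation (average precision).
- **Balancing.** The drowsy minority is raised to the alert majority by
  50%-overlap re-windowing: a new 30-s window bridging the second half
  of one original segment and the first half of the next (same subject,
  session, channel), rendered through the same scalogram path —
  physiologically valid new samples rather than pixel forgeries. When
  raw signals are unavailable or candidates run out, the fallback is a
  small seeded time-axis shift of existing minority images. Augmented
  rows are flagged in the provenance; originals are never altered.
- **Splitting.** `pooled_random`: stratified 70/30 at the scalogram
  level. `leave_subjects_out`: whole subjects held out to approximate
  30% of samples — provided because a pooled split does not isolate
  subjects and therefore overstates inter-subject generalization.
  Balancing **before** the split is the default (matching the
  evaluation order this pipeline mirrors) but leaks augmented
  near-duplicates across partitions; `augment='after_split'` restricts
  augmentation to the training partition, and the driver logs a warning
  in the default mode.

## Problem sizes used in tests and the acceptance script

End-to-end runs keep 4 windows per channel per session (the package's
chosen working set: 14 × 3 × 2 × 4 = 336 original scalograms, 448
after balancing) rather than the full 20 windows per session — the
spectral contrast, not the sample count, is what the synthetic check
exercises. The shared test fixture uses 6 subjects × 6 windows. CWT
oracle comparisons run on 2-s segments at 64 Hz, where the direct
double-loop evaluation is affordable.

## What passing tests show — and what they do not

The synthetic benchmark demonstrates that the implementation is
correct and the pipeline is coherent: the simulator's spectral contrast
survives filtering, scalogram rendering, CNN feature learning, and SVM
classification, recovering state labels nearly perfectly while a
shuffled-label control stays at chance. It does **not** demonstrate
performance on real EEG: the simulator's contrast is strong and clean
(no artifacts, no label noise, no borderline vigilance states), the
pooled split shares subjects between partitions, and
balancing-before-splitting adds further optimism. Real-data accuracy
claims require real recordings under a subject-disjoint protocol.

## Known limitations

- The numpy CNN is single-threaded apart from BLAS and is sized for
  64×64 inputs; it is not a general-purpose training framework.
- EDF output is minimal EDF (1-s records, 16-bit): sufficient for
  round-tripping synthetic cohorts, not a full EDF+ implementation.
- The simulator's alert/drowsy contrast is binary; graded vigilance,
  artifacts, and topographic structure are out of scope.
- Filter edge transients extend about one kernel length (~8 s for the
  high-pass) into each end of a recording; on 10-min sessions this
  touches the first and last windows only.
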