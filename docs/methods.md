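# Methods

This note documents the models, parameter choices and numerical decisions
behind `emgtcd`, and what the synthetic-data experiments do and do not
demonstrate.

## Signal model and preprocessing

Input is a channels × time matrix of microvolt sEMG sampled at 2000 Hz
from nine trunk muscles in a fixed canonical order (DT first, then four
left/right pairs). Denoising is the standard offline sEMG recipe:

- **Band-pass** 20–200 Hz Butterworth, minimum order meeting 0.1 dB
  passband ripple and 50 dB attenuation at the stop edges. The stop
  edges are not dictated by the passband alone; we use 10 and 400 Hz
  (half/double the passband edges), which yields order 10 and keeps the
  transition bands plausible for EMG. The 20 Hz high-pass edge is the
  pipeline's only ECG/motion-artifact countermeasure.
- **Notch**: a minimum-order Butterworth band-stop with its stop band at
  49–51 Hz and pass edges 5 Hz outside, rather than an IIR comb, since
  both filters are of the Butterworth family here.
- Both filters are applied **zero-phase** (forward–backward,
  `sosfiltfilt`), so onset timing is not skewed and the design
  attenuations apply to the squared magnitude response (i.e. exceed
  spec). Whether the original analysis was causal or zero-phase is
  unknowable from the outside; zero-phase is the right choice for an
  offline pipeline. Signals are reflect-padded by up to 1 s so short
  unit-test fixtures remain filterable; recordings shorter than ~3 filter
  orders are rejected with advice to pad.

Analysis windows are 256 ms (512 samples) with 64 ms (128 sample) steps;
only fully contained windows are emitted, so 1 s of signal yields
`floor((2000−512)/128)+1 = 12` windows. This windows-per-second count
also sets the minimum segment length below.

## Active-segment detection

Activity detection operates on the raw signed sum of the nine channels
(no rectification). Each window gets a sample entropy
`SampEn(m, r, M) = −ln(A/B)` with m = 2 and r = 0.25 σ, σ being the
standard deviation of the **entire** channel-sum sequence, not the
window: rest windows are then regular relative to r (low SampEn), burst
windows complex (high SampEn). Conventions: Chebyshev distance, ordered
template pairs with self-matches excluded, strict `< r`, and the same
M − m templates for both the m and m+1 counts so the ratio is a
conditional probability. If either count is zero (e.g. a constant
window, where σ = 0 forces r = 0), SampEn is *undefined* and the window
is treated as inactive — degenerate quiescence is rest by definition.

A window is active when SampEn ≥ Th; maximal runs of active windows
shorter than `L0 = (windows per second) × sec` are rejected as noise.
The pair (sec, Th) is found by a two-loop grid search (sec = 10…1,
Th = 0…2 in steps of 0.01) over candidates detecting exactly the known
repetition count n₀ (5 by default).

**Choice among admissible candidates.** Two objectives are implemented:

- `stability` (default): take the midpoint of the widest contiguous Th
  interval yielding exactly n₀ segments, ties toward larger sec then
  lower Th. Rationale: on the synthetic data the rest-level SampEn floor
  fluctuates (≈ 0.3–0.45 versus ≈ 0.8 within bursts, because eight quiet
  channels dilute the burst contrast of the sum), and any objective that
  favors minimal thresholds pads segments with rest windows. The most
  *stable* threshold sits mid-plateau, recovers burst boundaries to
  within a window or two, and keeps the downstream feature matrix free
  of rest rows (~0.76 → ~1.00 hold-out accuracy on the default
  conditions).
- `longest`: largest sec, then maximal total active length, then
  smallest Th — the literal make-segments-as-long-as-possible reading.
  Kept as an option; with clean, strongly contrasted recordings both
  objectives coincide to within the edge halo.

A search failure (no grid point yields n₀) raises an error reporting the
closest count found; the pipeline logs and skips such recordings.

## Features

Per window and channel: RMS, population variance (divisor M), mean
absolute value, waveform length (sum of |successive differences|; the
last sample has no successor, so M−1 terms), and the 4th coefficient of
an order-4 AR model under the convention `x(k) = Σ aⱼ x(k−j) + e(k)`.
The single scalar a₄ (not all four coefficients) is used because the
feature dimension is 5 per channel (5·9 = 45). Estimation is Burg's
method (stable on 512-sample windows); `statsmodels`' implementation is
used after verifying its sign convention by parameter recovery, and it
is cross-checked in the tests against an independently coded lattice
recursion. A constant window has no AR model; its feature value is
defined as 0.

Pair reconstruction replaces each bilateral pair's values (a, b) by
(a+b, |a−b|), which is invariant to swapping a and b — and hence to
which body side is affected, since a left-affected trial is the mirror
image of a right-affected one. DT is unpaired (the electrode is placed
on the moving arm's side) and passes through.

Reduced montages keep DT plus whole pairs only: 7 channels drop the
rectus abdominis pair, 5 additionally the obliques, 3 keep DT + lumbar
erector spinae. The removal order (abdominal first) reflects that
abdominal sites are the most artifact-prone in practice; it is
config-overridable. Windows outside accepted segments are discarded
rather than labeled as rest — the classifier separates motion classes,
not motion from rest.

## Classification and evaluation

Six pairwise linear SVMs (L2-regularized squared hinge, LIBLINEAR-type
solver, C = 1) with a z-scoring scaler fitted on the training split only
(microvolt-scale raw features would otherwise cripple the regularized
solver; the scaling can be disabled). Prediction is majority voting;
ties break by the summed signed pairwise confidences, then canonical
class order. Per-class scores for ROC are sums of **tanh-squashed**
pairwise decision values: squashing bounds the influence of pairwise
models that do not involve a sample's true class, whose raw margins are
extrapolations and can otherwise dominate the score (observed: NC AUC
0.89 with raw sums versus 1.00 squashed, at identical voting accuracy).

Evaluation is a repeated stratified hold-out: per repeat, each class's
windows are split 80:20 at random, the scaler+SVM fit on the training
part, metrics measured on the rest; 100 repeats by default. Confusion
counts are summed over repeats; accuracy, per-class recall, F1 and
one-vs-rest AUC are averaged. Window-level splitting follows the
protocol convention of dividing each class's feature set; it is
optimistic in that windows of one recording can appear on both sides of
the split, so a trial-level splitting mode is provided as an option.
ROC curves are computed on the scores pooled over repeats; AUC is
trapezoidal and is checked against an exhaustive Mann–Whitney pair count
in the tests.

## Synthetic data generator

Each trial is `rest, (burst, rest) × n_bursts` with n_bursts = 5, 2 s
bursts and 2 s rests (22 s total). Channel signals are amplitude-
modulated band-limited Gaussian noise: carriers are synthesized
spectrally on 20–450 Hz (out-of-band power numerically zero), and the
amplitude is `baseline_sigma · (1 + burst_sigma_scale · g · env(t))`
with baseline 2 µV, scale 10, and a raised-cosine 100 ms burst edge.
The per-class gain vectors g mirror the muscle roles of the
compensations — SE: DT 1.0, others 0.1; TR: ipsilateral OEA 1.0,
contralateral 0.3, others 0.1; LF: all four trunk pairs 0.7, DT 0.1;
NC: 0.15 everywhere (a task-related component, so NC trials still
contain detectable bursts). On top: 50 Hz powerline (5 µV, all
channels) and a periodic ECG artifact (1.2 Hz, 20 µV, biphasic 120 ms
pulse, trunk channels only — not DT). The 120 ms QRS-like width places
the artifact's energy below the 20 Hz high-pass edge so the
preprocessing genuinely removes it; a materially shorter pulse would sit
inside the EMG passband and no linear filter could separate it.
Left-affected trials are generated by swapping each pair's two rows of
the right-affected recording, making mirror symmetry exact by
construction.

What the generator does **not** model: motor-unit action-potential
trains, inter-subject variability, electrode placement error, fatigue,
co-contraction dynamics, or multi-compensation trials. Passing the
synthetic suite therefore demonstrates that the pipeline's machinery is
correct and that the stated muscle topographies are recoverable under
controlled noise — not that human-data accuracy would match.

## Problem sizes and numerical notes

The classification experiments use 10 trials per class (40 recordings,
≈ 6000 active windows) and 100 hold-out repeats — the full default study
conditions. Window counts use fully contained windows only; the SampEn
grid step is 0.01 over [0, 2]; all random draws flow from a single
master seed through `numpy.random.SeedSequence`, making every stage and
the end-to-end report deterministic for a given seed. EDF files quantize
to 16 bits over each channel's observed range, so EDF round-trips are
exact to the quantization step while the delimited format round-trips to
better than 1e-6 µV.
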