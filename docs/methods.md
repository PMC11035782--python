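# Methods

## Strip digitization

A rasterized single-lead strip is loaded as a grayscale matrix in an
inverted intensity convention: background 0, grid lines strictly between 0
and 1, waveform ink 1 (1 = darkest).  Grid removal is a threshold rule —
pixels below `trace_threshold` become background, the rest become 1.  On an
ideal raster the waveform is exactly `h = 1` and the threshold could sit at
1; real rasters are anti-aliased, so the default is 0.9 (configurable), with
the ideal rule as the limit case.  The rule is idempotent and monotone in
the threshold.

Trace reconstruction takes the extracted pixel set column by column: a
column occupied by several rows (a steep QRS stroke) contributes the *mean*
of its rows — the unbiased center of the stroke; a median variant would fit
the same interface.  Row index grows downward in the image, so amplitude is
`(height − 1 − mean_row)`.  Empty interior columns are linearly
interpolated, leading/trailing empty columns are trimmed, and the result is
z-scored by default (a mV-per-pixel factor may be supplied instead when the
grid calibration is known; printed strips carry no inherent voltage scale).
The sampling rate must be supplied (`fs`); pixel columns are assumed
uniformly spaced in time.  PDF pages must be exported to PNG/TIFF before
digitization — the package reads raster formats only.  Multi-row strip
layouts are handled via an explicit crop box, not automatic layout
detection.  Disjoint strokes in one column (signal plus artifact) are
averaged together; no artifact rejection is attempted.

## Denoising, resampling, segmentation

The three-filter chain is standard ambulatory-ECG practice: 4th-order
Butterworth high-pass at 0.5 Hz (baseline wander), IIR notch at the mains
frequency (default 60 Hz, Q = 30), 4th-order Butterworth low-pass at 45 Hz
(below the mains, above the QRS band).  All filters run forward-backward
(zero phase) so QRS peaks do not shift.  At sampling rates where a cutoff
would cross Nyquist, `FilterSpec.default_for_fs` shrinks the low-pass to
0.8 × Nyquist and drops an unobservable notch.  Resampling is polyphase
(band-limited).  Segmentation uses 5 s non-overlapping windows by default —
overlap is exposed because clinical corpora are sometimes augmented by
overlapping windows — and every window inherits its recording's label.

## Continuous wavelet transform

`T(a, b) = a^(-1/2) Σ_j x_j ψ((j − b)/a)` is evaluated on the sample grid
(`a` dimensionless, in samples).  The Mexican hat
`ψ(t) = (2/(√3 π^¼)) e^(−t²/2)(1 − t²)` is the negative-normalized second
Gaussian derivative: even, zero-mean, zeros at ±1.  Per scale, the kernel is
sampled on `|t| ≤ 8` (where it has decayed below 1e−12) and applied by FFT
convolution; the signal is padded symmetrically by one kernel support, so at
points further than the support from either edge the result equals the full
brute-force sum to machine precision.

Scale ↔ frequency uses `F = F_c f_s / a` with the toolbox convention
`F_c = 0.25` for mexh.  This convention is self-consistent for magnitude
scalograms: the scale maximizing the mean |T| of a pure tone is
`a = √2.5/(2π) · f_s/f₀ ≈ 0.2516 f_s/f₀`, within 1 % of the `F_c = 0.25`
prediction, so peak-scale localization lands within one step of a 64-scale
log grid.

The default grid is 64 log-spaced scales spanning pseudo-frequencies
1–50 Hz: this covers P/QRS/T morphology and the 4–10 Hz fibrillatory band
that distinguishes AF.  The image fed to the classifier is the coefficient
*magnitude* (an energy-density view), min-max normalized and bilinearly
resized (corner-aligned) to a square image — 224×224 by default, smaller in
desk-scale studies.  Signed coefficients stay available for verification.  A
constant coefficient matrix (no dynamic range) renders as all-0.5.

## Network

The backbone is the standard 18-layer residual recipe: 7×7/64 stride-2
convolution, batch norm + ReLU, 3×3 stride-2 max pool, four stages of two
`Y = F(X) + X` blocks at widths 64/128/256/512 (stride-2 first block and
1×1 projection shortcut where width or resolution changes), global average
pooling.  Input is one grayscale channel.  Each of the `N_b` branch heads is
a single affine map `feature_dim → 1` with sigmoid — the minimal head; depth
is configurable.  Weights use Kaiming-normal initialization, seeded.

The whole stack (im2col convolutions, batch norm, pooling, Adam) is written
in NumPy with explicit backward passes; convolution arithmetic reduces to
BLAS matrix products.  Gradient correctness is checked against central
finite differences in the test suite, and the forward convolution against a
nested-loop oracle.  Tensors are float32.

## Multi-branching training

`make_partition` shuffles the majority indices (seeded) and splits them into
`N_b` near-equal subsets (sizes within ±1; leftovers spread one-per-subset
rather than dropped).  The default `N_b = max(1, round(|D₋|/|D₊|))` makes
each subset roughly the size of the minority class — at the 5050/738 counts
of the public AF corpus this gives `N_b = 7`.  The partition is built once
per run; per-epoch re-partitioning is not done (a fixed partition keeps the
branch/sub-dataset correspondence stable and the run reproducible).

The loss sums (not averages) the branch-indexed cross-entropy terms exactly
as defined — every AF sample contributes `N_b` terms, every normal sample
one; probabilities are clamped to `[1e−7, 1 − 1e−7]` before the logs.
Mini-batches are drawn from the union dataset and each sample's gradient is
routed through the indicator mask, so one shared forward pass serves all
branches.  Adam uses lr 10⁻³ (the rate at which the classifier trains best)
with β₁ = 0.9, β₂ = 0.999, ε = 1e−8; epochs and batch size default to 50
and 32.  Train/test splits are subject-disjoint (inter-patient), 80/20.
Prediction averages the branch probabilities; the operating threshold on the
average is 0.5.

## Evaluation

ROC and PR curves sweep all distinct score thresholds with ties grouped
(scikit-learn).  AUROC is trapezoidal — hence exactly the Mann-Whitney
concordance probability, which the tests verify by exhaustive pair counting.
AUPRC is the step-wise (right-continuous) average precision, avoiding
optimistic linear interpolation.  F1 is the binary harmonic mean on the
positive (AF) class, with 0/0 defined as 0.  Single-class label vectors
raise rather than returning a degenerate value.

## Synthetic generator

Traces are sums of per-beat Gaussian bumps (P, Q, R, S, T) placed at RR
intervals drawn i.i.d. normal with the requested mean and coefficient of
variation (floored at the template extent, 0.35 s), plus white measurement
noise (sd 0.03 relative to the unit R amplitude).  Defaults: normal rhythm
70 bpm with RR CV 0.03 and a P wave; AF 95 bpm with RR CV 0.15, no P wave,
and a 7 Hz sinusoidal fibrillatory component at 0.1 relative amplitude.
These express the two discriminative AF features — P-wave absence with an
F-wave band, and RR irregularity — as a qualitative contrast, not as
physiological ground truth.  True beat times are stored with each trace so
oracle statistics need no QRS detector; at the defaults a plain RR-CV
threshold (0.08) separates the classes ≥ 95 %, i.e. the classification task
is learnable by construction.  All randomness flows from the seed.

The strip renderer draws a light grid (intensity 0.5) under a full-intensity
polyline, two pixel columns per sample: sample columns at the exact rounded
row, connector columns spanning the neighboring rows — so a column-mean
digitizer recovers a linearly interpolated waveform and the render→digitize
round trip correlates ≥ 0.99 with the source.

What the generator does *not* emulate: real QRS morphology variation,
ectopic beats and other arrhythmias, electrode artifacts, baseline drift
dynamics, skewed/rotated or color scans.  Passing tests therefore certify
the pipeline's mechanics and the imbalance treatment, not clinical
performance; headline numbers on real corpora require the real recordings
and full-scale training, which are outside this package's test surface.

## Desk-scale study sizes

The training study in `afwave.experiments` uses 700 normal / 100 AF
five-second segments at 300 Hz (the ~7:1 imbalance of public AF corpora),
32-scale scalograms rendered at 32×32, the first two backbone stages
(widths 64/128), batch 32, 20 epochs, lr 10⁻³, five seeds, with both the
multi-branching (`N_b = 7`) and single-head configurations trained on
identical data and budget.  These sizes make a full multi-seed study a
matter of minutes on one CPU while keeping the imbalance phenomenon intact.

## Numerical notes and edge cases

- Degenerate digitizer inputs: an empty pixel set is an input error ("no
  signal found"); a constant-row trace z-scores to all zeros (sd 0 guard).
- `segment` with a trace shorter than one window returns an empty list
  under `drop` and one zero-padded window under `zero-pad`.
- CWT of a constant signal is 0 (admissibility); linearity holds on signed
  coefficients to 1e−6.
- Batch norm uses batch statistics in training and running averages
  (momentum 0.1) at inference.
- The sigmoid is evaluated in the numerically stable split form; the loss
  clamp keeps Eq.-level arithmetic finite at saturated probabilities.
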