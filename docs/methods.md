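# Methods

This note documents the models the package implements, the numerical
conventions that make its two datapaths bit-comparable, the synthetic
data it is validated on, and the limits of what those validations show.

## Frame geometry

The unit of classification is a 20×256 single-precision matrix: 20
channels × 256 samples, nominally one second of scalp EEG at 256 Hz.
Clinical recordings are cut into consecutive non-overlapping windows;
when a recording does not have 20 channels (e.g. single-channel
intracranial data), each channels×window block of exactly 5,120 samples
is reshaped row-major into the fixed geometry, and `window_s` is exposed
so a 20-s single-channel window (20×256 after reshaping) is equally
expressible. Trailing partial windows are discarded.

## Synthetic EEG generator

The generator emulates the *spectral contrast* the classifier exploits,
not the full physiology of scalp EEG.

* **Interictal**: per channel, five sinusoids with frequencies uniform in
  2–12 Hz, amplitudes U(0.5, 1.5), random phases, plus white Gaussian
  noise (σ = 0.5). This stands in for the band-limited rhythmic
  background of awake EEG.
* **Ictal**: the same background attenuated by 0.5 (low-frequency
  suppression), plus three fast components uniform in 16–64 Hz with
  amplitude `high_freq_gain`·U(0.3, 0.6) (default gain 3), plus
  Poisson-placed biphasic spike-and-wave templates (rate 3/s, a ~30 ms
  Gaussian spike followed by a slower opposite-polarity wave, amplitude
  U(2, 4)).

One `numpy` Generator seeded per call makes frame sets byte-reproducible;
the ictal count is round(n·ictal_fraction) with shuffled positions. All
samples are stored float32.

What the generator does **not** model: electrode artifacts, inter-channel
correlation and montage structure, non-stationary background, 1/f
spectra, subject variability, and the extreme class imbalance of
continuous monitoring. Passing the end-to-end recovery tests therefore
demonstrates that the pipeline learns and detects the designed spectral
signature through its single-precision datapath — not clinical-grade
performance on real recordings.

## FFT front-end

Per channel, a 256-point radix-2 decimation-in-time FFT: bit-reversal
input permutation, eight butterfly stages, twiddle factors W₂₅₆ᵐ
(m = 0…127) computed in double precision and rounded once to complex64.
All butterfly arithmetic is complex64, emulating a single-precision
datapath; measured amplitude error against a double-precision direct DFT
is ~2×10⁻⁷ of the per-channel spectrum scale (the contract tested is
1×10⁻⁴), and Parseval holds to ~1×10⁻⁷ relative (contract 1×10⁻³).
The full two-sided 256-bin amplitude spectrum is kept so the CNN input
stays 20×256. No window function is applied. The front-end is toggleable
(`use_fft_frontend`) since the feature extractor also accepts raw
voltage frames.

Per-bin relative error is measured against the per-channel spectrum
maximum: near-zero bins have no meaningful pointwise relative error.

## Convolution and pooling

Valid cross-correlation, stride 1, one feature map per layer — the only
configuration that maps 20×256 to the printed 1×31 output. The fixed
float32 summation order is the contract that makes the reference and
pipelined paths bit-identical:

* the bias joins the very first product of the window (as the first PE
  adds it),
* each kernel row accumulates left to right,
* row partial sums combine top to bottom,
* ReLU last.

The pipelined path emulates K row units of K chained
multiply–add–register PEs fed one input column per clock. Its cycle
model is `K + H_out·W_out` (pipeline fill, then one result per cycle;
the cross-row adder emits one cycle after a row partial, which an
independent event-queue simulation in the tests reproduces). Pooling is
non-overlapping 2×2, stride 2, floor on odd dimensions (3×62 → 1×31),
realised as the two-stage comparator (Data0 vs Data1, Data2 vs Data3,
then winners); its cycle model is 2 cycles per window because the second
comparison stage runs at half the base clock. Ties return the shared
value; NaNs are rejected upstream by the frame invariants.

## CORDIC exp/ln

One hyperbolic shift-and-add core serves both functions, schedule
i = 1…16 with the convergence-mandated repeats at i = 4 and 13 (18
micro-iterations), gain K_h = Π√(1−2⁻²ⁱ) applied by pre-loading 1/K_h.
Registers are float32; "shifts" are multiplications by exact powers of
two (lossless in floating point). The angle ROM holds atanh(2⁻ⁱ) rounded
to float32.

* **exp** (rotation mode): Cody–Waite range reduction v = m·ln2 + r,
  |r| ≤ ln2/2; result rescaled by 2ᵐ via `ldexp`. Arguments are clipped
  to [−104, 89], outside which every float32 result is 0 (logged
  underflow) or inf anyway. Measured max relative error over 10⁵ points
  in [−30, 30]: ~1.6×10⁻⁵ (contract 1×10⁻⁴).
* **ln** (vectoring mode): the argument is reduced to 2ᵉ·f with
  f ∈ [√½, √2) so no cancellation occurs near 1; vectoring on
  (f+1, f−1) accumulates atanh((f−1)/(f+1)) = ln(f)/2 without a divider.
  Post-processing applies the first-order residual correction z + y/x
  (the leftover angle is atanh(y/x) ≈ y/x to cubic order). Below
  |t| = 2⁻⁷ the iterations are bypassed and the odd series t + t³/3 is
  returned directly: the float32 angle-accumulation noise of the core
  (~10⁻⁷ absolute) would otherwise dominate results near ln 1 = 0. With
  both post-steps the measured max relative error over a 10⁵-point
  log-spaced sweep of [2⁻³⁰, 2³⁰] is ~8×10⁻⁶ and the absolute error near
  1 is ~10⁻¹⁰ (contracts 1×10⁻⁴ and 1×10⁻⁶).

The error budget 1×10⁻⁴ reflects the atanh-table resolution at i = 16
(≈2⁻¹⁶ angle granularity). The iteration count is configurable; 16
iterations are verified to be no worse than 12 on the same grids.

## SVM and the DPU dataflow

Decision function f(x) = Σ αᵢ·exp(−γ_eff·‖u(x) − u(svᵢ)‖²) − b with
αᵢ carrying the class label and u the identity (default) or an
element-wise CORDIC ln (the hardware normalisation path; an optional
1×10⁻⁷ epsilon floor admits zero-valued post-ReLU features). The squared
distance accumulates element by element in ascending feature order, the
support-vector sum in ascending index order, all float32. Kernel values
saturate at 1 (the CORDIC exponential's ~10⁻⁵ relative error could
otherwise nudge exp(0) past the kernel's range).

γ_eff = (max s − min s)²/(σ·(max f − min f)²) is computed once at model
build. At that moment every training feature is a candidate support
value, so the two extrema coincide and γ_eff = 1/σ; after SMO retains
the support vectors their extrema are recorded on the bundle but γ_eff
stays frozen, so inference uses exactly the kernel the dual was solved
with. σ defaults to the median pairwise squared feature distance (the
standard RBF bandwidth heuristic) and is otherwise a free hyperparameter.

The DPU route evaluates the same score through the hardware sequence —
negate-and-add for subtraction, squaring through the multiplier, scale,
CORDIC exp, sequential multiply–accumulate, final addition of −b — and
both the label and the score are bit-identical to the reference because
IEEE-754 makes each re-expression (x − y vs x + (−y)) exact. Support
vectors are served by a sequential ROM/FIFO emulation whose access
pattern is observable in tests; no memory timing is claimed.

Decision threshold: f(x) ≥ 0 → ictal (the standard SVM sign rule).

## Training

* **CNN**: temporary logistic head on the 31 features, binary
  cross-entropy, mini-batch gradient descent with Adam-style
  per-parameter step normalisation (β₁ = 0.9, β₂ = 0.999, lr 0.01,
  global-norm clip 5). Plain SGD is not workable here without per-layer
  rate tuning: raw amplitude-spectrum inputs (values up to several
  hundred) put the layers' gradient magnitudes orders of magnitude
  apart, and a single global rate either freezes the deep layers or
  collapses the ReLUs. Convolution biases start at +0.01 to keep the
  ReLU chain alive on nonnegative spectral input, and the head input is
  scaled by one constant frozen from the initial forward pass. Training
  runs in double precision; weights are rounded to float32 at export.
  The head is discarded.
* **SVM**: simplified (Platt-style) SMO with an O(n) error cache, box
  constraint C = 10, tolerance 10⁻³, terminating after 10 clean sweeps.
  KKT residuals (box and Σαᵢyᵢ = 0) are exposed for testing; rows with
  α > 10⁻⁸ become support vectors. scikit-learn's SVC is used in the
  test suite as an independent cross-check, never as the implementation.
* **Pipeline**: stratified 80/20 split by seed; SVM features come from
  the float32 inference extractor, so there is no train/serve skew.

Defaults (12 epochs, batch 32, 1,000 frames) were chosen as the smallest
desk-scale configuration with comfortable margin on the synthetic
recovery properties; training plus evaluation completes in well under a
minute on one CPU core.

## Cycle and latency model

Per detection, with output maps H×W:

| stage | cycles | default |
|---|---|---|
| conv K×K | K + H·W | 4037 / 747 / 187 |
| pool | 2·H·W (half-rate second stage) | 2016 / 372 / 62 |
| SVM | L·(3k + 18 + 2) + 1, k = 31 | 113·L + 1 |

The SVM term counts three sequential DPU operations per feature element
(subtract, square, accumulate), the 18 CORDIC micro-iterations of the
exponential, and two multiply–accumulate cycles for the α weighting.
Latency is total cycles divided by the clock (default 10 MHz); the
conversion is exact arithmetic (80,300 cycles ↔ 8.03 ms). For L ≥ 100
support vectors the SVM stage exceeds half the total, matching the
qualitative dominance of kernel evaluation in such designs. This is a
documented *model* — it accounts for no control, memory or refill
overhead and is validated for internal consistency (against an
event-driven simulation of the PE pipeline), not against any silicon
measurement.

## Metrics

Ictal is the positive class: sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP), accuracy = (TP+TN)/total, reported as
percentages rounded half-to-even to one decimal. Empty denominators
raise rather than return a sentinel. The package does not compute
ROC/AUC or event-based (onset latency) seizure scores.

## Known limitations

* The synthetic generator's separability makes the end-to-end accuracy
  properties easy; they validate plumbing and numerics, not clinical
  performance.
* The cycle model is first-order; real implementations add SRAM access,
  control-state and refill cycles it does not represent.
* The EDF path depends on the optional `mne` reader and performs no
  montage handling, filtering or artifact rejection.
* Training is deliberately desk-scale: single feature map per layer, no
  augmentation, no hyperparameter search, binary classes only.
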