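# Methods

`ppgfuzz` implements a fuzzy-linguistic encoding of photoplethysmography
(PPG) signals for two-class cardiovascular-disorder (CVD) screening,
followed by bio-inspired optimization of the encoded streams and a
cross-validated classifier bank. This note records the model, the
defaults and why they were chosen, and the places where the design was
genuinely open.

## Pipeline model

1. **Segmentation.** Each single-channel PPG record (100 Hz) is cut into
   non-overlapping 2-second windows of 200 samples; a trailing remainder
   is dropped. The reference configuration uses 750 segments per subject
   (150,000 samples).
2. **Features.** Eight parameters per window: Energy (raw sum of
   squares), Variance and SD (unbiased, n−1), ApEn (Pincus convention,
   m = 2, r = 0.2 × sample SD, Chebyshev distance, self-matches
   included), Mean, Skewness and Kurtosis (moment-based, kurtosis plain
   i.e. ≈3 for a Gaussian), and Peak Maximum. Constant windows are
   flagged degenerate with ApEn/skewness/kurtosis defined as 0.
3. **Fuzzy inference.** Each feature carries five triangular sets
   (VL…VH) built from published numeric ranges, with the peak at the
   range midpoint and shoulder extensions on VL/VH. Energy is the shared
   first input; it is paired with each of the other seven features
   through one 5×5 fuzzy associative matrix (13 defined cells on the
   diagonal band, 12 don't-cares). Conjunction is min, aggregation per
   output level is max, and the result is the linguistic label itself
   (argmax, ties toward higher risk).
4. **Code words.** The seven output levels map to letters A–E; each
   letter's probability is its five-bit positional weight over 31,
   divided by 7, using the published six-decimal constants so worked
   examples reproduce digit-for-digit. A segment's code word value is
   the sum of the seven letter probabilities (range 0.032256–0.516124).
5. **Reduction and optimization.** Per subject, duplicate letter strings
   are dropped (first occurrence kept) and the values truncated or
   cycled to a fixed length of 375. Four metaheuristics — Differential
   Search, Shuffled Frog Leaping, Wolf Search (grey-wolf update), Animal
   Migration Optimization — minimize one-dimensional vector-quantization
   distortion, `f(x) = mean_i min_j (v_i − x_j)²`, over
   `[0, 0.516129]^375`, with the raw reduced vector seeded as a
   population member. Distortion is zero exactly when every stream value
   coincides with some representative, which operationalizes the
   "singleton pattern" goal; the objective is pluggable.
6. **Classification.** Each 375-vector is cut into five consecutive
   frames of 75 values (five instances per subject). Six classifiers
   (LR, FLDA, KNN with K=5, a 75-30-1 RBF network, a 75-25-1
   tanh/logistic MLP, and an RBF-kernel SVM with γ chosen on
   0.001…0.01 by inner 3-fold CV) run under stratified 10-fold CV.
   Metrics come from the class-wise counts PC/MC/FA through the bespoke
   formulas Sensitivity = PC/(PC+FA), Specificity = PC/(PC+MC),
   Accuracy = their mean, PI = (PC−MC−FA)/PC, GDR = (PC−MC)/(PC+FA),
   all ×100. These deliberately differ from the textbook definitions
   and are implemented as printed.

## Synthetic cohort

The generator emulates the study conditions of a pulse-oximetry
benchmark: 28 CVD + 14 normal subjects at 100 Hz, 750 two-second
segments each. A subject's waveform is a beat train — each beat a main
systolic Gaussian plus a delayed, smaller dicrotic-notch Gaussian — with
a slow baseline sinusoid (0.25 Hz, amplitude 0.1) and additive white
noise (SD 0.04). Class contrasts, chosen once as stylized but
physiologically plausible markers of vascular impairment: CVD beats are
faster (90 vs 75 bpm), larger (amplitude 2.1 vs 1.0), jitterier
(inter-beat CV 0.09 vs 0.03; amplitude CV 0.14 vs 0.05), and have a
damped, earlier dicrotic notch (relative amplitude 0.12 vs 0.30).

What the generator does **not** emulate: real pulse morphology
variability, motion artifacts, respiratory modulation beyond one
sinusoid, sensor drift, or any clinical heterogeneity within class. The
synthetic classes are far more cleanly separated than hospital data, so
end-to-end tests demonstrate pipeline correctness and determinism, not
clinical performance; cross-validated accuracies near 100% on this
cohort say nothing about accuracy on real recordings.

Determinism: each subject draws from `default_rng(seed + stride·class +
subject_index)`, so records are reproducible individually and under any
generation order.

## Feature calibration

The eight published linguistic ranges are mutually inconsistent for any
single raw waveform (a Mean of ~15 units over a 200-sample window forces
an Energy far above its 0–30 domain), so raw features pass through a
per-feature affine map, `calibrated = offset + scale·raw`
(`features.DEFAULT_CALIBRATION`). The constants were fixed once by
mapping the pooled 0.5 %–99.5 % quantile span of the default cohort's
raw features onto a target interval inside each feature's linguistic
union; they are data-independent thereafter. With these defaults ≥ 99 %
of segments land inside the unions, normal-class segments populate the
VL/L sets and CVD segments the H/VH sets for the amplitude-driven
features. One wrinkle is deliberate: ApEn runs *lower* for the CVD class
(its larger pulses raise the tolerance r relative to the fixed additive
noise), so the ApEn letter position carries class information with
reversed polarity.

## Numerical choices and edge cases

- **Coverage gaps** between adjacent linguistic ranges (e.g. Energy
  0.1–0.7) assign membership 1 to the set whose support is nearest,
  ties toward the higher set. Shoulder extensions cover values beyond
  the extreme ranges.
- **Zero-firing pairs.** The don't-care corners of the rule band can
  leave a pair with no firing rule; the output then falls back to the
  defined cell nearest (Manhattan distance) to the dominant set pair,
  ties toward the higher output level. This keeps the output monotone
  along the rule band; the min/max/argmax path is untouched whenever any
  rule fires.
- **Target codes** are the position-wise modal letter over a window,
  modal ties toward the higher-risk letter. On the published 60-word
  example window this rule yields BEEAEEE rather than the EEEEDEE the
  source text states; the construction there is unexplained, and the
  modal rule is kept as the documented, reproducible choice.
- **Hurst exponent**: rescaled-range analysis over dyadic block sizes
  8…n/2, least-squares slope in log–log. The plain R/S slope is biased
  toward 0.5 at these lengths, so by default the log deviation from the
  Anis–Lloyd/Peters i.i.d. expectation is regressed instead and 0.5
  added back; `corrected=False` restores the plain estimator. The
  corrected form recovers fractional-Gaussian-noise H* ∈ {0.3, 0.7}
  within ±0.1 at n = 8192 (verified in the test suite against an exact
  Davies–Harte simulator).
- **SVM scaling**: the γ grid 0.001…0.01 presumes unit-scale inputs;
  code values span ~0.5, which would flatten the kernel. The SVM path
  z-scores inputs with training-fold statistics.
- **MLP training**: "train to zero MSE" is operationalized as L-BFGS to
  tolerance 1e-6 or 2000 iterations, whichever first.
- **Eq-style MSE**: classifier continuous outputs (probability-like,
  in [0, 1]) are mapped affinely onto the segment between the two class
  target-code values before squared-error against the true class's
  target, so a perfect classifier scores near 0 on the code-value scale.
- **SFLA**: the integer rounding of the published step rule is dropped
  (values live in a continuous [0, 0.52] box); the ±Rmax clamp is kept.
  Default 15 worst-frog updates per memeplex per shuffle (at the fixed
  sphere budget, 5 updates converge in only half the seeds), and a run
  stops after 50 shuffles without improvement.
- **DS**: mask rates default to 0.3·rand per run; out-of-bound trial
  coordinates are re-drawn uniformly (other algorithms clamp).
- **AMO**: ring neighborhood half-width 2 (five indices, wrap-around);
  replacement probability by fitness rank, worst → 1, best → 1/NP.
- **Search budgets**: unit tests use the 5-dimensional sphere at
  NP = 20, 200 iterations; the pipeline optimizes each patient's
  375-dimensional vector at NP = 20, 40 iterations — enough for the
  seeded-stream objective, where the stream itself is already optimal or
  near-optimal, while keeping a full 42-subject, 4-optimizer,
  6-classifier run to a couple of minutes.

## Known limitations

- The letter order within a code word (Variance, ApEn, Mean, SD,
  Skewness, Kurtosis, Peak-Maximum) and the reuse of the single
  published rule band for all seven pairs are conventions; both are
  configurable (YAML for the rule band, `WORD_FEATURE_ORDER` constant).
- Cross-validation folds are stratified over frames, so frames of one
  patient can appear in both train and test folds; `group_by_patient=True`
  switches to patient-grouped folds (default off to mirror the
  per-segment counting of the source design).
- The quantization objective leaves redundant vector components free to
  drift without fitness penalty; classification tolerates this because
  class separation lives in the value distribution, but interpretation
  of individual optimized components is not meaningful.
- Rank-deficient inputs to the canonical-correlation diagnostic are
  ridge-regularized (ε = 1e-6) with a warning rather than rejected.
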