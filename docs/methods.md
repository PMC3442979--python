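# Methods

## The problem

Quantifying complex herbal extracts — here *Cordyceps sinensis* (C) and
*Ganoderma lucidum* (G) in a fermentation-based beverage — by targeted
chromatography is difficult because neither extract has a small set of known
marker compounds. Flow-injection mass spectrometry (FI/MS) skips the column
entirely: the sample is infused into the ESI source and the analytical
signal is the full positive-mode scan spectrum (m/z 100–700), summed over
the injection window (0–1.0 min). Quantitation then rests on two
statistical steps:

1. **Principal-channel selection.** For each analyte, the m/z channels
   whose normalized intensity correlates with concentration at Pearson
   r ≥ 0.995 across a single-analyte calibration series are declared
   *principal* and become the feature set. Using several channels rather
   than one or two markers makes the method robust to any single channel
   misbehaving.
2. **Neural calibration.** A single-hidden-layer network with exactly three
   tanh nodes maps the principal-channel intensities x₁…xₙ to
   concentration:

       Hₖ = tanh(0.5 · (aₖ + Σⱼ wₖⱼ zⱼ)),  k = 1, 2, 3
       ŷ  = α·H₁ + β·H₂ + μ·H₃ + constant

   where zⱼ are centered/scaled intensities. No penalty term is applied.
   Model selection uses K-fold cross-validation: the data are split into K
   concentration-stratified folds, K models are fitted (each trained on the
   complement of one fold and scored on that fold), and the model with the
   best validation statistics is kept.

The method-validation battery around the calibration comprises spiking-level
arithmetic, matrix enhancement/suppression from predicted concentrations,
spike recovery with intra-/inter-day RSDs, LOD/LOQ from signal-to-noise
against solvent blanks, and a noise-injection robustness check.

## The synthetic study

No real acquisitions ship with the package; a generator emulates the study
design so that every stage is testable against known ground truth:

* **Design**: mixed two-analyte calibrants at 2, 20, 50, 100, 200 and
  400 μg mL⁻¹; 5 repeat analyses; 3 independent sets; matrix-free and
  matrix-matched conditions — 180 calibration spectra. A spiked-blank
  recovery study runs over 2 days × 6 sets × 3 levels × 5 replicates.
* **Fingerprints**: each analyte owns a small disjoint set of principal
  channels on the fixed 0.1 Da grid (9 for C, 7 for G by default), each
  responding affinely to concentration: intensity = intercept + slope·c,
  with slopes drawn from [5 000, 20 000] counts per μg mL⁻¹ and intercepts
  from [500, 2 000] counts (raw counts span ~10⁴–10⁷, as on a linear ion
  trap).
* **Noise**: multiplicative replicate noise with CV 0.02 (consistent with a
  best-case 2% intra-day RSD), an additive detector baseline of 50 ± 5
  counts on every channel, and 200 concentration-independent background
  channels with lognormal intensities — the material the correlation
  threshold must reject.
* **Matrix effects**: matrix-matched acquisitions scale the analyte signal
  by a per-level factor drawn from [0.95, 1.03] (a −5%…+3% envelope);
  matrix-free acquisitions always use factor 1.0.
* **Blanks**: solvent blanks carry only the additive baseline — the absence
  of principal-channel signal is exactly what marks a good blank.

Everything is a pure function of its parameters and a seed; the pipeline
derives per-stage seeds from one root seed through named SHA-256 substreams,
so reruns are bit-identical and stages are independently reproducible.

What the generator deliberately does **not** emulate: ESI physics,
space-charging, carry-over decay between injections, cone precipitation,
drift within a run, or inter-batch material variation. Passing tests
therefore demonstrate the correctness and statistical behaviour of the
*computations* on data with the assumed structure — not that the assumed
structure holds for any particular instrument or matrix.

## Numerical choices

* **Normalization** (the instrument software's method is undocumented):
  per-channel max-normalization across the set, because it maps every
  channel into [0, 1] while leaving Pearson correlation — the selection
  statistic — exactly invariant. Per-spectrum TIC normalization is
  available as an option but changes the selection statistic.
* **Correlation scoring** uses all replicate-level points rather than
  per-level means, so irreproducible channels are penalized. Channels with
  zero intensity variance score r = 0 and are flagged degenerate; values
  within 1e-12 of ±1 snap to ±1 so exactly affine channels score 1.0.
  Attribution always runs on single-analyte series: in mixed calibrants
  both analytes co-vary and correlation cannot tell their channels apart.
* **Threshold** applies to signed r (not |r|): principal channels respond
  positively to concentration.
* **Training**: multi-start L-BFGS-B on the sum of squared errors with
  analytic gradients; default 20 restarts from N(0, 0.5) initial weights,
  ftol 1e-15 / gtol 1e-12, max 1500 iterations. The parameter count
  (3·(1+n)+4 ≈ 34 for n = 9) is small enough that multi-start quasi-Newton
  reliably reaches a near-global optimum: on noise-free data the training
  predictions recover the true concentrations to < 1e-4 relative error.
  Inputs are standardized per feature (raw counts would saturate tanh
  instantly) and targets internally; all constants are stored in the model
  so the closed form stays exactly evaluable on raw intensities. Separate
  models are fitted per analyte and per matrix condition.
* **K**: defaults to 5, stratified by concentration level so every fold
  spans the working range. "Best validation statistics" is operationalized
  as lowest validation RMSE%, ties broken by higher r², then lower fold
  index.
* **RMSE normalization**: RMSE% = 100·RMSE/mean(actual). The per-point
  relative form is available via `fit_metrics(..., relative=True)`.
  r² is the squared Pearson correlation of predicted vs actual; it is
  reported for the held-out fold (validation), the training rows, and
  pooled over all rows — pooled is the headline figure.
* **Spiking levels** truncate (floor) rather than round: the canonical
  series 3/33/83/166/333/666 mg kg⁻¹ from 2–400 μg mL⁻¹ at 100 mL / 60 g
  only reproduces under truncation (3.33 → 3, 166.67 → 166). A 1e-9
  relative guard absorbs binary-float representation error.
* **Matrix effect** is computed as (Cpm/Cps − 1)·100 from concentrations
  predicted for matrix-matched and matrix-free standards *by the
  matrix-free model*. Two remarks: (a) the sign convention makes
  suppression negative, matching how matrix-effect tables are read; the
  literal reading "100 − Cpm/Cps·100" flips the sign and is not used.
  (b) a common predictor is essential — if each condition were predicted by
  its own calibration, the effect would be identically ~0 because a
  matrix-matched model absorbs the matrix factor.
* **LOD/LOQ**: S/N per level = (mean summed principal-channel signal −
  blank mean)/blank sd, anchored at (0, 0) and interpolated
  piecewise-linearly to S/N = 3 and 10. Summed principal-channel intensity
  (not single-peak height) is used, consistent with the fingerprint-sum
  workflow. Global intensity rescaling cancels exactly.

## The noise-injection check

The robustness check appends solvent-blank spectra to the calibration data
and reruns the identical K-fold selection; a discriminating calibration
must come out worse. The injected blanks are given *nominal* concentration
labels (cycling through the calibration levels), emulating failed repeat
acquisitions of standards — the statistical outlier scenario the check is
meant to expose. Labelling blanks 0 instead (available via
`label_policy="zero"`) makes them *consistent* with the calibration — a
signal-free spectrum truthfully labelled zero analyte adds an easy,
well-predicted point — and the check degenerates to a no-op; under the
default policy the degradation direction (validation RMSE% up, r² down)
reproduces robustly, with magnitude growing in the number of injected
blanks.

## Known limitations

* At the edges of the working range (2 and 400 μg mL⁻¹) the matrix-effect
  table compresses toward zero: predicting a suppressed/enhanced standard
  pushes the matrix-free model slightly outside its training range, where
  tanh saturation biases predictions back toward the range. Closure against
  the generated factor is therefore asserted at an interior level
  (50 μg mL⁻¹), where recovery is within ±1%.
* The LOD/LOQ of the synthetic study reflect the generator's baseline
  noise, not any instrument; only the computation and its closure on
  constructed inputs are meaningful.
* The mzML reader covers plain full-scan files (32/64-bit float arrays,
  uncompressed or zlib); indexed/vendor-extended documents are out of
  scope, as are centroiding and profile-mode deconvolution.
* With 90 rows against ~34 parameters per model the fit is close to the
  interpolation regime; the model object warns when rows ≤ parameters.

## Problem sizes used by the test suite

The acceptance-style checks run the full 180-spectrum design (seed 42,
K = 5, 20 restarts). Unit and property tests use structurally complete but
smaller studies — typically 1–2 sets, 2–3 replicates, 2–3 principal
channels, 20–50 background channels and 2–4 restarts — which exercise every
code path at a fraction of the cost; feature-recovery and noise-monotonicity
properties average over 10–20 seeds.
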