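# Methods

## The screening problem

Jaundice — yellow discoloration of the sclera and skin — appears when serum
total bilirubin rises above roughly 3 mg/dL. Because the color shift is
optically measurable, a photograph of the exposed sclera taken next to a
known-white reference (a plain sheet of white paper works) carries enough
signal to estimate total bilirubin and screen for jaundice without a blood
draw. This package implements that pipeline end to end and, because no public
image/bilirubin dataset exists for it, ships a synthetic cohort generator
that reproduces the statistical structure the analysis relies on, so every
stage is testable.

## Synthetic cohort

Total bilirubin is sampled per group from a log-normal distribution:
positive, right-skewed, and fully determined by a median and an IQR ratio.
Defaults target a liver-disease group of 57 subjects (median 5.46 mg/dL, IQR
4.18–13.31) and 31 controls (median 0.85, IQR 0.63–1.11); the log-scale sigma
is solved from `q75/q25 = exp(2 z_0.75 σ)`. Note a two-parameter log-normal
cannot also reproduce the asymmetry of a target IQR about its median (the
geometric mean of 4.18 and 13.31 is 7.46, not 5.46); the generator matches
the median exactly and the quartile *ratio* exactly, and tests compare sample
quantiles against the configured distribution's own theoretical quartiles.

Direct bilirubin is a clipped-Gaussian fraction (mean 0.5, sd 0.12) of total,
so `0 ≤ direct ≤ total` holds by construction. AST/ALT/ALP columns are
generated the same way for table realism and are never used as predictors.
The jaundice label is `total > 3.0 mg/dL` (configurable).

## Synthetic photographs

Each frame contains a reference patch whose true surface color is exactly
white (255, 255, 255) — the left half of the frame, mirroring a sheet of
paper held beside the face — and an elliptical region of interest (RoI). The
RoI's true blue channel is attenuated by the saturating law

    blue = base_blue · (1 − g · B / (B + K)),   g = 0.65, K = 5 mg/dL,

a Michaelis-type curve: scleral yellowing saturates clinically at high
bilirubin but is invertible at low B, which is what makes parameter-recovery
tests meaningful. The whole frame is then multiplied by one per-photo
illuminant gain triplet drawn uniformly from [0.7, 1.2] per channel,
degraded by i.i.d. Gaussian noise (sd 4 intensity units, a plausible level
for 8-bit phone sensors), and clipped to [0, 255].

Illuminant gains above 1 saturate the white patch (and the brightest RoI
pixels) at 255. This is intentional and matters: for those frames the fitted
white balance under-corrects, leaving residual multiplicative color error of
up to ~20 %. That residual is the dominant noise source in the downstream
regression — per-pixel noise averages out over the ~1000-pixel RoI — and it
is what keeps out-of-fold R² in the 0.6–0.9 range rather than ~1.0.

The urine renderer uses the same law but multiplies the attenuation by a
per-subject log-normal confounder (sd 0.5 on the log scale): urine color
responds to hydration and pigments other than bilirubin, so the urine
pathway carries a strictly noisier copy of the signal. Its white reference
is the background itself. Everything is a pure function of (record, scene
config): per-subject streams are derived from the scene seed plus a stable
hash of the subject id.

What the generator does **not** emulate: eyelashes, vessels, specular
highlights, skin-tone diversity, camera tone curves, JPEG artifacts, or any
dependence of scleral color on age and pathology other than bilirubin.
Passing tests therefore demonstrate that the pipeline recovers a known
signal under controlled optics — not clinical performance on real eyes.

## Color correction

The correction is the diagonal von Kries adaptation: gains
`target_c / mean_c` computed from the reference patch's channel means, with
target white (255, 255, 255). It is applied directly in camera RGB — the
correction is defined relative to the photographed reference paper, so by
default no gamma linearization is assumed; a gamma-2.2 linearized variant is
available (`fit_von_kries(..., linearize=True)`), and a cone-space (LMS)
variant is deliberately not offered, since it would require a camera
characterization this protocol does not collect. With an unclipped render
the default correction is exact: corrected(illuminated) equals the
un-illuminated image to 1e-9.

Two saturation caveats are documented rather than hidden. First, outputs are
clipped to [0, 255] after each transform, and the would-be clipped fraction
is logged as a quality metric (warning above 1 %). Second, the diagonal map
centers the corrected patch *exactly* at 255, so with additive noise the
clip necessarily shaves the upper noise tail and biases the clipped patch
mean low by ≈ 0.4 σ; the white-point-fixation property (patch mean = target
within sd/√area) is therefore a statement about the linear map and is tested
pre-clip.

YCbCr uses the full-range BT.601 matrix (the JPEG/phone-camera convention);
the inverse matrix round-trips within half an intensity unit where nothing
clips. Yellowing lowers Cb, which is the channel the models lean on.

## Features and pixel sets

Each subject contributes two representations of the masked RoI after
correction and YCbCr conversion:

* the raw **pixel set** (all N triplets, order-free), and
* a **1567-dimensional feature vector**: per channel a 512-bin normalized
  histogram over [0, 256) (1536 values), ten order/moment statistics per
  channel — mean, population sd, min, max, median, IQR, skewness, excess
  kurtosis, 10th and 90th percentiles (30 values) — and log N (1 value).

The layout is explicit and versioned (`hist512+moments10+logN/1`).
Histograms use half-intensity bins; moment formulas are population (÷n) so
test oracles are unambiguous; skewness/kurtosis of a zero-variance channel
are defined as 0 to keep vectors finite. Channels are sorted before any
statistic is computed, which makes the extraction *exactly* permutation
invariant rather than invariant up to floating-point summation order.

## Models

* **decision_tree** — CART regressor, depth ≤ 8.
* **random_forest** — 500 trees.
* **xgboost** — 300 rounds, depth 4, learning rate 0.1.
* **deepsets** — `f(S) = ρ(mean_{x∈S} φ(x))` with φ: 3→64→64 (ReLU),
  mean pooling, ρ: 64→32→1; squared-error loss, Adam (lr 1e-3), 200 epochs,
  batch 16, implemented in NumPy with manual backpropagation.

The tabular models consume feature vectors; DeepSets consumes pixel sets and
is exactly permutation invariant by construction (mean pooling; prediction
always uses the full set). During training each set is subsampled once
(seeded) to at most 256 pixels: the mean-pooled color statistics the network
can learn are already stable at a few hundred pixels, and training cost is
linear in the cap. A zero-variance target short-circuits to a constant
predictor — the exact optimum — rather than relying on the optimizer to
approximate it. All training is deterministic given (spec, data, seed).

## Evaluation

* **Folds** — stratified k-fold (default 5): subjects are split into
  normal/abnormal strata at 3.0 mg/dL, shuffled with a seeded generator, and
  dealt round-robin, which bounds per-fold stratum counts within 1 of
  proportionality by construction. Out-of-fold predictions are pooled across
  folds before any metric is computed.
* **Regression report** — OLS of truth on prediction (`truth = a + B·pred`);
  slope standard error and p from the slope t-test; R² from the same fit;
  mean difference and its sample sd as agreement statistics. The direction
  (truth on prediction) makes slope ≈ 1 the well-calibrated reading and is
  switchable.
* **AUC** — the Mann–Whitney form via mid-ranks (ties count ½), verified in
  tests against an O(n²) pairwise oracle.
* **Threshold sweep** — for each t in 1.0–4.0 step 0.1, truth is
  re-binarised at t and AUC computed with the continuous predictions as
  scores; grid points where a class vanishes are recorded as undefined and
  excluded; ties break toward the lowest threshold. The confusion matrix at
  the chosen threshold binarises both predictions and truth at that t, and
  precision/recall with a zero denominator raise an explicit error rather
  than returning NaN. When predictions are near-perfect the AUC plateaus at
  1 over much of the grid and the tie-break lands low; with the default
  generator's residual white-balance error the headline models instead tune
  into the mildly-elevated 2–3 mg/dL band, below the 3.0 clinical cutoff.
* **McNemar** — exact two-sided binomial on the discordant pairs
  (`p = min(1, 2·P(X ≤ min(b,c)))`, `X ~ Bin(b+c, ½)`; p = 1 when b+c = 0).
  The exact form (not the χ² approximation) is the defensible choice at the
  small discordant counts a ~90-subject cohort produces.

## Orchestration and reproducibility

`run_experiment` chains simulate → correct → extract → cross-validate →
report for every configured model on both pathways, then compares the two
headline models (default deepsets vs random_forest) with McNemar at each of
their best thresholds. One global seed fans out to per-stage seeds through
`sha256(seed:label)`, so stages are independently reproducible; the report
embeds the seed and a hash of the resolved config, and reruns are
byte-identical. Problem sizes used throughout (88 subjects, 64×96-pixel
frames, 256-pixel training subsamples) are deliberate: they are the smallest
sizes at which every distributional property under test is stable.

## Known limitations

* The 1567-feature layout is a declared reconstruction of a standard color
  feature battery at the stated dimensionality, not a recovered original.
* The illuminant model is diagonal; real mixed lighting and non-linear tone
  curves would violate the von Kries assumption this pipeline (like the
  protocol it implements) relies on.
* Urine confounding is a single multiplicative factor; real urine color has
  structured causes.
* The fallback sclera segmentation (brightness + low chroma inside a user
  box) is a convenience for user-supplied photos, not a validated method.
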