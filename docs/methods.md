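# Methods

## Problem and data model

The package studies whether compression-based complexity indices computed on
simultaneous fetal (FHR) and maternal (MHR) heart-rate recordings can
discriminate acidemic fetuses (umbilical arterial pH < 7.15) from
non-acidemic ones in the last ~2 hours before delivery. Because no public
recording collection with this structure exists, a synthetic cohort generator
stands in for the clinical data: it defines the study conditions under which
every test and the acceptance script run.

Each synthetic subject is a pair of 4 Hz series:

- **MHR** = 80 bpm baseline + slow sinusoid mixture (three components with
  random periods of 2–20 min) + stationary AR(1) noise (lag-1 coefficient
  0.95, marginal SD 2 bpm), clamped to [40, 150] bpm.
- **FHR** = 140 bpm baseline + slow sinusoid mixture + AR(1) noise (SD 3 bpm)
  + Gaussian-shaped acceleration/deceleration bumps (±10–25 bpm, 15–60 s
  wide, ~1 per 10 min) + a coupling term: 0.10 × the mean-centred MHR lagged
  by 2 s, clamped to [60, 200] bpm.

Recording durations are drawn as 119.3 ± 1.0 min (uniform jitter), matching a
cohort whose median duration is just under two hours; the default cohort is
54 non-acidemic and 7 acidemic subjects. Maternal samples are lost in short
contiguous runs (1–4 samples) totalling a fraction 1e-4 of the record — the
reported average maternal loss, read as 0.01 % (a 1 % option is one config
key away). pH labels are drawn uniformly in [7.00, 7.14] (acidemic) and
[7.16, 7.37] (non-acidemic), consistent with the 7.15 cutoff and the observed
range of term cord-blood pH.

**The acidemia effect is a single dimensionless knob.** With effect size
`s`, acidemic subjects have their FHR AR(1) SD divided by `(1 + s)` (reduced
fast-fluctuation complexity) and their maternal→fetal coupling multiplied by
`(1 + s)` (stronger dependence on the mother, as reported for pathological
coupling). At `s = 0` the groups are exchangeable by construction. The
clinical literature does not quantify these differences, so `s` is a free
simulation parameter, not an estimate; tests use `s = 2` as a "strong,
detectable" condition and `s = 0` as the null.

What the generator does *not* emulate: beat-to-beat RR dynamics, uterine
contractions, gestational-age or labor-stage nonstationarity beyond the slow
sinusoids, and any mechanistic cardiovascular physiology. Passing tests show
the pipeline recovers a planted complexity/coupling effect of this specific
form; they say nothing about effect sizes or confounders in real
cardiotocography.

## Pre-processing

1. The maternal series is shifted by +50 bpm (scale conversion) so both
   channels share the fetal artifact thresholds.
2. Artifact rules: a sample is invalid if it is a gap marker (NaN), below
   60 bpm, above 200 bpm, or differs from the previous valid sample by more
   than 25 bpm. Invalid runs of ≤ 2 s are filled by linear interpolation
   between their valid neighbours; longer runs are filled by replicating the
   immediately preceding valid stretch of equal length (falling back to the
   following stretch, then to the nearest valid value, at recording edges).
   Rules are re-applied up to 5 passes because a replication can create a new
   >25 bpm step at its boundary.
3. The pair is truncated to the shorter channel (tail removed).
4. Trend = centered moving average over 17 samples (8 before, 8 after: a 2 s
   real-time delay at 4 Hz); residual = signal − trend on the trend's
   support; trend + residual reconstructs the signal exactly there.
5. Each component is cut into consecutive 10-minute segments **anchored at
   the recording end**, labelled h1-a…h1-f, h2-a…h2-f, so h2-f is always the
   last 10 minutes before delivery; a leading partial segment is kept only if
   strictly longer than 5 minutes. End-anchoring is a deliberate choice the
   source description leaves open: the final minutes are the clinically
   critical window, so the partial segment lands at h1-a.

## Quantization

Compression of symbol streams needs a finite alphabet. Each (subject,
channel, component) series is quantized by its own Lloyd-Max scalar quantizer
(20 levels by default): levels are cell centroids, boundaries are midpoints
of adjacent levels, iterated to a fixed point (tolerance 1e-6 bpm, ≤ 500
iterations; initialization at equally spaced empirical quantiles; an emptied
cell is re-seeded at its boundary midpoint). Fitting on the full preprocessed
series and reusing the codebook across that subject's segments keeps
between-segment comparisons in a common symbol space; trend and residual get
separate codebooks because their dynamic ranges differ by an order of
magnitude. The implementation works on sorted-sample cumulative sums, so each
iteration is O(L log n).

## Compression indices

- **Compression ratio** (per segment): serialized byte length over
  zlib/DEFLATE-compressed length, level 9. Serialization is 1 byte/sample,
  nearest-integer bpm clamped to [0, 255]; residuals are serialized with a
  +128 offset so their signed, near-zero values occupy the middle of the byte
  range instead of clamping at 0. The maternal-fetal variant compresses the
  fetal-then-maternal byte concatenation of simultaneous segments.
- **NRC** (normalized relative compression): `C(x||y) / (|x| log2 |A|)`,
  where `C(x||y)` is the ideal code length of `x` under an extended-alphabet
  finite-context model trained exclusively on `y` — the model predicts the
  next `d`-symbol block from the `k` preceding symbols (defaults k = d = 6,
  |A| = 20). `x` is coded in non-overlapping d-blocks after `k` bootstrap
  symbols; contexts may straddle block boundaries. Per-block code length is
  capped at `d·log2|A|` and bootstrap/partial symbols cost `log2|A|` each, so
  NRC ∈ [0, 1]. Only ideal code lengths are computed; no bit-exact arithmetic
  coder is emitted.
- **Smoothing.** Block probabilities are additively smoothed over the
  `|A|^d` block space. The pseudo-count default is `alpha = |A|^-d` (total
  pseudo-mass of one count) rather than 1: at the default operating point
  `|A|^d ≈ 6.4e7`, unit pseudo-counts would dominate the ~2 400 real counts
  of a 10-minute segment, pinning every code length at the cap and every NRC
  at ~1 — destroying the measure's dynamic range. With the scaled default,
  NRC on synthetic segments lands in the 0.3–0.8 range typical of
  heart-rate material. `alpha` remains configurable.
- **NCD** (normalized compression distance):
  `(C(xy) − min{C(x), C(y)}) / max{C(x), C(y)}` with zlib code lengths, the
  concatenation always fetal-then-maternal.

## Feature table

Nine index families × two components: fetal/maternal/maternal-fetal
compression ratio, maternal-fetal NRC and NCD on simultaneous segments
(x = fetal, y = maternal: the fetus's dependence on the mother), and
fetal/maternal NRC and NCD *over time*, each segment against the same
channel's **reference segment**. Features from the first 30 minutes are
eliminated (short recordings make that window inconsistent across subjects),
so the reference is the first retained segment (h1-d); its self-comparison is
excluded. A full recording therefore yields 77 columns per component: 5
families × 9 segments (h1-d…h2-f) plus 4 over-time families × 8 segments
(h1-e…h2-f). Columns any subject lacks (duration jitter) are dropped
cohort-wide.

Collinearity reduction: greedy, in canonical column order, removing every
column with |Pearson r| > 0.5 to an already-kept column; constant columns go
first. The filter is fitted on training rows only within each
cross-validation fold and frozen before testing. Feature-set tests A–I select
family/component subsets (A/B: all families, trend/residual; C/D: univariate
families only; E/F: maternal-fetal families; G/H: maternal-fetal without the
compression ratio; I: maternal-fetal families, both components).

## Balancing and validation

SMOTE at the feature-table level: each of the 7 acidemic originals seeds 6
synthetic rows `p + λ(q − p)`, with `q` one of its 5 nearest acidemic
neighbours and `λ ~ U[0, 1]`, growing the minority to 49 against 54 (103
cases). Every replica records its seed original.

The replica-aware cross-validation builds one fold per original acidemic
case: test = that original + its 6 replicas + 7 majority cases (sampled
without replacement, disjointly across folds — 7×7 = 49 of 54); train = the
remaining 89 rows, which never contain the held-out original or its replicas.
Predictions are pooled across the 7 folds and the six metrics (accuracy,
recall/sensitivity, specificity, precision, F1, ROC AUC with acidemic
positive) are computed once on the pooled set; per-fold averaging is
available as an option. A stratified 20-fold scheme is provided as the
conventional alternative. The SVM (RBF kernel, balanced class weights,
probability scores, features standardized in-pipeline) is the default
classifier, with random forest and XGBoost for parity; hyperparameters come
from a grid search (SVM: C ∈ {0.1, 1, 10, 100}, γ ∈ {scale, 0.01, 0.1, 1})
with inner stratified 3-fold CV scored by F1 on the training rows only.

## Known limitation: augmentation leakage under the null

The replica-aware scheme removes the held-out original's *own* replicas from
training, but it cannot remove other originals' replicas that interpolate
*toward* the held-out case: a training replica `p + λ(q − p)` with `q` the
held-out original and `λ` near 1 is a near-duplicate of the held-out case,
present in training with the positive label. With an expressive classifier
this inflates null performance dramatically: on zero-effect cohorts the
pooled custom-CV AUC measures ≈ 1.0 rather than ≈ 0.5 (held-out originals
score ~0.94, majority ~0.02). This is an inherent property of applying SMOTE
to the whole table *before* cross-validation; the only complete fix —
augmenting inside each training fold — would change the published procedure
this package reproduces, so it is documented rather than silently applied.
Consequence: absolute performance numbers from this validation scheme should
not be read as generalization estimates; between-feature-set *comparisons*
(tests A–I) remain informative because all share the same inflation.

## Numerical and design choices

- All randomness flows from one integer seed through `numpy` SeedSequence
  fan-out; cohorts, SMOTE, fold draws and classifiers are bit-reproducible.
- Integer-encoded contexts/blocks (base-|A| codes in int64) make FCM fitting
  a vectorised unique-count; code lengths are exact to float accumulation,
  with the total clamped at `|x| log2|A|` to keep the NRC bound exact.
- Problem sizes in the test-suite property checks (cohort sizes, durations,
  replication counts) are scaled to keep the full suite in a few minutes
  while leaving each statistical check comfortably powered; the
  parameter-recovery checks always use the full 61-subject study conditions.
- Degenerate inputs: cleaning refuses all-invalid series; quantization
  requires ≥ L distinct values; SMOTE requires ≥ 2 minority rows (a cohort
  with a single acidemic case fails the balancing stage, and the run manifest
  records the failure).
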