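# Methods

## Data model

The unit of analysis is a GC-IMS integration table: one row per volatile
compound feature, identified by `A<number>` (A1–A115).  A compound present
at high concentration produces proton-bound dimer ions with the same
retention time but longer drift time than the monomer, so one chemical
species can contribute two features (`-M`/`-D`); species-level counts
collapse such pairs.  Nineteen features have no database identity and carry
numeric labels; they are first-class features throughout (several rank among
the most class-informative).  Feature order everywhere is the numeric
identifier order, not the table's class-grouped row order, so model inputs
have a canonical, documented column ordering.

Per origin city (Rongcheng = 0, Dalian = 1, Xiapu = 2; n = 30 each) the
table stores the intensity mean, standard deviation and Duncan letter, plus
a per-feature ANOVA p-value.  p-values printed as `<0.001` are stored as a
bound with a placeholder value of 0.0005; every comparison consults the
bound (`p < alpha` is true iff `bound <= alpha`), never the placeholder.

## Synthetic cohorts

The raw 90-sample dataset behind the table is not public.  The generator
emulates the study design: for origin *o* and feature *j* it draws
`n_per_origin` (default 30) independent values from
Normal(mean[o,j], (sd_scale · sd[o,j])²).  Choices that matter:

- **Independence across features.** Only marginal moments are published;
  inventing a covariance would be unsupported.  A user-supplied feature
  correlation matrix is accepted (`generate_cohort(..., covariance=...)`)
  but none ships.  Consequence: synthetic cohorts are *easier* to classify
  than real data with correlated features; passing tests demonstrate
  pipeline correctness, not field performance.
- **No truncation at zero by default.** Intensities are physically
  non-negative and a `clip_at_zero` option exists, but it is off by
  default: the widest-SD rows (mean/SD ratios down to ≈ 0.54, e.g.
  3-methyl butanoic acid-M in Rongcheng, 1755.2 ± 3254.1) would have ≈ 29%
  of draws clipped, which raises that group's mean by roughly 600 a.u.,
  shrinks its variance, and turns a tabulated p = 0.062 feature into one
  that screens significant in every seed (pushing the median selected count
  to ≈ 109.5 instead of 107).  Unclipped Gaussian draws reproduce the
  tabulated moments exactly, which is the property every downstream check
  relies on; the rare negative values are harmless to ANOVA and z-scoring.
- **Normality** is an assumption matching the mean ± SD summary, not a
  claim about GC-IMS noise.

Determinism: one integer seeds a `numpy` PCG64 generator; identical seeds
give bit-identical cohorts.

## Screening

Classical fixed-effects one-way ANOVA per feature across the three origin
groups: F = MS_between/MS_within with (k−1, N−k) degrees of freedom
(87 within-group df at the default design).  Degenerate inputs are defined
explicitly: all values identical → F = 0, p = 1; zero within-group variance
with separated means → F = ∞, p = 0.  Selection keeps features with
p < 0.05 (strict) and no multiple-testing correction, matching the
per-feature reporting convention of GC-IMS origin studies; screening runs
on the full cohort before splitting (the selection is part of the
descriptive analysis), and users who prefer leakage-free screening can pass
the training cohort instead.

Duncan's multiple range test supplies the letter display: means are ranked
descending and a stretch of *p* adjacent means is homogeneous when its span
is at most

R_p = q(1 − (1−α)^(p−1); p, df) · √(MSE / n_h),

with q the studentized-range quantile (scipy, values cached — the ppf is
expensive) and n_h the harmonic mean group size.  A range contained in a
homogeneous stretch is never tested (the protection rule), and letters are
assigned to maximal homogeneous intervals, `a` starting at the largest
mean.  For two groups the procedure reduces to a t-test through
q(2, df) = √2 · t_{α/2}(df), which the test suite uses as an independent
oracle.

## Classifier

Input is the screened, standardized feature vector (107-long at tabulated
values; the width adapts to the realized selection).  Architecture:

    conv1d(kernel 3, 4 filters, valid) → ReLU → maxpool(3, stride 3)
    conv1d(kernel 3, 8 filters, valid) → ReLU → maxpool(3, stride 3)
    flatten → dense(32) → ReLU → dense(3) → softmax

Pooling windows do not overlap and trailing remainders are dropped:
107 → 105 → 35 → 33 → 11, flatten 11·8 = 88.  Parameters:
(3·1+1)·4 + (3·4+1)·8 + (88+1)·32 + (32+1)·3 = 3 067.  The filter widths
(4, 8) are pinned by this arithmetic: 8 second-layer channels are forced by
the 88-long flatten, and 4 first-layer channels is the unique width for
which the parameter count rounds to 3.1 K and the FLOP tally to 16.1 K.

FLOP convention (one forward pass): 2 FLOPs per multiply–accumulate in conv
(2·k·C_in·C_out·L_out) and dense (2·n_in·n_out) layers, one add per bias
application, `pool_len` comparisons per max-pool output element;
activations and softmax excluded.  Per layer at the reference geometry:
2520+420 (conv1), 420 (pool1), 6336+264 (conv2), 264 (pool2), 5632+32
(dense1), 192+3 (dense2) = 16 083.

Training: mini-batch Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-7), categorical
cross-entropy, 100 epochs, batch size 16, learning rate 1e-3, seeded
shuffling, Glorot-uniform initialization with zero biases.  Batch size,
learning rate and initialization are conventional defaults, all exposed in
the constructor.  Forward and backward passes are plain numpy (strided
windows + einsum); correctness is enforced by two mandatory oracles in the
test suite — a pure-loop forward implementation agreed to 1e-9, and central
finite differences agreed to 1e-4 relative on every weight.  The per-epoch
history records full-training-set loss (nats) and accuracy after each
epoch.  Training is bit-reproducible for a fixed seed.

## Evaluation protocol

The split precedes all preprocessing: stratified 7:3 with
floor(n_c · 0.7) per class and remainder seats by largest fractional part,
so 90 balanced samples yield exactly 63/27 (21/9 per origin).  The z-score
scaler (population-SD convention, via scikit-learn's `StandardScaler`) is
fitted on training rows only; there is no fit-on-test entry point, and
zero-variance columns transform to 0 with a warning.

Predicted label = argmax of the softmax row, ties to the lowest class
index.  Multiclass accuracy is trace(confusion)/n; precision, recall and F1
are computed per class from the one-vs-rest reading of the confusion matrix
and macro-averaged (on a perfectly classified test set every averaging rule
coincides).  ROC curves sweep thresholds over each class's probability
column; AUC is the trapezoidal area, which equals the Mann–Whitney
concordant-pair statistic (ties at half credit) — the test suite asserts
that equality exactly on random instances.

## Shapley attribution

The value function never retrains anything: v(S) fixes features in S at the
explained sample's values and replaces the rest with background values —
every background row in turn with outputs averaged (`sample-average`,
default, background = standardized training set) or the single background
mean (`mean-vector`).  v(∅) is then the model's mean output over the
background — the force-plot base value, ≈ 1/3 per class for a balanced
training set and a well-calibrated model — and v(F) = f(x).

- **Exact enumeration** over all 2^|F| coalitions for ≤ 15 active features:
  the oracle route, satisfying efficiency/dummy/symmetry/linearity to
  floating-point precision (property-tested).
- **Permutation sampling** at full width: marginal contributions averaged
  over seeded random orderings, each paired with its reverse (antithetic).
  Per-ordering telescoping makes the estimate satisfy additivity by
  construction; a proportional residual correction (shares ∝ |φᵢ|) is
  applied defensively and the raw residual reported.  Empirical error
  decays as O(n_perm^(−1/2)) (asserted as a log-log slope bound).
- Explanations operate on softmax probabilities in standardized input
  units (the base value is then a probability); a subset of features may be
  explained with the remainder held at background.

Global importance is the per-feature mean |φ| per class plus the stacked
sum across classes, ranked descending with ties kept in feature order.  On
synthetic cohorts the specific top-feature ranking differs from the real
study's (independent features cannot reproduce correlated-feature
attributions), so rankings are logged, not asserted.

## Problem sizes in the test suite

The default suite trains the reference 100-epoch network on the 90-sample
design once (shared fixture) plus twenty 20-seed replicates in the
acceptance checks; moment-recovery scans use 200 generator seeds, the
type-I-error calibration uses 1 000 null features, and Monte-Carlo
Shapley/permutation comparisons use a few thousand orderings on ≤ 9-feature
toys.  These sizes keep the full suite under a minute while leaving every
statistical bound comfortably powered.

## Known limitations

- No feature covariance, batch effects, instrument drift or censoring in
  the generator; it validates the pipeline, not the instrument.
- Duncan's test is implemented in its classical form only (no
  Welch/Kruskal–Wallis alternatives; equal-variance assumption inherited
  from ANOVA).
- The CNN is CPU-only numpy and intended for feature vectors of a few
  hundred elements, not spectra of thousands of points.
- Permutation Shapley cost scales linearly in features × orderings ×
  background rows; for 107 features with a 63-row background, explaining a
  sample at the default 4 antithetic pairs takes on the order of a second.
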