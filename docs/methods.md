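# Methods

## Overview

`fibrospec` implements a binary spectral-diagnostics pipeline for plasma
ATR-FTIR data: preprocessing → stratified Kennard–Stone partitioning →
variable engineering (PCA / SPA / GA) → discriminant classification
(LDA / QDA / SVM) → figures of merit on an external test set. Because no
patient spectra are distributed with the package, a synthetic generator
with known ground truth stands in for the cohort; everything downstream is
agnostic to the data's origin and accepts any wide-format spectra CSV.

## Synthetic cohort model

Each subject's noise-free spectrum is a sum of Gaussian bands
`Σ_b a_b · exp(−(ν − c_b)² / 2w_b²)` on the 900–1,800 cm⁻¹ axis at
4 cm⁻¹ spacing (226 points, matching a 4 cm⁻¹ acquisition resolution).
Band centers are the 24 marker wavenumbers of the packaged assignment
table plus the dominant Amide I band at 1,652 cm⁻¹; amplitudes are fixed
package choices giving an Amide-I-dominated profile (peak ≈ 0.5 AU,
Amide II ≈ 0.3 AU, carbohydrate/phosphate structure 0.04–0.09 AU) with
widths of 7 cm⁻¹ (16 cm⁻¹ for Amide I, 12 cm⁻¹ for its neighbours).
Gaussian line shapes were chosen over Lorentzian/Voigt as the simplest
model sufficient for exercising the pipeline.

Hierarchical noise, per replicate row:

```
row = scatter · (band_sum + baseline) + noise
```

- **Per-subject amplitude jitter** — each band amplitude is multiplied by
  `exp(N(0, subject_sd²))`, `subject_sd = 0.02`, so a subject's replicates
  share one biological state and replicate averaging is meaningful.
- **Class effect** — case subjects' amplitudes at the `effect_bands`
  (default: all 24 marker bands) are scaled by `1 + effect_size`
  (default 0.3). A multiplicative shift preserves non-negativity and
  mimics concentration differences.
- **Baseline** — a random polynomial of degree `baseline_order` (default
  2) with i.i.d. standard-normal coefficients on a [−1, 1]-scaled axis,
  scaled to `baseline_scale = 0.02` AU.
- **Scatter** — per-replicate factor `exp(N(0, scatter_sd²))`,
  `scatter_sd = 0.05`, emulating contact-pressure/thickness variation.
- **Noise** — additive i.i.d. `N(0, noise_sd²)`, `noise_sd = 0.005` AU.

The default cohort is 126 + 126 subjects in triplicate (756 rows). The
noise magnitudes are package choices — within-triplicate variance of real
plasma ATR measurements is not characterised in any source the defaults
could be pinned to. With all four noise knobs at zero the generator
returns the deterministic band sum bit-exactly, which the tests rely on.

What the generator does **not** emulate: water-vapour interference bands,
liquid- vs dried-film sampling differences, session-to-session instrument
drift, correlated (pink) detector noise, and any covariance structure
between bands beyond the shared per-subject jitter. Consequently a
pipeline that separates this synthetic cohort perfectly is shown to be
*correct*, not shown to reach any particular performance on clinical
data; the synthetic problem at the default 30% effect is considerably
easier than a real case/control cohort.

## Preprocessing

Order: truncate → Savitzky–Golay → AWLS baseline → vector normalise.

- **Truncation** keeps the closed interval [900, 1,800] cm⁻¹.
- **Savitzky–Golay** (window 9, order 2 by default) requires a uniform
  axis (1e-6 relative tolerance). Edges are handled by evaluating the
  polynomial fitted over the full-length window anchored at the spectrum
  end — asymmetric about the evaluated point, no padding.
- **AWLS baseline**: per row, a degree-2 (default) polynomial is fitted
  by iteratively reweighted least squares — points above the current fit
  get weight 1e-3 (a small floor kept for conditioning), points at/below
  keep weight 1 — until the baseline's maximum relative change drops
  below 1e-6 or 50 iterations (then a warning, last iterate used). This
  is the standard "automatic weighted least squares" behaviour of
  commercial chemometrics toolboxes. The Vandermonde basis is built on a
  [−1, 1]-scaled axis for conditioning.
- **Vector normalisation** divides each row by its Euclidean norm; an
  all-zero row is an error naming the sample.

Every stage is positively homogeneous up to the final normalisation, so
the full chain is *exactly* invariant to multiplying any input row by a
positive constant — the scatter-removal claim, asserted in the tests.

Replicates are averaged per subject *before* partitioning, so no subject
can contribute rows to two sets (leakage prevention).

## Partitioning

Kennard–Stone ranking: start with the two mutually most-distant samples
(Euclidean distance on the preprocessed spectra), then repeatedly add the
sample maximising the minimum distance to the selected set. All ties
break to the lowest row index, making the procedure deterministic with no
RNG. The split is stratified: within each class the first
`round(0.70·n)` ranked samples train; the remainder is re-ranked and its
first `round(0.15·n)` samples validate; the rest test. For 126 + 126
samples this yields 176/38/38 with 19 + 19 cases/controls in test. The
per-class variant was chosen because pooled Kennard–Stone cannot
guarantee the exact class balance the test-set metrics imply.

## Variable engineering

All selectors see only training and validation rows.

- **PCA**: mean-centered, via SVD; loadings sign-fixed so each one's
  largest-magnitude entry is positive; rank-deficient requests truncate
  with a warning. The component count is the smallest k reaching 95%
  cumulative explained variance, capped at 10.
- **SPA**: from every starting column (deterministic, no random
  restarts), a chain is grown in which each next column has the maximal
  norm after projection onto the orthogonal complement of the chain's
  span (computed on the centered training matrix). Every chain prefix is
  a candidate; candidates are scored by LDA validation misclassification;
  ties prefer fewer variables, then earlier scan order. Default cap: 20
  variables per chain.
- **GA**: binary masks over the 226 columns; fitness = LDA validation
  accuracy − 0.05 · (selected/total) (a soft parsimony pressure toward
  marker-scale subsets of tens of variables, not a hard cap);
  tournament selection of size 2, one-point crossover (p = 0.6), per-gene
  bit-flip mutation (p = 0.01), 1-elite, population 40, 100 generations,
  initial per-gene activation probability 0.1. An all-zero chromosome
  receives −∞ fitness. Fully reproducible from the seed; the best-ever
  fitness is non-decreasing (elitism), asserted in tests.

The selection cost is LDA-based for both SPA and GA regardless of the
downstream classifier — the standard choice in wavelength-selection
practice — so in the nine-pairing benchmark each selector runs once and
its variables are shared by LDA, QDA and SVM.

## Classification

LDA and QDA are implemented directly from their Mahalanobis score forms
(see README). Per-class covariances use the n−1 denominator; the pooled
covariance is their (n_k − 1)-weighted average; priors are training
proportions (0.5/0.5 for balanced cohorts). When any covariance's
condition number exceeds 1e10 — GA/SPA subsets can be nearly collinear —
a ridge of 1e-8 × mean(diag) is added as ε·I before inversion. Prediction
assigns the class with the minimal score; ties break to the first class
in sorted label order ("case" before "control"). The wording ambiguity
around the QDA covariance ("pooled variance–covariance matrix of class
k") is resolved as the ordinary per-class covariance — standard QDA.

The SVM's soft-margin dual is solved by scikit-learn's SVC; the package
stores only the support vectors, multipliers α_i > 1e-8, labels
y_i ∈ {−1, +1} (case → +1) and bias, and evaluates the kernel-expansion
decision rule itself, with sign(0) defined as +1. Linear kernel by
default; the box constraint is tuned on the validation set over
{1, 10, 100}; an RBF kernel with explicit γ is available.

## Figures of merit and benchmark

With "case" as the positive class: accuracy = 100·(tp+tn)/n,
sensitivity = 100·tp/(tp+fn), specificity = 100·tn/(tn+fp). Values are
stored at full precision and rendered to one decimal; a truth vector
lacking one class makes the undefined metric NaN with a warning, never a
silent zero. The benchmark runs all nine pairings, scores the test set
exactly once per pairing, records per-row failures without aborting the
rest, and is bit-for-bit reproducible from its seed. Marker assignment
matches query wavenumbers to the nearest of the 24 packaged bands within
a 4 cm⁻¹ tolerance (one axis step).

## Problem sizes

The shipped analysis and the acceptance script use the full study-scale
cohort (252 subjects, 226 variables); a complete nine-pairing benchmark
including the GA takes a few seconds on one CPU. The test suite's
Monte-Carlo checks use 10 seeded repetitions at full cohort size for the
end-to-end recovery property and smaller cohorts (12–30 subjects per
class) for distributional properties.

## Known limitations

- SPA restarts from *every* column, which is O(p) LDA fits per chain
  prefix; for axes much longer than a few hundred points a random-subset
  restart strategy would be preferable.
- The GA's hyperparameters are sensible defaults, not tuned; on the
  synthetic cohort the signal is strong enough that tuning is moot.
- Only two-class problems are supported end to end (the discriminant
  scores generalise to K classes, the SVM coding and figures of merit do
  not).
- CSV is the only I/O format; instrument-native formats (OPUS, SPC,
  JCAMP-DX) must be converted externally.
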