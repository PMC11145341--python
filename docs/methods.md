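# Methods

## The transform

PERCEPT replaces binary p-value thresholding with a continuous shrinkage
of each measured effect toward a hypothetical mean m₀:

    V = m₀ + (m₁ − m₀) · F^(−p),   s = F^(−p) ∈ (0, 1] for F ≥ 1

where m₁ is the replicate mean, p the p-value of a one-sample t-test of
the replicates against m₀ (two-sided by default; one-sided exposed as an
option), and F > 0 the penalty factor. The transform is an affine
interpolation between the measurement (p = 0) and the hypothetical mean
scaled by 1/F (p = 1); it is equivariant under affine changes of units
and monotone in both p and F. F ≤ 1 is permitted but warned about, since
it amplifies rather than suppresses low-confidence effects. F = 10·n is
surfaced as the `auto` default, a starting point for tuning only — the
analyses here also use a fixed F = 20 for five-replicate subsets, and
both choices remain free parameters.

Numerics: F^(−p) is evaluated as exp(−p·ln F) for stability at large F.
When s = 1 exactly (p = 0) the measurement is returned verbatim rather
than through the algebraic form, which can otherwise lose the tail of m₁
to cancellation when |m₀| ≫ |m₁|.

Degenerate replicate vectors (zero sample variance) take the continuous
limit of the t-test: p = 0 when the common value differs from m₀ (a
consistent deviation is infinitely confident and fully preserved) and
p = 1 when it equals m₀. Missing values are dropped per feature before
computing n, mean and sd; features left with n < 2 yield flagged null
outcomes (NaN row) so whole-table runs never abort.

## Cohort workflow

Intensity tables (features × donors, strictly positive) are converted to
per-donor log2 ratios against the *linear-space* control-cohort mean of
each feature. Note the lognormal consequence: even for null features the
mean log2 ratio carries a Jensen offset of −ln2/2·σ² and extra spread
from the control-mean estimate; the synthetic-data tests encode this
closed form rather than the naive N(0, σ/√n) approximation.

Data-driven effect thresholds come from a pseudo-control distribution:
the control cohort is compared against a label-randomized version of
itself (per feature, donor labels are permuted with a seeded generator
and each donor's value is divided by the permuted cohort's mean for that
feature), all log2 ratios are pooled, and the (1−c)/2 and 1−(1−c)/2
quantiles are returned (5th/95th percentiles at the default 90%
coverage, linear interpolation between order statistics). Because the
pooled mean is permutation-invariant, this reduces to each control
value over its feature's control mean; the permutation is kept behind a
single function so alternative randomizations (e.g. random cohort
splits) can be swapped in. The bounds are deliberately not symmetrized.

Volcano categories cross two strict booleans: "affected" (effect
strictly outside (lower, upper)) and "significant" (p < α, default
0.05, i.e. −log10 p > 1.3). Significant-but-inside points get their own
S/NA label so the four categories partition the plane.

A caveat the demo makes visible: the pseudo-control thresholds describe
*per-donor* ratio variability, while categorization applies them to
per-feature *mean* ratios. When per-donor noise is large relative to the
true effects (as in the subsampling evaluation conditions below), the
data-driven thresholds exceed every mean effect and no feature is
"affected" — a faithful property of the thresholding recipe, not a bug.

Cross-study compilation uses max-abs normalization: every value divided
by the table-wide maximum absolute value, scaling each dataset
symmetrically into [−1, 1] without moving the center of 0.

## Imaging demonstration

A binary (0/1) ground-truth image is corrupted with i.i.d. Gaussian
noise (sd 1 by default, the parameter-free reading; exposed as an
option) across n replicates. The large-n population is n = 100; the
small-n subset (default 5) is drawn from it by seeded sampling without
replacement. Per pixel, PERCEPT tests the replicate values against the
ground-truth value and shrinks the replicate mean by F^(−p) with F = 20.
The scaled value always lies on the segment between the replicate mean
and the truth. Line scans report, per column of a chosen row, the truth,
the mean, the scaled value and the empirical 2.5th–97.5th percentile
band of the replicate values (a parametric interval is deliberately not
assumed at n = 5). Pixels are addressed row-major, (row, column), 0-based.

## Evaluation machinery

Small-n studies are emulated by drawing k = 5 case donors (without
replacement, seeded) 100 times. Per trial, raw per-feature means and
scaled values are compared against the population values (per-feature
mean over all donors unless supplied) via the mean absolute per-feature
difference, with pairwise-complete dropping of missing features. All
distances are then normalized to the mean raw distance across trials, so
the mean normalized raw distance is exactly 1 and the mean normalized
scaled distance reads as a fraction of the raw error.

Cumulative distributions are aligned for averaging by interpolating each
trial's empirical CDF at 101 equidistant increments (0, 0.01, …, 1)
using the nearest empirical position; the i-th order statistic sits at
position i/n (so the maximum maps to 1.0) and ties are broken toward the
lower position. Agreement is summarized Bland–Altman style: mean
difference of the paired values and mean ± 1.96·sd (n−1 denominator) as
95% limits of agreement. Cross-dataset correlation uses Pearson R on
pairwise-complete shared features (pairs with fewer than 3 shared
features are flagged null), tagged "inside" when the two datasets share a
disease label and "outside" otherwise.

## Synthetic data

The cohort generator draws per-feature baselines from a log-normal
(natural-log mean 14, sd 2 — a multi-decade dynamic range typical of
label-free intensity data; the values are arbitrary units and fully
overridable) and per-donor multiplicative noise of sd `noise_sd_log2` on
the log2 scale. A fraction of features carries a fixed-magnitude log2
effect with random sign (so volcano plots are two-sided) in the case
cohort only. Defaults are 500 features, 20 control and 40 case donors,
30% affected at |log2 effect| 0.5 with noise sd 0.6 — the study
conditions used by the subsampling evaluation. An `effects` override
lets two simulated studies share one ground truth with independent
noise, which is how the cross-study correlation property is exercised.

What the generator does *not* emulate: missingness mechanisms, batch or
center effects, peptide-level quantification, mean-variance dependence,
or correlated features. Passing tests therefore demonstrate the method's
behaviour under clean lognormal noise with known truth, not performance
on any real cohort; dataset-specific published figures (e.g. percentage
of features per category, or the exact fraction by which scaled
summaries are closer to the population) are properties of real data and
are not reproduced here — only their directions are asserted.

## Problem sizes and determinism

The test and evaluation problem sizes — 64×64 images with 50 seeded
repetitions, 500-feature cohorts with 100 subsampling trials — are the
package's chosen demonstration scale; all are parameters. Every source
of randomness flows through explicit integer seeds; the scale workflow
derives per-stage substreams from its single seed via a CRC32-keyed
`SeedSequence` spawn so adding a stage never perturbs another stage's
draws. Output tables are serialized at 6 significant digits by default
(full precision behind a flag), and reruns with the same config and seed
are byte-identical.

## Known limitations

- PERCEPT is not a frequentist estimator; scaled magnitudes are
  deliberately flattened (by up to 1/F) and should not be read as
  unbiased effect sizes.
- With large n, p-values for real effects collapse toward 0 and scaling
  approaches mean smoothing; the method is designed for small n.
- The one-sample t-test assumes approximately normal replicate noise on
  the tested scale; heavy-tailed noise will distort p and hence s.
- No multiple-testing correction is applied anywhere: the transform
  consumes raw p-values by design.
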