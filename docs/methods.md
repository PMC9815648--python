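# Methods

This note documents the statistical procedures the package implements,
the synthetic-data model used to validate them, the defaults and why they
were chosen, and the places where a genuine design choice had to be made.

## Connectivity and strength scoring

Block-wise functional connectivity is the Pearson correlation between
parcel time series restricted to a block's TR window (0-based, half-open
`[onset, offset)`; a configurable `lag_trs` shifts the window to absorb
hemodynamic delay). Correlations are clipped to |r| ≤ 1 − 1e−6 before the
Fisher transform so a degenerate block (e.g. duplicated parcels) yields a
large finite edge value rather than poisoning every downstream aggregate.
Blocks shorter than 3 TRs or containing a zero-variance parcel are
errors, not silent NaNs.

Network strength sums each undirected edge **once** (upper triangle),
weighted by the mask sign. Summing the full symmetric matrix would simply
double every strength and leave all correlation-based results unchanged;
the unique-edge convention is used because it matches the edge counts the
masks are described by.

Motion exclusion is strict-inequality on both framewise-displacement
summaries: a run/block is retained iff `fd_mean < 0.2 mm` **and**
`fd_max < 2 mm` (the liberal profile uses 0.5/5). Exact-threshold values
are excluded; the boundary choice is asserted by test.

The optional denoiser regresses confound columns out of each parcel
series (least squares, demeaned) and then band-passes by zeroing FFT bins
outside 0.008–0.12 Hz. FFT masking was chosen over an IIR filter because
it is deterministic and parameter-free; it is applied per run *before*
block extraction, fixing the otherwise-ambiguous order of operations as
denoise → extract → correlate.

Subjects with no retained block in a condition are dropped from
across-subject analyses (logged), never imputed.

## CPM

Edge selection keeps an edge, signed by its correlation, when the
two-tailed Pearson p (t transform, n−2 df) is below α = 0.01. Selection
p-values are deliberately not multiplicity-corrected: the edge *sets*,
not individual edges, are the inferential unit. Leave-one-site-out
training fits one mask per held-out site on all other sites' subjects;
training connectomes average **all** task blocks of both conditions,
while evaluation strengths may be condition-specific. The consensus mask
averages signed site indicators and binarizes at |mean| ≥ 0.5 —
inclusive, so an exact even split of votes survives. Averaging *signed*
indicators means sign-conflicting edges attenuate toward zero and
typically drop out; this is the interpretation adopted where the
binarization convention was underdetermined.

Empirical p-values against random size-matched edge sets use the add-one
convention p = (1 + #{null ≥ observed})/(n_null + 1), so an effect beyond
all 200 null draws reports 1/201 — strictly positive and below the 1/200
resolution of the null family.

## Overlap statistics

The overlap of two edge sets (sizes K and N, intersection x, pool
M = P(P−1)/2) is tested with the hypergeometric upper tail. The default
is the literal `1 − F(x) = P(X > x)`; `P(X ≥ x)` is computed alongside
because the two conventions differ at the third decimal at typical
counts, and reporting both makes the choice auditable. Both are evaluated
through scipy's log-space survival function, stable at M ≈ 35,778.
Overlap percentages use the union denominator K + N − x ("percent of
combined edges").

## Lesioning

Lesioning removes every mask edge with at least one endpoint in a
region. Predictive power is R² from OLS of behavior on strength; the
default model is univariate with covariates available behind a flag
(minimal assumption, since the covariate set of the original analyses is
not recoverable). A fully lesioned (constant) strength is defined to have
R² = 0 — a constant predictor explains nothing. The group comparison
bootstraps subjects within group (sizes fixed), recomputes the ΔR²
difference per iteration jointly, and reports a symmetric add-one
two-sided p. Because strength is linear in the edge matrix, recomputing
strength under the lesioned mask is mathematically identical to
subtracting the removed edges' sum; the identity is asserted by test.

## Two-group behavioral PLS

The cross-block matrix R has one row per group: the within-group Pearson
correlation of every edge with behavior, with edges and behavior z-scored
within group (the correlation-PLS convention). This "behavioral PLS with
groups" construction is the central interpretive choice: with two groups
and one behavior it yields exactly two LVs, a group-common pattern and a
group-differential pattern, which is the structure the analyses here are
about. Whether behavior should be z-scored within group or pooled affects
only the LV scale, not its identity; within-group was chosen for
consistency with the per-row correlations.

SVD signs are fixed deterministically (each LV oriented so its
largest-|salience| edge is positive) so results are seed-stable. The
covariance fraction σ_XY of an LV is its squared singular value over the
sum of squared singular values.

Permutations shuffle the subject rows of the edge matrix against the
fixed (behavior, group) labels — group sizes are preserved by
construction — and add-one p-values are reported per LV on the singular
values. Bootstraps resample subjects within group; each resample's scaled
saliences U·S are aligned to the original solution by a Procrustes
rotation computed from the design saliences (a per-LV sign-flip
alignment is available as a fallback), and Z_BR is the original scaled
salience over the bootstrap SD, with 0/0 defined as 0 and |Z_BR| ≥ 3
marking reliable edges. Resamples that leave behavior constant within a
group are redrawn and counted. Unequal group sizes are handled by
repeatedly subsampling the larger group to match the smaller, running the
full PLS per replicate, and averaging Procrustes-aligned solutions.

## Auxiliary inference

Williams' t (two dependent correlations sharing one variable) and
Steiger's Z (two dependent correlations with different variables) follow
Steiger's 1980 formulations — the t2 statistic with n−3 df, and the
Fisher-z statistic with the pooled-r̄ covariance estimate. Both are
exactly zero at equality, antisymmetric under swapping, and their type-I
error is Monte-Carlo-calibrated in the tests. d′ uses the log-linear
correction (+0.5 to counts, +1 to totals) by default so perfect
performance stays finite; the correction is configurable to "none"
because the original convention is unknown. The weighted correlation uses
weighted moments throughout and reduces exactly to replicated-data
Pearson for integer weights. Mixed-effects regressions are out of scope;
the package exposes the OLS/correlation layer these helper tests need.

## The synthetic study

The generator emulates the *structure* of a two-group, multi-site,
block-design n-back study; the emulated study is empirical and publishes
no generative model, so all distributions and effect sizes below are
artifact choices, made once and documented here.

Structure (defaults): P = 268 parcels; 754 subjects per group across 18
sites (round-robin); 2 runs × 8 blocks (conditions alternating, 4
stimulus types cycling), block lengths alternating 30/31 TRs at
TR = 0.8 s; latent abilities (a_SA, a_WM) bivariate standard normal with
r = 0.62; adults get +0.5 SD ability and +0.05 z-units on mask edges;
planted masks of 757/630/1,674/1,203 edges with forced pairwise overlaps
37 and 33; 100 group-common and 100 group-differential edges with random
±1 signs; 20 macroscale regions assigned round-robin.

Edge model (direct mode): each edge's Fisher z is a fixed baseline
μ ~ N(0.25, 0.25²) plus mask, common, and differential ability effects
plus N(0, 0.3²) block noise. The mask effect is β = 0.033 z-units per SD
of ability, chosen so that the *task-average* per-edge correlation with
ability is ≈ 0.4 under the default 16-block, σ = 0.3 noise regime — the
planted population effect the recovery tests target. The common effect
matches β; the differential effect (0.025) is smaller so the common
pattern dominates LV1. A per-block latent state (SD 1, gain 0.15 on the
condition-matching masks, 0.02 on accuracy) couples strength and accuracy
block-to-block, which is what the within-subject tracking analyses
recover.

Accuracy is linear-then-clipped to [0, 1] (matching its use as a linear
outcome): base 0.87 + 0.06·ability + stimulus effect (standardized
values, place = −0.22, scaled by 0.1) + run effect (−0.01) + motion
effect (−0.05 per mm of block FD above 0.1) + state + N(0, 0.1) noise.
The 0.1 noise SD approximates the binomial SD of a 10-trial block near
0.87 accuracy. Block FD is lognormal around a subject-level median of
0.10 mm, so a realistic minority of blocks fails the strict motion
criterion.

Time-series mode converts the target z matrix to r = tanh(z), projects to
the nearest unit-diagonal PSD matrix (eigenvalue clipping at 0, rescale
to unit diagonal — simple and deterministic), and draws the block's TRs
as zero-mean multivariate normal, so estimated FC carries realistic
T-limited noise; inter-block TRs are white noise. Direct-edge mode is the
default because it is fast and its ground truth is exact; time-series
mode exists to exercise the FC-estimation path, and recovery under it
improves with block length as expected.

One global seed fans out to per-stage generators through
`SeedSequence(seed, spawn_key=(stage,))` with fixed stage counters
(0 ground truth, 1 subjects, 2 behavior, 3 connectomes), so any stage can
be regenerated independently and identical (config, seed) pairs produce
byte-identical outputs (fixed float formatting in all writers).

### What the generator does *not* emulate

Hemodynamics, voxel-level structure, realistic motion artifacts, scanner
or site effects on the edges themselves, non-normal ability
distributions, and missing-data patterns beyond motion exclusion.
Passing recovery tests therefore demonstrates that the estimators are
correct and calibrated under the planted model — not that real data
carry effects of this size or cleanliness.

## Problem sizes used in the tests

Module and acceptance tests run the generator at desk scale — typically
P = 20–100 parcels with mask sizes scaled by the edge-count ratio
(`SimulationConfig.scaled`), 30–1,000 subjects per group, 100–500
permutations/bootstraps — sizes chosen so each planted effect is
recoverable with comfortable statistical margin while the whole suite
stays fast. The analytic overlap results are computed at the full
M = 35,778 edge count, where the implementation is exact.

## Known limitations

* The consensus binarization and the PLS Y-construction are
  interpretations of underdetermined descriptions; both are documented
  above and alternatives (sign-flip alignment; unsigned averaging) are
  either available or straightforward.
* Pooled held-out CPM correlations across folds are not exactly null
  under permutation (cross-fold dependence); per-site evaluation is, and
  the calibration tests use it.
* One printed overlap percentage in the emulated study's results (0.9%
  for 19/1,941) is inconsistent with the union denominator that
  reproduces the others (19/1,941 = 0.98%); it is treated as a rounding
  artifact and both conventions are computed.
* The FFT band-pass assumes stationarity over the run and does not claim
  optimal filtering for 30-TR blocks.
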