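# Methods

## The model

`denscan` tests a *directional* hypothesis: that a candidate cranium sits on
the Denisovan-predicted side of reference distributions across many
phenotypes at once. The profile contains no effect sizes — each prediction is
a sign *s* ∈ {+1, −1} attached to one continuous measurement and one
reference group (AMH or Neanderthal). Accordingly every statistic in the
pipeline is rank- or side-based, never magnitude-based, and a larger
phenotypic distance is read as higher confidence of divergence, not as a
better Denisovan fit.

The packaged default profile carries 18 predictions over 12 phenotypes —
12 tested against AMHs, 6 against Neanderthals; 14 on linear (mm)
measurements and 4 on angles — with the six Neanderthal-referenced
predictions being the Denisovan-/Neanderthal-derived clade differentiators.
The profile file documents which of its entries are structural stand-ins for
the published prediction table (an external database download) and which
directions follow published descriptions.

## Quantile estimation and phenotypic distance

Reference values for one measurement are cleaned with Tukey fences
(quartiles by linear interpolation of order statistics at 1 + (N−1)p, the
default convention of mainstream statistical software; the convention is
isolated in `remove_outliers` so it can be swapped). The i-th order statistic
of the N surviving values estimates the (i − 0.5)/N quantile; exact ties
share the mean of their positions; quantiles are linearly interpolated in
between. Outside the support the estimate clamps to [0.5/N, 1 − 0.5/N]
rather than returning 0/1 or missing — this keeps the distance
D = 2s(q − ½) strictly inside (−1, 1) and corresponds to
nearest-value extrapolation. A reference group needs ≥ 3 finite values;
an all-identical group yields a flagged degenerate CDF (0.5 at the point,
clamp bounds elsewhere). Outlier removal applies to the reference sample
only, never to the test subject's value. Subjects belonging to a reference
group are scored leave-one-out against their own group.

## Scores

* **Binomial score.** Success = D strictly > 0 (a value exactly on the
  reference median does not count as a match). The default p-value is the
  one-sided mid-p, P = P(X > n⁺) + ½·P(X = n⁺) under Binomial(k, ½); the
  plain exact tail and a continuity-corrected normal approximation are
  selectable. The mid-p variant is the one consistent with a score of 3.44
  at 16 successes of 18 (exact tail ≈ 3.18, normal ≈ 2.96), and is verified
  against full 2^k enumeration in the tests.
* **Wilcoxon score.** One-sided signed-rank test of median distance > 0,
  normal approximation with mean ranks for tied |D|, Pratt handling of zeros
  and Cureton tie/zero-corrected variance, no continuity correction —
  matching `scipy.stats.wilcoxon(zero_method="pratt", method="approx",
  correction=False)`, which serves as an independent cross-check in the
  tests alongside an exact 2^k sign-flip enumerator (k ≤ 22). An all-zero
  vector is degenerate and scores p = 0.5 by convention.
* Scores are S = −log₁₀ P with p floored at 10⁻³⁰⁰; the combined statistic
  is the Euclidean norm √(S_b² + S_w²). Benjamini–Hochberg adjustment
  (statsmodels step-up) is applied across test subjects only — reference
  specimens are controls, not discoveries.

## Permutation null

The two scores assume independent comparisons; cranial measurements violate
this through shared size and regional anatomy. The permutation test asks
whether the actual profile measurements are more informative than random
ones while conserving the observed structure per subject:

* replacement happens at the **measurement level**: each testable original
  measurement (a "slot unit", carrying one or two prediction slots) receives
  one random measurement of the same class (linear vs nonlinear), distinct
  within a permutation, sampled from the pool of measurements observed for
  that subject with a valid CDF for every needed reference group. This
  preserves the total prediction count, the per-reference-group counts, the
  linear/nonlinear ratio, and — because a phenotype predicted against both
  references keeps both slots on one sampled measurement — the correlation
  structure of paired comparisons;
* measurement directionality is arbitrary (a "forehead height" could as well
  be a "forehead shortness"), so every pool measurement is sign-aligned to
  the biorbital-breadth anchor (EKB) by the sign of its pairwise-complete
  Pearson correlation (Spearman selectable); a sampled slot's effective
  direction is the slot sign times that orientation. Near-zero correlations
  (|r| < 0.05) default to +1 with a warning;
* p_raw = (# permuted combined scores ≥ observed)/n_perm, ties counted
  (conservative); an add-one smoothed estimator is available but off by
  default. BH family = test subjects with ≥ 5 testable predictions.

Sampling is without replacement within one permutation and with replacement
across permutations; the original measurement may be redrawn. Identical
seeds give bit-identical results (per-subject child streams of one seed
sequence, spawned in a fixed order).

## Clade differentiation

The differentiation profile keeps only predictions whose lineage annotation
is Denisovan- or Neanderthal-derived (six in the default profile), plus,
optionally, M2 molar crown area computed as the mesiodistal × buccolingual
rectangle product — the standard odontometric convention; no ellipse factor
is applied to crown area. A subject's combined score is placed in the
leave-one-out Neanderthal score distribution (specimens with ≥ 5 testable
differentiation predictions) using the same outlier-cleaned interpolated CDF,
reported as a 0–100 percentile. Exact percentile invariance holds under
affine rescalings of all scores; a general monotone transform warps the
interpolation and the Tukey fences but can never reorder subjects.

## Morphospace

Measurements with > 20% missing values are dropped, then specimens with
> 15% (both thresholds strict ">", both orders supported; a nonlinear-only
variant uses a 30% measurement cap). Remaining holes are imputed by plain
iterative PCA (EM-PCA): missing cells start at column means, then rank-2
SVD reconstruction of the standardized matrix refills only the missing
cells until the largest relative change < 10⁻⁸ (max 1000 sweeps; a warning
plus best iterate on non-convergence; a ridge-style regularization parameter
is exposed but 0 by default, since the regularized variant's behaviour is
version-dependent across implementations). Imputation runs on all specimens
jointly; the PCA plane (centering, population-SD scaling, loadings) is then
fitted on reference individuals only and test subjects are projected onto
it. Loading signs are fixed by making each vector's largest-magnitude
element positive.

## Mandibular validation

The packaged fixture encodes the mandibular checks for the two confirmed
Denisovan mandibles: five measurements carrying six predictions each. Checks
with both printed values are compared numerically (observed strictly on the
predicted side of the comparator; equality counts against); checks for which
only a published greater/less relation exists are stored as that relation
rather than invented numbers; missing elements are untestable. Comparator
type (median vs mean) is stored per check because the sources mix them. The
fixture reproduces 4/4 confirmed for the Xiahe mandible, 5/6 for the Penghu
mandible (9/10 = 90%), and 25/28 = 89% when pooled with the 16/18 cranial
tally.

## Synthetic studies

The generator's defaults define the study conditions: reference groups of
20 H. erectus, 18 H. sapiens and 15 Neanderthal crania plus 10 test
subjects; 142 measurements — 118 linear with positive anchor correlation,
12 linear with negative correlation, 12 nonlinear (size-free) — matching the
observed positive/negative EKB-correlation split; a standard-normal latent
size factor with loadings U(0.4, 0.9) in magnitude (anchor fixed at 0.9 and
kept free of group shifts and residual factors so it stays a clean size
proxy); three residual "anatomical region" factors (loading SD 0.3) plus
diagonal noise (SD 0.5), so measurements are genuinely correlated; random
per-group mean shifts (SD 1.0; 1.5× for H. erectus, which is the most
distinct group) applied identically to profile and non-profile measurements
so that profile membership carries no systematic information under the null;
MCAR missingness at rate 0.1 (a preservation-block pattern is available);
and cranial capacities N(1300, 100) cm³.

A planted Denisovan-like specimen draws non-profile values from the base
group's per-measurement normal distribution and places each profile
measurement on the predicted side of every reference median involved with a
margin of `effect` within-group SDs (capped at 10 SD; capped at the interval
midpoint when two predictions bound the value from both sides; when a
study's random group geometry makes a measurement's two predictions jointly
unsatisfiable, the first prediction is honoured and the other conceded). At
the default 1.5 SD effect such a specimen matches ≥ 14 of 18 predictions in
≥ 90% of seeds and is recovered as top-ranked and permutation-significant in
≥ 9 of 10 study replicates.

What the generator does *not* emulate: anatomically realistic covariance
estimated from real crania, ontogenetic variation, measurement error
structure, and systematic (non-random) group placement of profile
measurements. Passing tests therefore demonstrate the statistical mechanics
of the pipeline — calibration, constraint conservation, power against a
planted directional signal — not the anatomical validity of any particular
profile.

## Numerical and design choices

* Null calibration is assessed by pooling subjects across independent study
  replicates: within one study the random assignment of group geometry to
  the fixed profile measurements shifts all null subjects' p-values
  coherently (a study-level random effect), while marginally over studies
  the p-values are uniform. Tests use 40 replicates × 5 subjects at
  n_perm = 500 and 10 replicates at n_perm = 1000 for recovery — sizes
  chosen to make the checks sharp while keeping the suite fast.
* Quantile lookups, binomial tail tables and the tie-corrected signed-rank
  z are precomputed/vectorised across permutations, so 10⁴ permutations of
  one subject cost milliseconds.
* Missing markers accepted on read: `?`, empty, `NA`, `-`; written as `NA`
  (CSV/TSV) and `?` (NEXUS). The NEXUS reader handles only the
  DIMENSIONS/FORMAT/CHARLABELS/MATRIX core of a continuous CHARACTERS block.
* Measurement class (linear vs nonlinear) is supplied metadata, not inferred
  from units; size normalization (division by cranial capacity^(1/3))
  applies to linear measurements only, angles and ratios being inherently
  size-free.
* `n_testable` is recomputed against the supplied profile at load time
  rather than trusted from input metadata.

## Known limitations

* The percentile machinery clamps rather than extrapolates, so a subject far
  outside the Neanderthal score range reports 100·(1 − 0.5/N), not 100.
* The asymptotic Wilcoxon p is anti-conservative at very small k; the exact
  enumerator is the reference there and the permutation null is the
  calibrated quantity in any case.
* The default profile's measurement pairings are structural stand-ins; real
  analyses should load the published prediction table via `load_profile`.
* Reproducing the published per-specimen scores and percentiles requires the
  original measurement matrix, which must be supplied by the user as
  CSV/TSV/NEXUS.
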