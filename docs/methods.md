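# Methods

## The correlation model

ICI-Kt extends Kendall's tau-b to vectors with missing entries by giving a
present-vs-missing comparison ordering information. Within one coordinate,
a missing value orders strictly below every observed value and ties with
any other missing value; the classical concordant/discordant definitions
then apply to the extended ordering. This is motivated by left-censoring:
when a value is absent because it fell below the limit of detection, "it
was too small to see" is a statement about its rank.

Two perspectives govern points missing in both vectors. `local` removes
them before counting (appropriate when only the two vectors matter);
`global` keeps them as ties in both coordinates, so all sample pairs over
a fixed feature set share the same pair total n(n−1)/2 and their
correlations are directly comparable. Matrix-level drivers default to
`global`; the single-pair API defaults to `local`.

The implementation substitutes missing entries with a sentinel strictly
below the minimum observed value across both vectors
(min − 1 − |min|·1e-6, safe for negative data) and computes tau-b by
sorting plus exchange counting. The substitution is an exact re-expression
of the extended pair rules, and the test suite verifies it against an
O(n²) census that applies the rules pair by pair, to 1e-12 over randomized
inputs with up to 60% missingness, both perspectives.

All pair counts are exact integers (the inversion counter is a hybrid
mergesort: vectorized O(B²) base blocks of B = 64, then bottom-up merges
with binary-search cross counts); floating point enters only at the final
ratios. Empirically the core's log-log runtime slope over n ∈ [10³, 10⁵]
is ≈ 1.05, consistent with O(n log n).

### Derived statistics

- **tau_max** = (n_tot − n_xtie − n_ytie + n_tie) / √((n_tot − n_xtie)(n_tot − n_ytie)),
  the ceiling tau-b can reach given the pair's tie structure (1 when ties
  are absent or fully shared). Dividing a dataset's tau matrix by the
  maximum tau_max over its pairs rescales all correlations onto a common
  attainable ceiling. Because the factor is dataset-specific, rescaling
  makes values incomparable across datasets, so `scale_max` defaults to
  off. tau_max is computed identically for negatively correlated pairs; it
  is a property of the tie structure, not of the sign.
- **completeness** = fraction of positions missing in neither vector,
  always computed on the full vectors (before any local-perspective
  removal). The composite tau × completeness multiplies the *unscaled*
  tau: completeness modulates the observed correlation before any
  dataset-wide rescaling, so the composite stays meaningful whether or not
  `scale_max` is requested later.
- **p-value**: two-sided Mann–Kendall normal approximation
  z = S/√Var(S), S = n_c − n_d, with the standard tie-corrected variance
  over the tied-group multiplicities of both vectors (missing entries form
  one shared lowest group), and no continuity correction. This matches
  SciPy's asymptotic tau-b p-value exactly on complete data.

### Degenerate inputs

A pair whose tau-b denominator vanishes (one vector fully tied after
substitution), a local pair with fewer than two surviving points, or a
non-positive Mann–Kendall variance raises an undefined-correlation error.
Matrix drivers catch it, log a warning, and carry the cell as missing —
never as 0 — so downstream medians and network steps skip it.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `perspective` | `global` (matrices), `local` (single pair) | handling of both-missing points |
| `scale_max` | off | divide tau by the dataset max tau_max |
| `alternative` (censor test) | `greater` | one-sided toward left-censorship; the null is success probability 0.5 |
| `alpha` (outlier harness) | 0.05 | BH-adjusted significance threshold |
| `tail_fraction` (networks) | 0.025 | per-tail quantile for edge selection (5% total) |
| `condition_target` (partial corr.) | 1e4 | condition-number cap that fixes the shrinkage |

## The binomial left-censorship test

Within each subject-sample-factor (SSF) group, each sample's median of
present abundances is computed; for every feature missing in at least one
group sample, each present value counts as a success when ≤ its sample's
median ("≤" per the boundary convention; even-length medians are the mean
of the central pair). Counts aggregate across groups into one exact
binomial test against 0.5. The alternative is one-sided toward success —
left-censorship can only push values below the median — and switchable.
Batch mode applies Benjamini–Hochberg across datasets.

**Calibration caveat.** The test treats present values as independent
trials. In replicate cohorts, a feature sits on the same side of the
median in every sample, so the effective number of trials is closer to the
number of eligible features than the number of values. On data realizing
the exchangeable null (independent sample draws) the measured level is
≈ 0.02 at nominal 0.05 (conservative, as expected from the per-sample
half-below-median structure); on strongly correlated replicates with
purely random missingness it inflates to ≈ 0.14–0.18. Interpret marginal
p-values cautiously when samples are near-duplicates; the extreme
p-values this test is designed to flag (left-censored data give p below
1e-6 in the benchmark) are unaffected by this caveat.

## Outlier detection

Each sample's median ICI-Kt correlation to its within-group partners is
transformed to the score ln(1 − cor_median); a natural log, since the base
only shifts a monotone transform and the interquartile-range fence is
invariant to it. Within each group, samples whose score strictly exceeds
Q3 + 1.5·IQR are flagged — the high end only, because a *high* correlation
is never evidence of a bad sample. Quartiles use linear interpolation
(type-7); the fence position depends on this convention. A median
correlation of 1 is clamped to 1 − 1e-15 before the log; clamping lowers a
score and therefore cannot create an outlier. Both the fence and the
high-end restriction are applied per group.

The evaluation harness (fraction of features differential across groups
after removal) uses the ordinary one-way ANOVA F-test with BH adjustment.
Moderated-variance (shrunken residual variance) statistics would raise
power at small n but are out of scope; with simulated group sizes ≥ 5 the
ordinary F-test is an adequate yardstick for *comparing* removal
decisions, which is all it is used for here.

## Networks and the partitioning ratio

Feature–feature correlations are inverted to partial correlations
p_ij = −Ω_ij/√(Ω_ii Ω_jj). With more features than samples the
correlation matrix is singular, so Ω inverts the shrunk matrix
(1 − λ)C + λI, with λ the smallest value capping the condition number at
`condition_target` (closed form from the extreme eigenvalues; λ = 0 when
the matrix is already well-conditioned, so small exact cases are
unchanged). The chosen λ is returned with the result and logged by the
CLI. Undefined correlation cells are imputed to 0 before inversion.

Edges are the off-diagonal entries at or beyond the 2.5% and 97.5%
empirical quantiles (ties at a threshold included deterministically),
then trimmed to positive weights. For annotation sets, with *annotated*
the total weight of edges touching any annotated feature, *within_i* the
weight with both endpoints in set i, and *outer_i* the weight of edges
with one endpoint in i and the other in a different set,

Q = Σ_i [ within_i/annotated − (outer_i/annotated)² ].

A crossing edge i↔j counts in outer_i and outer_j (both directions, the
default; a single-direction count is available). Q is invariant to uniform
weight rescaling; for disjoint single-label annotations it ranges over
[−2, 1], and overlapping sets widen the range.

## The simulation module

Generators are pure functions of (parameters, seed) and default to the
benchmark conditions: log-normal base intensities with meanlog 1,
sdlog 0.5 on the natural-log scale (matching the log-like intensity
distributions of MS metabolomics data), n = 1000 features.

- **perfect pair**: sorted base; the partner adds uniform(−0.5, 0.5) noise
  and is re-sorted, so rank correlation is exactly +1. The negative pair
  is the negated re-sorted copy, making it a true linear mirror: both its
  Kendall and Pearson correlations start at −1, so deviations under
  censoring are measured from a genuine −1 baseline. (A descending
  re-sort of the positive partner would instead pair two differently
  curved quantile functions, starting Pearson near −0.74 and conflating
  censoring effects with curvature.)
- **outlier variant**: the noise of the top 0.5% of points (5 at
  n = 1000) is replaced by uniform + log-normal(1.2, 0.1) draws before
  re-sorting — Pearson shifts, rank correlations do not.
- **low-end missingness**: up to 499 of one vector's lowest-half values
  (selected by value, so the negative vector is censored at its own low
  end) are set to missing.
- **realistic pair**: the base plus one N(0, 0.2)-noised copy, giving an
  ICI-Kt near 0.90 uncensored. Censoring operators: an intensity cutoff
  (grid 0 → 1.5 by 0.1) applied to both vectors, or uniformly random cell
  positions (0 → 300 by 50).
- **dynamic-range cohort**: 100 replicate samples of one base on the
  log10 scale (noise sd 0.2 on the natural-log scale before conversion);
  per-sample censoring floors at the sample minimum plus uniform(0, L)
  with L ∈ {0.5, 1, 1.5} for low/medium/high dynamic-range variability,
  and a half-minimum global imputation partner.

What the generators deliberately do *not* emulate: multimodal feature
distributions, batch effects, heteroscedastic noise, NMR-vs-MS missingness
profiles, or feature-feature biochemical correlation beyond the simple
shared-base / block constructions. Passing benchmarks therefore show the
method behaves as designed under clean left-censoring and random
missingness — not that it is optimal on any particular real dataset.

## Problem sizes in the shipped checks

The acceptance script runs 100 replicate seeds per quantity at n = 1000
with the full 0–499 missingness grid; the test suite uses the same
replicate counts with a thinned grid (step 25 plus the 499 endpoint — the
maximum deviation grows with the number missing, so the thinned maximum is
a lower bound of the full-grid maximum), 200 replicates per censorship
arm, and 100 replicates for outlier recovery and network-partitioning
properties. These sizes keep the whole suite under a minute of compute
while leaving the replicate counts of the stochastic claims intact.

## Known limitations

- Right-censoring (saturated detectors) and mixtures of censoring with
  missing-at-random are not modeled.
- The binomial censorship test is anti-conservative under strong
  replicate correlation combined with random missingness (see above).
- Partial correlations depend on the shrinkage convention; with features
  ≫ samples the chosen λ is large and partial correlations are
  correspondingly compressed. The value is always reported.
- tau_max rescaling is within-dataset only.
- Weighted Kendall variants and Spearman-based analogues are out of scope.
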