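# Methods

This note documents the statistical procedures, the synthetic cohort the
test suite runs on, and the design decisions that were genuinely open.

## Study design assumed by the pipeline

Participants are classified once, at baseline, by the NPZ-6 composite —
the arithmetic mean of six standardized cognitive-domain z-scores — with
the Lower (impaired) group defined by NPZ-6 ≤ −0.5 (boundary closed on the
impaired side) and the Higher group by NPZ-6 > −0.5. The reference design
has 3 Lower and 15 Higher participants sampled at three visits (`bsl`,
`post`, `final`). All group inference is built for this tiny, unbalanced
regime.

## Small-sample tests

**Exact rank-sum.** The two-sided Wilcoxon rank-sum p is computed from the
full enumeration null of all C(n₁+n₂, n₁) assignments (implemented as a
counting recursion over ranks, which is arithmetically identical to literal
enumeration) whenever n₁+n₂ ≤ 20 and the pooled data are tie-free; the
two-sided p is 2·min(lower tail, upper tail), capped at 1. At n = 3 vs 15
the smallest attainable level is 2/816 ≈ 0.0025 and the achievable α at a
nominal 0.05 is 0.0392 — both matter when reading rejection rates below.
With ties or larger samples the normal approximation with mid-ranks, tie
correction and continuity correction is used; degenerate all-equal input
returns p = 1.

**Chi-square.** Pearson chi-square without Yates continuity correction,
df = k−1 for a 2×k table; all-zero columns are dropped with a warning.
The no-correction choice is deliberate: it exactly reproduces the four
recomputable descriptive-table p-values the pipeline is checked against
(0.021, 0.180, 1.000, 0.701); with correction none of them match.

**Kruskal–Wallis** is the tie-corrected H with a chi-square reference. For
two groups H equals z² of the rank-sum normal approximation without
continuity correction; the test suite asserts this identity to 1e-9.

## Discriminant selection

**Taxa (LDA effect size).** Features pass a Kruskal–Wallis gate at
α = 0.05; candidates are scored on abundances rescaled to 1e6 per sample by
30 rounds of balanced subsampling (2/3 per class, at least 2 per class),
each fitting a one-dimensional LDA on the candidate block. The per-feature
effect size averages the raw class-mean difference with the feature's share
of the class separation along the unit discriminant axis; the reported LDA
score is its log₁₀, thresholded at 2.0. Zero-variance features are skipped
with a warning; the direction of a retained feature is the class with the
higher median raw abundance. Bootstraps are seeded, so results are
deterministic.

**Metabolites (sparse PLS-DA + rank-sum).** Intensities are median-scaled
per feature and log-transformed, then autoscaled inside the model. The
sparse PLS is NIPALS against a centered/scaled class-indicator matrix;
each loading-weight vector is soft-thresholded to exactly keepX = 100
non-zero entries (the cardinality convention — the published constraint is
a count, not a penalty) and renormalized; X and Y are deflated by the score
regression. With keepX ≥ p the model reduces to dense PLS-DA, which the
test suite checks against scikit-learn's PLSRegression to 1e-8. The union
of kept variables from the two components is then tested by the exact
rank-sum at raw p < 0.05 — deliberately unadjusted, because the two-stage
gate (shortlist, then test) is itself the selection rule.

**PC1 extraction.** PCA on the autoscaled discriminant-metabolite block.
The component sign is anchored to the groups: the Lower-group mean score is
made positive, so positive loadings are the Lower-elevated side. Loadings
are reported in the factor-analytic convention — the correlation between
each metabolite and the PC1 score — rather than as unit-norm eigenvector
entries. This is a deliberate choice: eigenvector entries scale as
1/√n_features, so any fixed threshold (here +0.15 / −0.10) would be
unattainable for one panel size and trivial for another, while correlation
loadings keep fixed cutoffs meaningful regardless of how many metabolites
enter the PCA. The asymmetric thresholds are kept as published. PC1's
explained-variance share is reported, with a warning below 20%.

Note one consequence of group-anchored orientation: negating the data
genuinely swaps each feature's elevation direction relative to the Lower
group, so the positive and negative sets swap roles; what is invariant is
the resolution of the PCA solver's arbitrary component sign.

**Pathways.** Only pathways with global mean relative abundance > 1% are
tested (exact rank-sum, α = 0.05); rarer pathways are not tested at all.

**Heatmap clustering** is Ward linkage on Euclidean distances of
autoscaled values (scipy), verified against an O(n³) re-evaluating Ward
oracle in the tests.

## Balance indices

For numerator set N (Lower-enriched at baseline) and denominator set D
(Higher-enriched), the index of a sample x is
`ln gm(x_N) − ln gm(x_D)`. Design choices:

* **Natural log.** The base is a monotone rescaling and cannot affect rank
  tests or correlations; it is recorded in the definition and configurable.
* **Zeros** are replaced by half the smallest non-zero value of the same
  table (per table, not per feature); configurable to a fixed pseudocount.
* **Frozen definitions.** The baseline-derived sets are applied unchanged
  at `post` and `final`; the longitudinal claim is about the *same* index
  over time.
* **The combined index** pools taxa (relative abundances) and metabolites
  (normalized intensities) in one geometric-mean ratio despite different
  units. Because the statistic is exactly invariant to per-sample rescaling
  of each table, the group comparison is well-defined; the absolute value
  of the combined index still has no physical unit, which is a caveat worth
  keeping in mind when comparing magnitudes across studies.
* An index with an empty side is **undefined** and raises an error — never
  a silent NaN. On signal-free data at these sample sizes this is the
  common outcome, which is itself a useful property (the pipeline refuses
  to build an index out of noise roughly half the time, and the features it
  would otherwise use are pure false positives).

## Associations

Spearman correlations use mid-ranks with the t-approximation for p (an
exact permutation p is available for n ≤ 8). BH adjustment is the step-up
rule applied within a declared family; the default family is one
index-set × outcome-set × timepoint block, matching how such heatmaps are
displayed panel by panel. Correlation networks threshold at |ρ| ≥ 0.6 with
a stricter 0.7 view. PERMANOVA uses Bray–Curtis dissimilarities, the
pseudo-F from among/within squared-distance sums, free label permutations
(no strata — the design has no baseline blocking) and
p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm). Note that at n = 3 vs 15 a random
permutation reproduces the observed partition with probability 1/816 and
then ties F_obs, so under complete separation the attainable p floors at
1/(n_perm+1) only in about (1−1/816)^n_perm of runs. Metabolite set
enrichment is the hypergeometric upper tail against a user-supplied GMT
library, with the universe defined as all measured (named) metabolites and
BH across tested pathways.

## The synthetic cohort generator

The generator emulates the *structure* of the reference study, with planted
ground truth for recovery testing:

* **Species** (default 200): per-feature log-normal abundances with wide
  base means (N(0, 2.5²) on the log scale), a participant random intercept
  (σ = 0.5) making repeated measures positively correlated, residual noise
  (σ = 0.5), closure to relative abundances, truncation of values below
  1e-6 to structural zeros, re-closure. Planted discriminant species
  (default 6, split 3/3) get base abundances near 1% so they resemble the
  detectable discriminant species of real cohorts.
* **Metabolites** (default 1300, 64 planted, split 32/32): log-normal, no
  closure (plasma intensities are not compositional), median-scaled per
  feature.
* **Cognition and outcomes**: one latent cognition factor per participant
  (Lower drawn below, Higher above the −0.5 threshold); six domain z-scores
  whose noise is centered so their mean equals the NPZ-6 trajectory value
  exactly; five functional scales loading on cognition with fixed signs
  (quality of life and daily functioning positive; depression/anxiety,
  stress, CNS symptoms negative) at loading 0.85.
* **Planted effect**: expressed in units of the total within-group SD
  (√(0.5²+0.5²) ≈ 0.71 log units). The shift follows the continuous
  cognition gradient, normalized so the Lower-group mean shift is exactly
  `effect_size × attenuation[t] × SD` and the Higher-group mean shift is
  zero. Species damp the within-Higher gradient by 0.7 (their contrast is
  closer to discrete enrichment); metabolites follow it fully. The
  within-group gradient is essential: a purely group-level shift caps the
  index–cognition Spearman at the 3-vs-15 point-biserial ceiling
  (|ρ| ≈ 0.41), far below the BH-surviving correlation strengths the
  analysis is meant to exhibit.
* **Defaults as study conditions**: `effect_size = 4.0` SD (a ~17-fold
  abundance contrast) was fixed by a power calibration against the regime
  the analysis targets — per-feature exact-test power ≈ 0.99 at n = 3 vs
  15, full recovery of all six planted species in ≈ 93% of cohorts, and
  complete baseline index separation (p = 2/816) essentially always; at
  2 SD the exact test's per-feature power is only 0.76, which no selection
  procedure can repair at these sample sizes. `attenuation = (1.0, 0.5,
  0.1)` drives the bsl → post → final convergence of the groups.
* **What the generator does not emulate**: real taxonomic correlation
  structure, batch effects, unnamed biochemicals, non-log-normal tails,
  missing samples, or any coupling between the intervention arm and the
  outcomes. Passing tests therefore demonstrate correctness and calibration
  of the procedures, not performance guarantees on real cohorts.

## Calibration facts worth knowing

* Under the null, the sPLS-DA shortlist is selected on the same data the
  rank-sum filter then tests, so the retention rate *among kept candidates*
  is ≈ 0.25 — pure selection bias. The meaningful false-positive rate of
  the cascade is per feature entering it (retained / all metabolites),
  which is ≈ 0.036, right at the achievable exact-test α of 0.0392. The
  same per-feature convention is used for the taxa gates.
* The LDA-score gate (> 2.0) only ever removes KW-passing candidates, so
  the taxa cascade's false-positive rate is bounded by the KW gate's.

## Problem sizes

Monte-Carlo checks run at: 100 cohorts for recovery, attenuation and
sign-pattern studies; 200 null cohorts for cascade calibration; 1000 null
cohorts (199 permutations each) for PERMANOVA calibration; 500 replicates
for the generator's null check. These sizes give standard errors well below
the decision margins of the corresponding checks.

## Known limitations

* The exact rank-sum switches to the normal approximation as soon as any
  tie appears; for heavily zero-inflated species this means the exact
  branch is the exception, not the rule.
* LDA effect sizes follow the original algorithm's conventions
  (subsampling fraction, bootstrap count, log₁₀ rescaling) but are not a
  byte-level reimplementation of any specific release of the original tool.
* The metabolome index depends on the PC1 loading convention (see above);
  with unit-norm eigenvector loadings the published thresholds would select
  nothing on panels of ~64 strongly correlated discriminant features.
* With 3 participants in the impaired group, within-group longitudinal
  tests are exploratory by construction and are flagged as such in the
  output.
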