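# Methods

This note documents the statistical procedures implemented in
`arrestome`, the assumptions behind them, the defaults and why, and what
the synthetic benchmark does and does not demonstrate.

## Input model

The pipeline consumes, rather than produces, interaction-probability
scores: each bait–prey pair arrives with a SAINT-style probability of
authenticity in [0, 1] and a Bayesian false discovery rate (BFDR), plus
per-replicate spectral counts.  Bait identifiers, prey identifiers and
annotation vocabularies are opaque strings; no identifier normalisation
is attempted.  Bait-to-bait self pairs are removed at score load time
(and logged).  Missing (bait, prey, replicate) cells are explicit zeros,
not missing data — an undetected prey genuinely scored zero spectra.

## Cutoff selection and filtering

**Validation ROC.** Curated positive and negative PPI sets anchor the
score scale.  Negatives typically outnumber positives by an order of
magnitude or more, so ROC curves are computed over `n_cohorts` (default
1000) random negative cohorts, each number-matched to the positive set
and drawn without replacement from a seeded generator.  Per cohort the
AUC is the rank (Mann–Whitney) concordance of positive versus
cohort-negative scores; TPR/FPR are averaged pointwise at shared
thresholds (the sorted distinct observed scores plus sentinels 0 and 1)
rather than by vertical averaging at fixed FPR — simpler, exactly
testable, and equivalent for the cutoff decision being made.  Validation
pairs absent from the score table are assigned score 0: an undetected
pair carries no evidence.

**Score cutoff.** The working cutoff is the minimum score among
interactions with BFDR at or below the target (default 0.01), so
thresholding at it admits exactly the BFDR-passing set.

**Spectral-count sweep.** For each cutoff 1..15, only pairs whose count
in *every* replicate meets the cutoff are retained; Pearson correlations
of retained counts are computed per replicate pair within each bait,
averaged within bait, then across baits.  A bait retaining fewer than 3
pairs has no defined correlation at that cutoff and is excluded from the
grand mean (logged).  Correlations are computed on raw counts by
default; a log2 transform is a config option.  The final filter applies
the same all-replicates rule at the chosen minimum count (default 6)
together with the score cutoff; a mean-count alternative
(`all_replicates=False`) is available because the all-replicates reading
is the stricter of the two defensible interpretations.

**Isoform collapsing and zero imputation.** Isoforms collapse onto their
parent gene by summing counts (conserves total evidence; `max` keeps the
dominant isoform instead).  Zero counts can be floored at 0.01 before
ratio computations to avoid division by zero; only exact zeros change.

## Motif–domain support and enrichment

A PPI is *supported* when some motif annotated on the bait and some
domain annotated on the prey form a known affinity pair.  Matching is by
annotation table only — no sequence scanning.  The enrichment test
compares supported fractions between the high-confidence network and the
raw-minus-high-confidence remainder (disjoint strata, so the 2×2 margins
are well defined) with a one-sided (greater) Fisher exact test, reported
uncorrected because it is a single test per network.

The EASE score for per-bait domain enrichment builds the 2×2 table
[query-with-domain, query-without; background-other-with,
background-other-without], decrements the query-with cell by one
(floored at zero) and applies a one-sided Fisher test.  The decrement is
a deliberate conservatism: a category represented by a single query gene
can never be significant (p = 1 exactly), and EASE p ≥ Fisher p always.
The background universe defaults to all detected preys; BH correction is
applied within each bait's family of domains, significant at q ≤ 0.05.

Localization profiles distribute one unit of weight per annotated prey
equally over its k terms (1/k each) from a fixed 11-term cellular-
component vocabulary; preys without any in-vocabulary annotation are
excluded from the denominator, so profiles sum to 1.

## Complex association

**Statistic.** For a complex of N subunits scored against one bait, the
association score is the interquartile mean of the subunit scores:
sort ascending, take ranks Q1 = ⌊N/4⌋+1 through Q3 = ⌊3N/4⌋ (clamped so
Q3 ≥ Q1; the floor convention fixes the integer behaviour for N not a
multiple of 4), and average.  Subunits absent from the bait's network
score 0 and count toward N — a complex must be penalised for undetected
members, otherwise any complex containing one strong interactor would
score highly.  Complexes with fewer than 3 subunits are rejected.

**Permutation test.** The null is the IQM of random same-size complexes
drawn uniformly without replacement from the permutation universe
(default: all proteins appearing in any input complex database;
detected-preys is a config option).  The add-one estimator
p = (1 + #{null ≥ observed}) / (n_perm + 1) never returns exactly zero,
which keeps downstream BH correction well behaved.  Null distributions
are shared across same-size complexes of one bait — random subsets of a
fixed score vector are exchangeable, so this is exact, and it makes the
permutation pass linear in the number of distinct sizes.

**Merging.** Redundant complexes (pooled across all source databases;
cross- and within-source pairs both eligible) are agglomerated greedily:
repeatedly the pair with the highest overlap coefficient
|X∩Y|/min(|X|,|Y|) is replaced by its union (subunits and intra-complex
edges unioned, provenance recorded) while that maximum exceeds 0.5.
Ties break on the lexicographically smallest id pair, making the result
independent of input order; at most n−1 merges can occur.

**Pruning.** Deterministic rules replace what would otherwise be manual
curation: subunits with degree 0 in the intra-complex edge set are
dropped, then complexes with fewer than 3 remaining subunits or fewer
than 2 supporting PPIs are removed.  The PPI count is by default the
number of high-confidence bait–prey interactions landing on remaining
subunits; counting surviving intra-complex edges instead is a config
option, since either reading of "two PPIs" is defensible.  Complexes
lacking an edge set keep all subunits (logged) or are rejected, per
policy.

**Pipeline.** Stage 1 screens every (bait, source complex) pair at
permutation p < 0.05 (per bait); stage 2 merges survivors; stage 3
prunes; stage 4 rescores, recomputes permutation p, BH-corrects within
bait and keeps q < 0.2.  Identical seeds give bitwise-identical output.

## Cross-species comparison

Ortholog predictions carry a confidence score and a prediction
direction.  Pairs with score ≥ 2 are kept; reciprocity (predicted in
both directions, each passing the score threshold) is required by
default.  Ortholog groups are connected components of the retained-pair
graph restricted to the high-confidence preys of the two species, so
groups are disjoint and cover exactly the preys with retained pairs.
The group × bait matrix entry is log2(1 + mean over replicates of the
counts summed over the group's same-species members); summing before the
mean is the natural aggregation when a group has several same-species
members, and the pseudocount 1 keeps undetected groups at 0.
Clustering uses distance 1 − Pearson correlation with Ward linkage;
zero-variance vectors get correlation 0 (distance 1) with a warning so
degenerate inputs never crash the linkage.  Flat cuts (default 7 bait
clusters) are config parameters; functional labelling of groups is left
to the analyst.

## Synthetic data generator

The generator emulates the data model the analysis assumes, with
defaults chosen to resemble a small bait-panel study:

| parameter | default | rationale |
| --- | --- | --- |
| baits × preys | 6 × 300 | small bait panel against a realistic detected proteome slice |
| replicates / control runs | 2 / 4 | paired purifications with a modest control pool |
| true-interaction rate | 0.05 | ~15 genuine partners per bait |
| signal counts | NB(mean 50, dispersion 5) | strong pull-down abundance, overdispersed |
| background counts | NB(mean 2, dispersion 2) | low contaminant counts, overdispersed |
| contaminant fraction | 0.30 | CRAPome-style shared background |
| score model | logistic(2·log2 fold − 2) | monotone in bait/control fold-change |
| planted complexes | 5 among 50 decoys, sizes 4–8, purity 0.8 | sparse true structure in a larger candidate set |

Counts are negative binomial, not Poisson — AP/MS spectral counts are
overdispersed.  Contaminants are shared across all baits and the control
runs, which is what lets the score model discount them.  The score
generator is explicitly *not* a reimplementation of any published
scoring tool: it is a documented stand-in preserving the only properties
the pipeline relies on — a probability-like score monotone in the
bait/control fold-change and a valid BFDR column (empirical FDR of the
score ranking against the truth labels, made monotone by a reverse
running minimum).  What passing the synthetic benchmark shows is that
the pipeline's statistics behave as designed under the assumed data
model; it does not show robustness to batch effects, carry-over,
abundance-dependent detection, isoform ambiguity or scoring-model
misspecification, none of which the generator emulates.

## Numerical and design choices

- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; the pipeline driver derives per-stage seeds from the global
  seed via `SeedSequence([seed, stage_index])` so stages can be rerun in
  isolation.  Outputs are byte-identical across re-runs.
- Thresholds (BFDR 0.01, minimum count 6, screen p < 0.05, merge 0.5,
  complex FDR 0.2, ortholog score 2, EASE q 0.05) all live in the YAML
  config with these defaults.
- Degenerate inputs: empty networks propagate to empty results rather
  than errors wherever a downstream stage can proceed; correlation of a
  bait with <3 retained pairs is flagged undefined, not 0.
- Text I/O uses `%.17g` float formatting and round-trip parsing, so
  write→read cycles are bit-exact.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data
at the default configuration (6 baits × 300 preys, 55 complexes, 1000
permutations, 10 replicate seeds for the recovery benchmark; 200 decoy
complexes for p-value calibration; exhaustive enumeration on universes
of ≤ 8 proteins).  These sizes exercise every code path at full
statistical resolution for the planted effect sizes while completing in
seconds on one CPU.
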