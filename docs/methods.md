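# Methods

This note documents the statistical procedure `crossmb` implements, the
choices made where the design was genuinely open, what the synthetic data
generator does and does not emulate, and the known limitations.

## The comparison model

The pipeline treats each expression dataset as an independent, internally
contrasted experiment. No attempt is made to put absolute expression
values from different platforms or species on a common scale; instead,
each dataset is reduced to a *within-dataset* ordering of genes by their
SHH-group overexpression, and only those orderings (quantile ranks in
[0, 1]) are compared across datasets and species. This is robust to
platform, normalization, and cohort-composition differences, at the cost
of discarding effect-size information: a gene 4 log2 units up and a gene
0.4 units up can both sit at rank ≈ 1.

Key consequences of the design:

* **Contrast asymmetry is deliberate.** Human datasets contrast SHH
  tumors against other MB subgroups; mouse datasets contrast Shh tumors
  against healthy cerebellum. Row-centering uses whatever group columns a
  dataset carries — there is no special-casing — so the human and mouse
  rankings answer slightly different questions. The cerebellum-normalized
  mode (subtracting the control-group median instead of the row mean)
  exists as an explicit robustness variant for panels that do include
  healthy-cerebellum controls; its control column is identically zero by
  construction.
* **Array-level batch shifts are harmless to ranks.** An additive
  per-array offset moves a whole group-median column; a column shift is
  monotone, and quantile ranks of a column are invariant under monotone
  shifts. The synthetic generator plants such shifts specifically so the
  tests exercise this (and the invariant-set normalizer, which removes
  them when absolute values are wanted).

## Stage-by-stage numerical choices

**Group medians.** Sample medians per feature per group; a single-sample
group contributes that sample's value. Group columns are sorted
alphabetically so downstream outputs are order-deterministic.

**MaxMean probeset collapse.** Applied to the *group-median* table, not
the sample-level matrix: per gene, the probeset with the highest mean over
group columns is retained; mean ties break to the lexicographically
smallest probeset id. Probesets annotated to several symbols
("A /// B") are dropped by default (policy flag: `first` keeps the first
symbol); unannotated probesets are dropped. A separate sample-level
max-mean probe selector exists only for single-gene plotting.

**Quantile ranks.** `(r − 1)/(n − 1)` with average ranks for ties, so the
n untied ranks are exactly {0, 1/(n−1), …, 1}. Rank vectors are averaged
per species with equal weight per dataset regardless of cohort size; a
gene absent from some datasets of a species is averaged over those where
it is present, with the count carried in `n_datasets`.

**Homolog matching.** Canonical keys are human (uppercase) symbols; mouse
symbols are matched case-insensitively (Gpr153 ↔ GPR153). With no
explicit map, a case-convention map is built from the gene symbols
actually present. Explicit maps are resolved one-to-one by default
(ambiguous symbols dropped and counted); a `max_mean_tiebreak` policy
keeps the highest-mean-expression partner when means are supplied.

**Specificity labels.** `human_specific` requires human mean rank ≥ 0.8
and mouse mean rank ≤ 0.2 (and symmetrically); both-extreme genes are
`shared`; everything else `neither`. The 0.8/0.2 cutoffs operationalize
"rank close to 1 / close to 0" and are configurable. Under a no-effect
null suite they label ≲ 0.1% of genes species-specific.

**Invariant-set normalization.** Per non-reference array: start from all
features, iteratively discard those whose proportion rank difference
versus the reference (|rank_a − rank_ref|/n) is ≥ 0.05, re-ranking within
the surviving set, until stable (≤ 30 iterations; error below 20
surviving features). The mapping through the invariant points is a
51-point running-median smooth, made strictly increasing (monotone
envelope plus infinitesimal slope) and applied by piecewise-linear
interpolation with linear extrapolation beyond the invariant range — so
within-array rank order is preserved *exactly* (Spearman ρ = 1 by
construction). Default reference is the pseudo-median array (per-feature
median profile). The smoother window and threshold are package choices;
they recover a pure additive shift to < 0.01 and a 1.2× scale distortion
to < 0.02 on interior quantiles.

**Enrichment score.** Weighted KS running sum with weight exponent 1 by
default (weight 0 reduces exactly to the classic signed two-sample KS
statistic, which the tests verify against a brute-force oracle). Score
ties in the ranked list are broken by gene symbol before analysis so
results are platform-deterministic. If all hit scores are exactly zero the
increments degrade to the unweighted form. The leading edge is the hit
genes at or before (positive ES) / at or after (negative ES) the running-
sum extremum; at an exact extremum-magnitude tie the positive extremum is
reported.

**Permutation null, NES, FWER.** The null is gene-label permutation: one
random relabeling of list positions per permutation, every set scored on
it, so per-permutation family maxima are coherent. NES divides ES by the
mean magnitude of the set's same-sign null ES; the nominal p is the
same-sign tail fraction. The FWER p of a set is the fraction of
permutations whose most extreme same-sign NES over the whole family
reaches the observed NES; permutations with no same-sign ES anywhere in
the family are excluded from the denominator, which makes a single-set
family's FWER equal its nominal p on the NES scale. Sets with no
same-sign nulls at all are flagged and excluded. Default size filters
15–500 (on the set ∩ list intersection), 1000 permutations.

**Concordance.** Ordinary least squares of one rank vector on another
over shared genes; R², slope, two-sided p for zero slope, and n are
reported. The correlogram uses Pearson correlation of SHH-group
overexpression *values* (not ranks) over the pairwise homolog-mapped gene
intersection, with an `on_ranks` switch.

**Non-log input detection.** A matrix whose maximum exceeds 50 is assumed
linear-scale and log2(x+1)-transformed; log2 microarray values rarely
exceed ~16, so the transform can never trigger twice.

## The synthetic generator

Defaults define the study conditions used throughout the tests and the
acceptance script: 2000 genes, 3 mouse + 3 human datasets, mouse groups
Shh/cerebellum at 8 samples each, human groups SHH/Group3/Group4 at 20
samples each (magnitudes typical of public MB panels: human subgroup
cohorts of tens of samples, mouse cohorts of 5–10 animals), baseline
N(7, 1.5²) log2 units shared across datasets, per-sample noise sd 0.8,
per-array batch shift sd 0.3, 1–3 probesets per gene with probe offset
sd 0.3, and three planted 50-gene programs with a +1.5 log2 effect:
shared targets (up in SHH of both species), human-specific, and
mouse-specific. Mouse symbols are title-case, human symbols uppercase
versions of the same root. The *Gli1*-coexpression surrogate scores
shared-target genes +1 over N(0, 0.25²) jitter and quantile-ranks the
result.

What it emulates: per-dataset group structure with the species-specific
contrast asymmetry, probeset redundancy, additive array batch effects,
log-scale noise, and cross-species symbol conventions. What it does not:
platform-specific probe response curves (nonlinearity, saturation),
correlated gene programs beyond the planted blocks, missing values,
sample-level biological covariates (age, sex, TP53 status), or the
many-to-many messiness of real ortholog tables. Passing tests therefore
demonstrate that the *procedure* recovers planted cross-species structure
under realistic noise and batch conditions — not that any particular
biological claim about real tumors is reproduced.

With these defaults the pipeline recovers the planted human-specific
program in the top decile of the rank-difference ordering with ≈ 90%
sensitivity, shared targets attain mean rank ≈ 0.97 in both species with
mean |Δ| ≈ 0.02, within-species correlogram means exceed between-species
means by ≈ 0.24, and both planted set directions reach FWER 0 at 1000
permutations — all recomputed, never stored, by the test suite and
`scripts/acceptance.py`.

## Degenerate inputs and tie-breaking summary

Single-column tables cannot be row-centered (error). Quantile ranking
needs ≥ 2 genes. Correlogram cells need ≥ 3 shared genes, concordance ≥ 3.
Empty gene sets, sets covering the whole list, and sets outside the size
filters are rejected or skipped with a log line. All sorts use stable
mergesort with documented keys (diff descending; FWER ascending then |NES|
descending then name), so identical inputs and seeds give byte-identical
output bundles; the run manifest intentionally contains no timestamps.

## Known limitations

* Rank averaging treats datasets as exchangeable; a systematically
  atypical cohort (e.g. infant-only SHH-MB) is not down-weighted.
* The FWER is computed within whatever set family survives the size
  filters in the same run; significance is not comparable across runs
  with different collections.
* The invariant-set smoother assumes enough rank-stable features to
  anchor the mapping; arrays with globally reordered expression (< 20
  invariant features) are rejected rather than force-fitted.
* Real GEO ingestion is limited to plain TSV series-matrix exports;
  CEL-level processing, RMA summarization, and platform SOFT parsing are
  out of scope.
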