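# Methods

This note documents the statistical procedures the package implements, the
choices made where the design was genuinely open, what the synthetic-data
generators emulate, and the package's known limitations. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Quantile fragment classifier

A candidate fragment X (one profile-search hit with bit score S, profile
alignment interval [a, b] on an L-column profile, and coverage
C = (b − a + 1)/L) is accepted into a family iff S and C both **strictly**
exceed the c-quantile (default c = 0.04) of the scores and coverages of its
*conditioning set*: the positive reference fragments with X's length whose
interval contains [a, b] or is contained by it. Hits scoring below 8 bits
are discarded first (a score of exactly 8 is kept).

Decisions and numerical details:

- **Quantile estimator.** Linear interpolation of order statistics (the
  common type-7 default). On small conditioning sets the c = 0.04 threshold
  is estimator-sensitive, so the estimator name is recorded in every
  verdict and is configurable (`ClassifierConfig.quantile_method`).
- **Marginal thresholds.** The rule is read as two marginal quantiles (one
  on scores, one on coverages), not a joint quantile of (S, C) pairs.
- **Length matching.** Exact length equality by default;
  `length_tolerance` (aa) widens the conditioning population for datasets
  whose fragment lengths are continuous.
- **Empty conditioning set → reject.** With no comparable positives there
  is no evidence the fragment is typical of the family; this is the
  conservative resolution.
- **Coverage is profile-relative** (fraction of profile columns aligned),
  because the conditioning is defined on the profile region where the
  fragment aligns.

An intrinsic property worth knowing: if candidates are drawn from exactly
the positive population, the rule accepts at most ≈ (1 − c) − 1/|Q| of them
per variable (the empirical quantile of a finite conditioning set Q sits
about one order statistic above the population quantile). High acceptance
of true hits therefore presumes a reference set broader than the candidate
population — which is what a curated family reference is; the c-quantile
exists precisely to cut the reference's own stragglers.

## Root clades and placement profiles

The reference tree is cut into exactly `n_rc` (default 44) disjoint
subtrees covering all leaves — the *root clades* — chosen to minimize the
summed root-to-clade branch-length distance. "Closest to the root" is
measured in cumulative branch length; ties break by topological depth,
then node id. The minimizing covering cut is found by an exact dynamic
program over the tree (cost of splitting a subtree into m parts = best
composition of its children's solutions, or the subtree itself for m = 1);
it is validated against full enumeration of covering cuts in the tests.

Placements (jplace v3) are reduced to each fragment's single most probable
location (maximal like-weight-ratio; ties go to the lowest edge number and
are logged). A placement edge is attributed to the unique RC whose leaf
set contains the edge's leaf set; edges above the cut cannot be attributed
and those fragments are dropped with a logged count. The profile is

    p_i = Σ_{f in RC i} h_f/l_f  /  Σ_{f attributed} h_f/l_f ,

so Σ p_i = 1 whenever any weight was attributed; a zero-weight metagenome
yields an all-zero profile flagged empty rather than NaNs. Metagenomes
with fewer than 10 fragments in the tree (counting zero-read fragments)
are excluded — a metagenome with exactly 10 is kept.

Family proportions weight each RC's reference-leaf family fractions
(unweighted leaf counts; unannotated leaves count as "unknown") by `p_i`,
so they sum to the same total as the profile.

## Recombinase-normalized abundance

`RHO_abundance = Σ_rho(h/l) / Σ_rec(h/l)` with REC = RecA ∪ Rad51 (ids
prefixed by subfamily on merging). Only classifier-accepted fragments
contribute. The measure is invariant to global sequencing depth. A
metagenome with zero recombinase weight is flagged undefined and should be
excluded from comparisons instead of being treated as infinitely
rhodopsin-rich. The interpretation "rhodopsin genes per genome
equivalent" rests on the single-copy assumption for recA/rad51; no genome
size or copy-number correction beyond that is attempted.

## Recursive consensus clustering

At each level of the recursion:

1. **RC elimination**, applied in this order on the progressively reduced
   matrix (which makes the operation idempotent): constant columns;
   sparse columns (> 95% of metagenomes below 0.001 **and** every
   remaining value below 0.02 — applied to all values ≥ 0.001, not to
   exactly 5% of them); and, of any set of columns pairwise Pearson-
   correlated at |r| ≥ 1 (with a 1e-12 numerical allowance; threshold
   configurable downward), all but the lowest-indexed column. The constant
   check runs first so an all-zero column is reported as constant rather
   than as vacuously sparse.
2. **Grid search.** Every distance (euclidean, maximum, manhattan,
   canberra, minkowski with p = 3 — p = 2 would duplicate euclidean) ×
   aggregation method × k ∈ [2, min(10, n−1)]. Hierarchical methods run
   the Lance–Williams recurrence on the distance matrix *as given* (the
   `hclust` convention): Ward D on raw distances, Ward D2 on squared
   distances, median/centroid likewise on the raw matrix. Merge ties go to
   the lexicographically smallest cluster-index pair. K-means participates
   only with the euclidean distance (its objective), with 25 restarts and
   a fixed seed.
3. **Index vote.** Seven validity indices (silhouette, Calinski–Harabasz,
   Davies–Bouldin, Dunn, C-index, point-biserial, McClain–Rao), each with
   an orientation flag so voting is uniform. Per combination, each index
   votes for its best k (plurality; ties to the smaller k); each index
   then votes for the best combination evaluated at its voted k (ties:
   lexicographic (distance, method)); the winner is the plurality of
   combination votes. Indices returning NaN (e.g. pair-based indices on
   singleton-only partitions) abstain. Calinski–Harabasz is computed
   in-house so that a zero-within-dispersion partition scores +infinity
   (best) instead of a degenerate constant; it matches the standard
   definition elsewhere and is cross-checked against scikit-learn in the
   tests. The index panel is pluggable; these seven cover the
   distance-based and centroid-based archetypes of the longer index
   roll-calls used interactively, and the majority mechanics — not the
   size of the panel — are what define the procedure.
4. **Recursion** into every resulting group with at least `min_group`
   (default 10) members, re-running elimination on the subgroup's rows of
   the *original* matrix. Branches stop when they are too small, their
   submatrix is degenerate (identical rows), elimination removes every
   column, or no index can vote; a failing branch is annotated on its node
   without aborting siblings. Because the grid always proposes k ≥ 2,
   homogeneous groups keep splitting until their pieces drop below
   `min_group`; the level-0 partition is therefore the natural summary for
   flat structure, and the leaf partition for nested structure.

## Marker utilities

CPM follows the TPM scheme: `cpm_g = 1e6 · (count_g/length_g) / Σ rates`.
Process profiles sum CPM over each process's marker ids (KO/COG), broken
down by taxon; the bundled registry covers anoxygenic photosynthesis,
photosynthesis, sulfate reduction, sulfur oxidation, nitrogen fixation,
denitrification, ammonia oxidation, and carbon fixation (KO and COG
marker sets). Alpha diversity is the effective species number
`base^(−Σ p log_base p)`; the base (default 10, matching the antilog form)
cancels for any distribution's uniform limit, where the value equals the
species count.

## Synthetic data: what it emulates, and what it does not

- **Hits** (`HitSimSpec`). Scores follow a per-aligned-column model
  (score = bits-per-column × span + Gaussian noise), coupling score and
  coverage the way real profile searches do. Alignment intervals anchor
  near the profile's conserved core (Beta(50, 50) midpoint jitter), so
  intervals of different widths nest — giving candidates containment
  support. True candidates draw coverage from Beta(8, 2); the positive
  reference uses a broader Beta(4, 2) (a curated reference spans the
  family's diversity, including short-aligning distant members), plus 10%
  near-full-profile anchors. False hits: Beta(2, 5) coverage at a lower
  per-column rate, putting their scores several standard deviations below
  the true population. Fragment lengths come from a narrow band (60–62 aa)
  so exact-length conditioning has support; real fragment-length
  distributions are broader, which would require a nonzero
  `length_tolerance`.
- **Communities** (`CommunitySpec`). Every genome carries one recombinase;
  a fraction q carries one rhodopsin. Read counts are negative-binomial
  (overdispersion typical of metagenome depth; dispersion 0 switches noise
  off), lengths uniform. No sequence content, no mapping ambiguity.
- **Profiles** (`ProfileSimSpec`). Group centers are Dirichlet draws on
  the RC simplex (optionally redrawn until pairwise-separated); members
  are center + truncated Gaussian noise, renormalized. The two-level
  generator perturbs super-centers into sub-centers the same way.
- **Placements.** Each RC receives a fixed number of fragments on random
  leaf edges; one fragment-length vector is shared across RCs and reads
  are allocated multinomially with probability ∝ p_RC × fragment length.
  Sharing the length vector makes the length terms cancel in expectation,
  so recovery error is pure multinomial noise — a deliberate idealization;
  real placements also vary in edge depth and length composition per
  clade.

Passing tests on these generators show the *estimators* are correct under
their stated models; they do not certify behavior under real-data
pathologies (chimeric fragments, frame duplicates, clade-biased read
mappability, non-independent placements).

## Problem sizes and runtime choices

The test suite and acceptance script use desk-scale sizes chosen to make
the statistics sharp while keeping runs fast: 200-hit × 200-positive
classifier batches (10 seeds for operating rates), 50 placement tables at
1e5 reads, 30 random trees (≤ 64 leaves, n_rc ≤ 10) for cut enumeration,
500-genome communities × 20 replicates × q ∈ {0.1, 0.3, 0.7}, 39
metagenomes × 3 planted groups × 20 seeds for clustering recovery, and
12-point datasets for the exhaustive linkage-oracle comparison.

## Known limitations

- The classifier consumes hit tables as given; reconciliation of multiple
  reading frames of one read is upstream and out of scope.
- Root-clade selection optimizes total root distance; if the original
  44-clade set was defined by a published clade labeling rather than a
  distance cut, the two can differ.
- The recursion's termination rule (min group size, degenerate submatrix,
  index abstention) is a declared operationalization; the grid vote
  cannot elect "one group".
- Criterion (iii) of RC elimination uses Pearson correlation; Spearman is
  not offered.
- Alpha diversity assumes the annotation counts are comparable across
  species (no coverage correction).
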