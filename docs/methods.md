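# Methods

This note documents the models, estimators, numerical choices and
limitations behind `phyllonet`.  It covers what each stage computes and why
the defaults are what they are; every number quoted here is produced by the
test suite or `scripts/acceptance.py`, not asserted from elsewhere.

## Preprocessing

OTU tables are samples × OTUs matrices of integer read counts.  Two rules
mirror standard amplicon practice:

* **Low-count filter** (`filter_low_count`, default `min_reads = 10`): any
  cell with fewer than 10 reads is treated as absence *in that sample* —
  a guard against PCR/sequencing error — and OTUs left with no reads
  anywhere are dropped.  The alternative reading (drop an OTU globally when
  any sample is below threshold) would delete ubiquitous taxa and is not
  used.  The filter is applied before rarefaction by default; the pipeline
  exposes both the threshold and the rarefaction depth.
* **Rarefaction** (`rarefy`): each sample's counts are subsampled without
  replacement to a common depth, i.e. a multivariate hypergeometric draw.
  Column sums then equal the depth exactly and no count exceeds its
  original value.

Partitioning treats an OTU as present in a compartment when it has a
nonzero count in at least one sample after filtering; percentages of the
union are rounded to two decimals.

## Community statistics

Distances are computed on Hellinger-transformed counts
(`sqrt(count/sample-total)`), which makes Bray–Curtis robust to dominant
taxa.  NMDS minimizes Kruskal stress-1 with isotonic regression of
configuration distances on dissimilarity ranks (SMACOF, via scikit-learn),
taking the best of `n_starts` random starts plus one deterministic
Torgerson metric-scaling start; coordinates are column-centered and the
reported stress is the minimum found.  Error contract: `k` up to `n − 1` is
allowed, since `n` points always embed exactly in `n − 1` dimensions.

ANOSIM uses mid-ranks of all pairwise dissimilarities,
`R = (r̄_between − r̄_within)/(M/2)` with `M = n(n−1)/2`, and a one-tailed
permutation p with add-one correction, `p = (1 + #{R_perm ≥ R_obs})/(n_perm
+ 1)`; the default `n_perm = 9999` supports p-values down to 1e-4.  The
Mantel statistic is the Pearson correlation of lower-triangle vectors with
rows/columns of the second matrix permuted jointly; the pipeline correlates
Bray–Curtis *similarity* (1 − dissimilarity) with phylogenetic distance
using `tail='less'`, so a significant result means related hosts carry more
similar communities.  Both tests are exact permutation procedures, so their
type-I error is nominal by construction; the acceptance run measures ≈ 4–6%
at α = 0.05 over 500 null simulations.

The richness contrast is a paired *t*-test on log richness with a
one-tailed (`greater`) default, matching the directional hypothesis that
leaf surfaces carry more taxa than interiors.

## Phylogenetic signal

Both statistics build on the Brownian covariance `V_ij` = shared
root-to-MRCA path length, computed once per tree by a post-order traversal
and cached.

* **Blomberg's K** is the ratio of the observed to the Brownian-expected
  mean-square contrast, `K = [(x−â)ᵀ(x−â)/(x−â)ᵀV⁻¹(x−â)] / [(tr V −
  n/(1ᵀV⁻¹1))/(n−1)]` with the GLS phylogenetic mean `â`.  Its expectation
  under Brownian motion is ≈ 1 (measured 0.99 over 500 simulations on
  64-tip trees).  Significance comes from tip-label permutations with
  add-one correction (default 999).
* **Pagel's λ** multiplies the off-diagonal covariances by λ and maximizes
  the Gaussian likelihood with mean and rate profiled out analytically,
  using bounded scalar optimization on [0, 1] (the bound keeps V positive
  semidefinite on ultrametric trees); endpoint likelihoods are checked
  explicitly so a boundary optimum is never missed.  The p-value is a
  likelihood-ratio test against λ = 0 (χ², 1 df); when the MLE sits at the
  λ = 0 boundary the LR statistic is 0 and p = 1 by convention.  Recovery
  at the extremes exceeds 95% of 200 replicates on 64-tip trees.

Both estimators were cross-checked against R phytools (`phylosig`) on a
shared fixture and agree to ≥ 5 significant digits.

## Network metrics

Interaction matrices are plants × fungi with read counts as weights.  All
four indices are invariant to row/column permutation and positive weight
rescaling.

* **H2′** rescales the Shannon entropy of the weight distribution between
  its marginal-constrained extremes, `H2′ = (H2max − H2)/(H2max − H2min)`,
  with `H2max` the entropy of the independence table (sum of marginal
  entropies).  For `H2min`, note entropy is concave, so its minimum over
  the transportation polytope is attained at a vertex; for small integer
  matrices (total ≤ 200, ≤ 100 cells) the exact minimum is found by
  memoized enumeration of saturating allocation sequences (which generate
  all vertices), and for larger matrices a greedy largest-pair packing is
  used as an upper-bound heuristic.  Greedy packing alone is *not* exact —
  random 3×3 integer cases show ~8% suboptimality — which motivates the
  exact small-case path.  Entropies are in nats; the base cancels in the
  normalization.
* **Weighted connectance** is Bersier linkage density — the
  abundance-weighted mean effective partner count, `2^H` with base-2 row and
  column entropies — divided by total species number; it is at most 0.5.
* **WNODF** sorts rows and columns by decreasing marginal totals; each
  ordered pair contributes `100 · #{cells of the lower member that are
  positive and strictly smaller than the upper's}/fill(lower)`, and exactly
  0 when the marginal totals are tied (strict decreasing fill).  Note other
  implementations (e.g. vegan's `nestednodf`) apply the tie rule to row and
  column *fills* rather than totals; the two definitions coincide whenever
  fills and totals are strictly co-ordered, which is how the cross-check
  against vegan is set up.
* **Modularity** maximizes Barber's bipartite
  `Q = (1/W) Σ_ij [w_ij − r_i c_j/W] δ(g_i, g_j)` by label propagation
  (each guild adopts the label with the best Q gain, ties to the lowest
  label) alternated with greedy agglomerative merging, best of `n_restarts`
  seeded initializations.  On all matrices with ≤ 6 species the optimizer
  matches exhaustive partition search.

## Null models and standardization

Null matrices preserve row totals, column totals and fill.  A Patefield
draw (uniform over tables with the given marginals, built row-wise from
multivariate hypergeometric draws on the remaining column capacities) is
followed by marginal-preserving 2×2 weight shifts until the nonzero count
matches the observed fill: moving `min(w_ab, w_cd)` across a submatrix with
all four cells positive removes one or two filled cells; moves into two
empty cells add one or two.  A local dead end restarts from a fresh
Patefield draw.  Weights must be integers (read counts); non-integer input
is rejected rather than rounded.  Metrics are standardized as
`z = (obs − exp)/sd.exp` with a two-sided add-one empirical p; a
zero-variance ensemble is flagged degenerate instead of yielding an
infinite z.  `standardize_many` evaluates several metrics on one shared
ensemble, which keeps them comparable and avoids regenerating nulls.

## Robustness

One guild is removed in uniformly random order; a species of the other
guild goes extinct when *all* its partners are gone — a topological rule on
the nonzero pattern, deliberately ignoring weights, following the
area-based coextinction framework.  The grid is `x = k/n_primary`; curves
are averaged across replicates and the mean curve is fitted (fit-to-mean,
not mean-of-fits) with `y = 1 − x^a` by least squares over `log a`.  Both
`R_fitted = a/(a+1)` (the exact integral of the fitted curve) and the
trapezoidal `R_empirical` are reported; on noiseless dense curves they
agree within 0.02, and a perfect one-to-one network yields the linear decay
`a = 1`, `R = 0.5` exactly.

## Synthetic data

The generators emulate the paired two-compartment survey design over 11
host species.  Defaults: 800 OTUs per compartment with a quarter of the ids
shared (mirroring a ~14% shared fraction of the union), sampling depth
78,264 reads per sample, per-OTU lognormal baseline abundances, and
host-affinity traits evolved on a unit-height Yule tree — full Brownian
structure (λ = 1) for the epiphyte pool, none (λ = 0) for the endophyte
pool, reflecting the empirical contrast the package is designed to test.
Affinities map through a softmax with `concentration = 3`, which produces
strongly host-specialized OTUs consistent with the large specialization
z-scores such networks show; reads are multinomial at fixed depth, so
sample totals are exact.

What the generator does **not** emulate: sequencing error and chimeras,
taxonomy, within-species replicate variation, spatial or temporal
structure, and compartment asymmetries in richness.  Passing tests
therefore demonstrate correctness of the estimators and the qualitative
reproducibility of the design's contrasts, not any property of real
mangrove data.

## Problem sizes and reproducibility

The test suite and acceptance script use desk-scale sizes chosen for fast,
stable statistics: 500 simulations for permutation-test calibration and
Blomberg-K, 200 replicates for λ recovery, 50 replicate worlds (full
generator defaults) for the end-to-end Mantel contrast, 200–1000 null
matrices for standardization checks.  Every random draw flows from a master
seed; the pipeline derives per-stage seeds by hashing stage names (CRC32
xor master), so adding a stage never perturbs earlier stages' results and
identical configs give byte-identical reports.

## Known limitations

* H2min is heuristic (greedy packing) above the exact-search size cutoff;
  H2′ for large matrices is thus a tight upper bound, consistent across
  observed and null matrices.
* The modularity optimizer is a local search; restarts make it reliable at
  survey scale but global optimality is only guaranteed where brute force
  was feasible.
* λ is optimized on [0, 1] and not extended above 1.
* The swap-web null requires integer weights and can in principle need many
  restarts on pathological fill targets; the iteration cap raises a clear
  error with the achieved fill.
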