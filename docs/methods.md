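# Methods

This note documents the models, defaults and numerical choices behind
`coexmap`, and what the synthetic benchmark does and does not establish.

## Expression model and normalization

Expression lives in an `ExpressionMatrix`: genes × samples with a condition
(tissue or stage) and replicate label per sample and a unit tag (`counts`,
`cRPKM`, or `zscore` for standardized profiles; non-negativity is enforced
only for the first two). cRPKM divides counts by effective gene length in
kilobases (uniquely mappable positions / 1000) and by per-sample mapped
reads in millions. Mapped reads are the column sums of the supplied count
matrix rather than an external total, which makes normalization
self-contained and exactly scale-invariant per sample. Replicates are
averaged arithmetically per condition; all standard deviations use the n−1
denominator. Whether soft clustering consumes replicate-averaged profiles
is exposed as a flag (averaging is the default).

## Soft clustering

Fuzzy c-means (Bezdek alternating optimization) on standardized gene
profiles: memberships `u_ij = [Σ_k (d_ij/d_ik)^{2/(m−1)}]⁻¹` with Euclidean
distances, centers as membership-weighted means, objective
`J = Σ u_ij^m d_ij²`, which is non-increasing by construction. A gene at
zero distance from a center takes membership 1 there (first such center on
ties). Iteration stops when the largest membership change falls below
`tol = 1e−6` (default cap 1000 iterations). Centers are initialized from
`c` distinct gene profiles sampled with the run's seed — reproducible and
fast to converge; the price is that very unlucky initializations can reach
a local optimum, which the planted-truth tests bound in practice.

Defaults: fuzzifier m = 1.25 (common practice for standardized expression
profiles; memberships harden toward k-means as m → 1). The cluster count c
is mandatory per dataset; there is no automatic c or m selection (the
`mestimate`/`Dmin`-style heuristics are out of scope). Hard assignment is
argmax membership with ties to the lowest cluster label; *core genes* are
those whose top membership reaches `min_membership` (default 0.5, exposed
as `--min-acore`); a cluster's peak is the argmax of its center with ties
to the earliest condition.

## Co-expression modules

Per species: Pearson correlation across samples on genes pre-filtered for
variation (coefficient of variation ≥ 1 by default), soft-thresholded to an
unsigned adjacency `|r|^β` (signed `((1+r)/2)^β` available). β defaults
to 6; `scale_free_fit` reports the R² of the log–log regression of the
binned connectivity density (logarithmic bins, the unbiased binning for a
power law) and `choose_beta` picks the smallest candidate reaching R² ≥ 0.8.
The topological overlap measure combines direct adjacency and shared
neighbours; the dissimilarity 1 − TOM is clustered by average linkage and
cut *statically* at 0.9 × the maximum merge height. Clusters below
`min_size = 10` become label 0 (unassigned); surviving modules are
relabelled by decreasing size. A static cut was chosen over dynamic hybrid
tree cutting because it is fully specifiable and testable; dynamic cutting
is a natural extension point. Module eigengenes, module merging and
module-preservation statistics are out of scope.

## Cross-species module overlap

Modules are mapped to orthogroup space with one vote per family —
collapsing lineage-specific duplicates so that an expanded family cannot
inflate the overlap. The test universe N is the set of orthogroups with at
least one analysed (post-filter) gene in *each* species: the hypergeometric
test then conditions on what could actually have been drawn. Unassigned
(label 0) genes keep their orthogroups in the universe but form no module.
Every module pair gets the raw upper-tail hypergeometric p-value of its
family overlap; raw p-values are the primary output, with
Benjamini–Hochberg columns on request. Swapping the species order
transposes the count and p matrices exactly. The conserved core of a module
pair is the family intersection expanded back to per-species gene lists
(which may have unequal lengths when paralogs expand differently).

## Tau and the shared-tissue filter

`τ = Σ (1 − xᵢ/max x)/(n−1)` on condition-averaged cRPKM without log
transform; τ is undefined (NaN) for unexpressed genes. τ is scale-invariant
and monotone under specialization (zeroing a non-maximal coordinate never
lowers it). Specific genes are called at τ > 0.8.

The shared-tissue filter takes each gene's *second* condition as its
highest-expressed non-focal condition; the test group {focal, second} must
reach `min_expr = 20` (cRPKM) and every remaining condition must be at most
`1 − margin = 70%` of the test-group *minimum*. Applying the margin to the
test-group minimum is the strictest of the plausible readings (mean or
per-member margins would be looser); it is a configuration policy so the
alternatives can be tested. Results are tabulated per second condition.

## Phylostratigraphy

On a rooted species tree (unlabelled internal nodes are auto-named in
preorder), a focal gene's stratum is the position on the root→focal path of
the MRCA of the species holding members of its orthogroup (focal included).
Genes absent from the table, or in focal-only families, take the youngest
(species-specific) stratum — standard phylostratigraphy practice for
singletons. Gains at a node count orthogroups whose member-species MRCA is
that node; *core* gains additionally require every sampled leaf below the
node to retain a member (the definition is deliberately explicit because
"core" is not standardized). Gains partition the orthogroup set. Losses can
only make a family look younger, never older — the synthetic benchmark
asserts exactly that.

## Exact statistics

Hypergeometric tails and two-sided Fisher tests are evaluated through
scipy's log-space implementations; the two-sided Fisher p sums all tables
with fixed margins whose point probability is at most the observed one (up
to a ~1e−7 relative tolerance for floating-point ties — the convention of
mainstream statistical software). Conventions: upper tail at x ≤ 0 is 1, an
impossible overlap (x > min(K, n)) is 0, an all-zero Fisher table is 1. The
test suite checks both statistics against exact rational enumeration
(exhaustively for all universes up to 30, and on random instances up to
100) so the implementation route and the oracle route stay independent.
Benjamini–Hochberg adjustment is the standard step-up procedure.

## Synthetic data generator

The generator emulates a multi-tissue/stage, multi-species bulk RNA-seq
study: eight conditions with two replicates per species by default, two
species on a ladder tree, ~400 orthogroups yielding roughly 300–330 genes
per species. Gene baselines are log-normal (location 2.0, scale 1.0 on the
natural-log scale, i.e. a ~7-fold interquartile-ish spread of per-kb
expression); replicate noise is log-scale Gaussian (`noise_sd`, default
0.3); effective lengths are uniform on 0.5–3 kb; counts are Poisson-thinned
from expected expression to a fixed library size of 2·10⁶, which is what
makes cRPKM meaningful. With `noise_sd = 0` counts degenerate to rounded
expected values, so zero-noise datasets give exact downstream recoveries.

Planted structure:

- **Modules.** Four module pairs of 40 genes, each up-regulated by 3.0 on
  the log scale (≈20-fold) at its peak condition(s) — the strength of a
  clearly tissue-biased programme (muscle, gut or neural structural genes
  are routinely tens-fold enriched). A fraction φ = 0.8 of each module's
  genes sit in orthogroups shared by all species (origin at the species
  MRCA); the rest are species-specific families. One module peaks jointly
  in wing pads and gills, so those two samples share a programme and
  co-cluster in the sample dendrogram.
- **Tissue-specific genes.** Ten genes per species in each of three
  tissues, expressed at a 2% off-target floor elsewhere; with the floor and
  library-composition effects their τ sits just below 1 and comfortably
  above the 0.8 call.
- **Orthogroup scaffold.** Background families take a single-copy 1:1 form
  with probability 0.5, otherwise an origin node sampled uniformly over the
  tree with per-leaf retention probability 0.8 (at least one survivor) and
  a 10% paralog rate. Every family records its true origin node; every
  planted gene its module or tissue.

Replicate dispersion of real libraries is unknown for this design, so the
noise and dispersion defaults are free parameters of the benchmark, not
estimates of any real dataset. The generator does not model read-level
effects (mappability, positional bias, GC), batch structure, correlated
noise between tissues, or overdispersion beyond the log-normal×Poisson
compound — so passing recovery tests demonstrates correctness of the
algorithms under the stated statistical shape, not performance on real
data. Problem sizes in the tests and the acceptance script (≈320 genes per
species, 5–10 simulation seeds) are desk-scale choices that keep the full
benchmark comfortably reproducible on a laptop; genome-scale module counts
and published gene tallies are not reproduction targets because they
depend on the deposited sequencing data and external annotation resources.

## Degenerate inputs and tie-breaking

Constant gene rows are dropped (with a warning) before standardization;
zero-variance genes must be filtered before adjacency; zero-variance
samples are a named error in sample clustering. Sample clustering uses
1 − Pearson on log10(x+1) cRPKM (the transform is a flag), average linkage,
and inherits scipy's deterministic tie-breaking by input order. Cluster and
module label ties break to the lowest index / first appearance. All
randomness flows from explicit integer seeds through `numpy`'s Generator,
so identical configurations reproduce byte-identical outputs.
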