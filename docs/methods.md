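# Methods

## Problem and data model

The pipeline quantifies how parallel gene-expression evolution is across three
levels of genetic divergence. Its inputs are integer read counts (genes ×
samples) from common-garden experiments, a design table assigning each sample
a divergence level, a lineage (evolutionary replicate, population, or
species), an optional sub-replicate, and an ancestral/evolved state, plus an
optional gene → gene-set annotation. All analyses are within one common
garden (one level) except the PCA embedding, which may be joint when the
count matrices share a gene universe.

A *comparison unit* is one evolved-vs-ancestral contrast: a within-population
evolved replicate (its sub-replicates vs the garden's shared ancestral
replicates), one population, or one species (each vs its own reconstituted
ancestral replicates). The canonical design — 10×3+5 / 3×(5+5) / 2×(5+5)
samples — yields 10, 3 and 2 units and therefore 45, 3 and 1 unordered
pairwise comparisons per level.

## Differential expression

Genes are kept when CPM ≥ 1 in **every** sample of the experiment (threshold
configurable). Normalization uses TMM scaling factors: trimmed mean of
M-values against the sample whose scaled upper quartile is closest to the
mean, with two-sided 30% M-trim and 5% A-trim, unweighted, rescaled to
geometric mean 1. We omit the delta-method precision weights some TMM
implementations apply; with the deep, balanced libraries simulated here the
difference is negligible. Log-CPM uses a prior count of 0.5 (not part of the
test; only for PCA and reporting).

Per gene the model is NB with log link and offset log(library size × TMM
factor); the single covariate is the evolution state. Group means are fitted
by Newton iteration on the score in log-mean space (the score is strictly
decreasing, so the root is unique; all-zero groups have MLE 0). The test is
the likelihood-ratio statistic 2(ℓ_alt − ℓ_null) against χ²(1); log₂FC is the
log-ratio of the fitted group rates (±∞ when one group has zero counts —
downstream rank statistics handle this); BH-FDR q-values are computed across
all tested genes, with significance at q < 0.05 by default.

**Dispersion.** The estimate is a tagwise method-of-moments (Pearson-style)
statistic with an n/(n−p) degrees-of-freedom correction, averaged 50/50 with
the common (mean) dispersion across genes and floored at 1e-6. It is computed
**once per common-garden experiment**, using all the experiment's samples
with lineage × state cells as fitted means (~24 residual df in the canonical
designs), then held fixed for every unit's test. Estimating instead from each
unit's 8–10 samples (~6 df) inflates the deep tail of the LRT p-values by
more than an order of magnitude at p ≈ 1e-5, which both breaks null
calibration and — because within-population units share ancestral samples —
produces *correlated* false positives that masquerade as parallelism. The
per-experiment estimator mirrors how an edgeR-style analysis estimates one
dispersion per dataset before testing contrasts. Quasi-likelihood F-tests and
robust/empirical-Bayes dispersion moderation are intentionally out of scope;
the LRT with per-experiment moment dispersions is calibrated well enough for
the downstream statistics (null KS ≤ 0.04 at 5000 genes, ≤ 0.2% of genes at
q < 0.05 under the global null).

## Parallelism statistics

* **Jaccard** of the two units' significant gene sets; 0 when both are empty.
  Sharing is direction-agnostic by default (a gene significant in both units
  counts regardless of sign); a direction-concordant variant is available.
* **Fisher overlap test**: one-sided (greater) hypergeometric tail of the
  2×2 in/out-of-A × in/out-of-B table over the genes tested in both units.
* **Spearman ρ** of log₂FC over *all* tested genes (average ranks for ties,
  t-approximation p). Zero-variance vectors return missing.
* **Gene-set level**: classic per-set one-sided hypergeometric enrichment of
  the significant genes (sets with ≥ 5 members in the universe; BH across
  sets; no ontology-hierarchy weighting — the set universe is flat), Jaccard
  of enriched-set lists, and per-set Spearman ρ of log₂FC restricted to set
  members (≥ 5 members), averaged over the available unit pairs (45/3/1).

## Geometry

PCA is run on gene-wise-centered (not scaled) log-CPM with samples as
observations; the sign convention makes the largest-magnitude loading of each
component positive. For each level, the evolution vector runs from the
ancestral-centroid to the evolved-centroid in a chosen PC plane (defaults
PC2–PC3 and PC3–PC4). The reported angle between two levels' vectors is the
acute slope-angle arctan(|m₂−m₁|/|1+m₁m₂|) in degrees, which deliberately
collapses sense (a vector and its reverse give 0°); the full dot-product
angle in [0°, 180°] is reported alongside for interpretation. Vertical
vectors (Δfirst-axis = 0) are handled by the analytic limit 90° − arctan|m|.
No statistical test accompanies the angles; the analysis is descriptive.

## Level comparisons

Three one-sided Wilcoxon signed-rank tests per statistic, in the direction
"closer level more parallel": within-population pairwise estimates vs the
mean of the between-populations estimates; within-population vs the single
between-species estimate; between-populations estimates vs the
between-species estimate; Bonferroni correction over the three tests. Zeros
are dropped (classical convention) and tied absolute differences receive
average ranks; p is exact for n ≤ 20 (convolution of the rank generating
function over all 2ⁿ sign assignments, conditional on the observed ranks) and
uses the normal approximation with continuity and tie corrections above.
With only 3 between-populations estimates the attainable one-sided p is
bounded below by 1/8, so the third comparison can never clear a
Bonferroni-adjusted 0.05 — the `consistent` flag (observed ordering of the
means) is reported for exactly this reason.

The jackknife equalizes comparison structure: for all C(10,3) = 120 subsets
of the within-population units (lexicographic enumeration), the mean pairwise
statistic over the subset's 3 pairs is recomputed. The quoted
`empirical_p` is the fraction of subsets with estimate ≤ reference (small p =
strong support for "within more parallel"); the raw exceedance fraction
(> reference) is reported alongside, since either tail convention appears in
the literature.

## Synthetic data generator

The generator defines the study conditions the tests run under. Defaults:
5000 genes; library sizes uniform on 6.4–15.7 million (the count depth range
of typical fly whole-body RNA-seq of this design); baseline relative
expression log-normal (σ_ln = 1.2, spanning ~3 orders of magnitude, so the
CPM filter removes a realistic small tail of weakly expressed genes);
per-gene NB dispersions Gamma(shape 2, rate 40) (mean 0.05, i.e. biological
CV ~0.22, typical for inbred-panel fly RNA-seq); 5% of genes adaptive per
lineage; log₂ effect magnitudes N(1.0, 0.25) with random sign.

Per level, each lineage's adaptive set is a level-wide shared core of size
round(s·k) — drawn once per level so every pairwise overlap at a level has
the same expectation — plus lineage-private genes; s defaults to 0.6 / 0.3 /
0.1 for the three levels, which operationalizes genetic redundancy: the more
diverged two lineages, the smaller the shared fraction of their adaptive
architecture. Shared genes reuse the core sign with probability 1 (the
`sign_concordance` knob relaxes this). Counts are NB with the gene's baseline
mean scaled by 2^log₂FC in evolved samples of the owning lineage;
sub-replicates share their lineage's effects and differ only by counting
noise (they emulate phenotyping replication, not genetic drift). Gene sets
(200 sets, sizes 10–100) are uniform draws except a designated 20% "adaptive"
fraction whose members are sampled with 5× odds for adaptive genes.

What the generator does **not** emulate: mean–dispersion trends, batch or
lane effects, correlated co-expression modules, allele-frequency dynamics or
linkage, species-level baseline divergence (all lineages share one baseline
transcriptome, so a joint PCA has no species-separating PC1), and any
quantitative mapping from divergence time to s. Passing tests therefore show
the pipeline recovers a planted redundancy gradient under idealized NB noise
— not that any particular biological system has one.

## Numerical choices and degenerate inputs

Newton fits iterate to |Δlog μ| < 1e-12 (≤ 100 iterations, step-clipped);
dispersions below 1e-8 fall back to Poisson sampling in the generator and are
floored at 1e-12 when supplied to the test. Jaccard of two empty sets is 0
(logged). Wilcoxon with all-zero differences returns p = 1 with a warning.
PCA on a constant matrix, empty CPM-filter results, zero library sizes,
non-subset inputs to the overlap test, and <2 samples per DE group are hard
errors. All simulation randomness flows from one integer seed through
spawned, stage-specific generator streams, so equal configs give
byte-identical artifacts.

## Known limitations

* The NB test is a deliberately simple LRT; its deep tail is only
  approximately calibrated at these replication levels (null KS ≈ 0.03), and
  no moderation protects against dispersion outliers.
* The divergence ordering of mean Spearman ρ between the two most divergent
  levels rests on a small expected gap (sharing 0.3 vs 0.1 on 5% adaptive
  genes); across independent seeds the strict three-level ρ ordering is
  recovered in roughly 85–100% of 20-run batches, whereas the Jaccard
  ordering is essentially always recovered. The acceptance script reports
  both recovery fractions.
* Problem sizes used throughout the test suite (300-gene studies for unit
  tests, the full 5000-gene design for calibration and recovery suites, 20
  seeds for stochastic properties) are the package's chosen defaults for
  routine verification; all scale linearly if larger studies are needed.
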