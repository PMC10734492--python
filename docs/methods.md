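# Methods

## Analysis model

The pipeline analyses a paired two-timepoint cohort design: each subject
contributes one stool-derived taxon count vector at 1 month and one at
6 months, and subjects belong to a weight-gain or a weight-loss group. One
input count table is routed into three branches with different
normalizations, because the three analyses make different distributional
assumptions:

* **diversity branch** — counts rarefied (exact multivariate-hypergeometric
  subsampling, without replacement) to a common depth, so alpha-diversity
  metrics are not confounded by sequencing effort; samples below the depth
  are dropped and reported;
* **abundance branch** — unrarefied counts after the taxon filters,
  transformed to log10(relative abundance × average library size + 1);
  the transform is strictly monotone in the count at fixed library size and
  maps zero counts to exactly zero;
* **network branch** — absolute counts after the network filter, untouched:
  the compositional correlation estimator handles closure itself via
  Dirichlet resampling.

Taxon filters: a taxon is removed when its grand total is ≤ 420 counts
(equivalently, under two reads per sample at 210 samples) or, on the
diversity/abundance branches, when it appears in fewer than 10% of samples
(prevalence uses ceil for the minimum sample count: exactly 10% is kept).
Total-count filtering runs before prevalence filtering; the two only
partially commute, and this order is fixed. The network branch instead
pairs the 420-count rule with a mean-reads-per-sample ≥ 2 rule.

## Compositional correlation (SparCC-type estimator)

For strictly positive fractions x, the statistic t_ij = Var[log(x_i/x_j)]
relates to basis (absolute-abundance) variances and correlations by
t_ij = ω_i² + ω_j² − 2ρ_ij ω_i ω_j. Assuming the true correlation network
is sparse, the cross terms approximately cancel in row sums, giving the
linear system M ω² = t with M = (D−2)I + 11ᵀ and t the row sums of T. The
implementation:

1. draws fractions per sample from Dirichlet(counts + 1) — counts are
   treated as evidence about an underlying composition, never divided
   directly — 20 draws by default;
2. per draw, solves the basis system, computes ρ, then iteratively excludes
   the single most-correlated pair while max |ρ| exceeds 0.1, up to 10
   rounds, re-solving after each exclusion (ties cannot occur in practice;
   argmax is deterministic);
3. reports the element-wise median over draws, clamped to [−1, 1].

A pair exclusion removes its t_ij contribution and the matching
coefficients from M. If a taxon loses every pair, or the solve fails, a
typed `SingularBasisError` is raised — this is a real, expected condition
for small taxon sets under aggressive exclusion, and the subsampling layer
reacts to it by redrawing. Basis variances are floored at 1e-8.

Significance: each permutation replicate shuffles every taxon's counts
across samples independently (destroying co-occurrence, preserving
marginals), reruns the full estimator, and the two-sided p-value is
(1 + exceedances)/(1 + B). The +1 pseudo-count keeps p in
[1/(B+1), 1]. On 70 independent taxa at 200 samples and B = 200 the
empirical type-I rate at α = 0.05 is ~0.050 (computed in the test suite).

## Networks and subsample equalization

Edges are pairs with p strictly below α = 0.05; all filtered taxa are
nodes. Edge density is edges over all unordered node pairs; average
clustering is the mean local clustering coefficient with degree-<2 nodes
contributing 0 (the usual convention). Unequal group sizes inflate the
larger group's edge count, so the larger group is subsampled to the smaller
group's size (40 of 65 by default), 250 times, each draw without
replacement within the replicate and independent across replicates. Each
replicate re-randomizes the estimator seed from a master seed sequence, so
replicate spread includes estimator noise; a `reseed_per_replicate=False`
mode fixes the estimator seed, under which full-size "subsampling"
degenerates to identical replicates. Singular replicates are discarded and
redrawn with a retry budget of 10× the replicate count. The representative
network minimizes the Euclidean distance over z-scored
(edge count, density, clustering) from the replicate means, ties broken by
replicate index. Percent changes between timepoints are
100 × (m6 − m1)/m1 rounded to two decimals; a zero baseline is reported as
undefined rather than infinite. A full-sample (no subsampling) variant is
also emitted for comparison.

## Diversity

Shannon entropy uses base 2 (bits; configurable — conventions differ and
nothing downstream depends on the base). Faith's PD uses the rooted
convention: the sum of branch lengths of the minimal subtree connecting
the root and all observed leaves, computed by a single postorder pass.
Paired t-tests refuse zero-variance difference vectors rather than
returning NaN. PERMANOVA partitions squared Bray-Curtis distances
(SS_total = Σ_{i<j} d²/n; within-group analogues per group) into a
pseudo-F, with a free-permutation null over timepoint labels (999
permutations by default) and the +1 pseudo-count on both sides of the
p-value. The pipeline default is the standard unrestricted PERMANOVA
between timepoints; a restricted within-subject permutation mode
(``strata=subject ids``) is available for explicitly paired testing. Beta
diversity is computed on rarefied relative abundances.

## Abundance testing

Per taxon, the paired t-test runs on the log10 transform (which stabilizes
variance and respects the test's assumptions) while the reported percent
change is the ratio of raw group-mean relative abundances
(ratio-of-means; a mean-of-ratios mode exists as an option). The BH family
is all taxa of one taxonomic level within one group — mixing levels in one
family would make the test count hard to interpret — with a pooled mode
available. Results sort by phylum alphabetically, family-level labels
before genus labels, alphabetically within. The weight-return sensitivity
analysis flags subjects within 5 kg (inclusive boundary) of pre-pregnancy
weight at 6 months and reruns diversity/abundance per stratum; subjects
missing a weight are excluded with a count.

Cohort descriptives report means ± SD per group × timepoint with a compact
letter display: letters are maximal cliques of the
"not-significantly-different" graph over the four cells (paired tests
within a group, unpaired between groups — a paired test between disjoint
subject sets is not defined), and no letters are shown when one clique
covers all cells or a variable is constant.

## Synthetic cohort generator

The generator emulates the study conditions the pipeline is designed for:
105 subjects (65 gain / 40 loss) × 2 timepoints, 70 genus-level taxa in 8
phyla with GREENGENES-style lineages, and library sizes from a truncated
log-normal (median ≈ 30,785, range [12, 64,069]). The generative law is
the one the correlation estimator assumes: per design cell, log basis
abundances are multivariate normal with unit marginal variance and a
planted correlation matrix; counts are a multinomial draw of the closed
basis at the sampled library size, so rows sum exactly to their library
size. A per-subject, per-taxon normal effect (SD 0.6) is shared between a
subject's two timepoints, making the paired design informative. A
`dropout` knob can zero basis entries to emulate extra sparsity (default
0). User-supplied correlation targets are validated (symmetry, unit
diagonal — violations raise naming the offending cell) and near-PSD
matrices are repaired by eigenvalue clipping with a warning, since
hand-written block matrices are often slightly non-PSD.

Planted structure, chosen once to mirror the magnitudes the reported study
prints:

* **correlations** — the gain group's 16-taxon constant-0.6 block shrinks
  to 10 taxa at 6 months (connectivity loss); the loss group keeps a
  12-taxon block whose internal correlation rises 0.45 → 0.65 (clustering
  gain at roughly stable edge scale);
* **fold changes** — 6-month basis multipliers in the gain group with the
  reported significant-taxon magnitudes (+85% Pasteurellaceae genera,
  +65% Streptococcus, −50% Akkermansia, −47% the unknown Cerasicoccaceae
  genus, and so on); all other taxa are 1;
* **diversity** — an extra multiplier (`dominance_factor` = 3.5) on the
  most abundant taxon at 6 months in the gain group. This value was fixed
  so the realized cohort reproduces the reported Shannon shift of about
  −0.35 bits at n = 65 (measured −0.349 over 12 seeds, paired-test power
  ≈ 0.92).

`PlantedTruth` records the expected relative-abundance ratios *after*
closure (what abundance testing can actually see — multiplying one taxon
up necessarily pushes every other taxon's relative abundance down), the
per-cell correlation targets, and the expected change in effective genus
count.

What the generator does **not** emulate: read-level errors or chimeras,
real phylogenetic signal (the tree is a random seeded bifurcation with
exponential branch lengths — sufficient for Faith's PD to be well-defined,
not biologically meaningful), diet/activity covariates, or realistic
zero-inflation beyond the multinomial's own sparsity. Passing tests
therefore demonstrate correctness of the statistical machinery under the
assumed generative model, not robustness to every pathology of real 16S
data.

## Problem sizes and numerical choices

The default test suite and the acceptance script use a reduced resampling
resolution (10 estimator draws, 50 permutation replicates per p-value, 25
subsample replicates, 499 PERMANOVA permutations) — the package's fast
preset; `PipelineConfig.paper_scale()` restores 20/1000/250/999. All
randomness flows from a single master seed through named seed sequences,
so reruns are bit-identical. Percent changes are rounded to two decimals
at the reporting boundary only; internal computation is double precision
throughout.

## Known limitations

* The sparsity approximation behind the basis system degrades for very
  small taxon sets (D < ~10) and aggressive exclusion; the singular-system
  error path exists precisely for this regime.
* The permutation null shuffles taxa independently and ignores library-size
  heterogeneity across samples; calibration is verified empirically on the
  generator's law, not proven in general.
* PERMANOVA's free permutation ignores subject pairing; with two samples
  per subject the test is slightly conservative for within-subject effects.
* Percent change on ratio-of-means is sensitive to heavy-tailed abundance
  distributions; the mean-of-ratios option trades this for ratio noise.
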