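# micronet

Paired two-timepoint gut-microbiome analysis for cohort studies of weight
change: compositional (SparCC-style) co-occurrence networks with
subsample-based group-size equalization, alpha/beta diversity with paired
testing, and Benjamini-Hochberg-corrected per-taxon abundance-change
testing. The package targets the common postpartum-cohort design — two
stool samples per subject (1 and 6 months), subjects split into a
weight-gain and a weight-loss group — and ships a synthetic-cohort
generator with planted ground truth, so every stage of the analysis can be
validated without access to protected sequence data.

## The methods at its core

**Compositional correlation.** Sequencing counts are compositional:
proportions in a sample sum to one, so naive Pearson correlations between
taxa are biased. The estimator here models the variance of pairwise log
ratios, t_ij = Var[log(x_i/x_j)] = ω_i² + ω_j² − 2ρ_ij ω_i ω_j, solves a
sparsity-approximation linear system for the basis variances ω², iteratively
excludes the most-correlated pair, resamples each sample's fractions from
Dirichlet(counts + 1), and reports the median correlation matrix over
resampling draws. Two-sided significance comes from a permutation null that
shuffles each taxon's counts across samples independently:
p = (1 + #{|r_perm| ≥ |r_obs|}) / (1 + B).

**Co-occurrence networks.** Taxa are nodes; an edge is drawn where
p < 0.05. Reported metrics: edge count, edge density (edges over all
unordered node pairs) and average clustering coefficient. Because a larger
group yields a denser network through sample size alone, the larger group
is subsampled without replacement to the smaller group's size, 250 times by
default; metrics are averaged over replicates, degenerate (singular)
replicates are redrawn, and a representative replicate closest to the means
is retained for display.

**Diversity and abundance.** Alpha diversity (richness, Shannon entropy in
bits, Faith's phylogenetic diversity) is computed on counts rarefied to a
common depth (10,000 reads by default) and compared across timepoints with
two-sided paired t-tests. Beta diversity uses Bray-Curtis dissimilarity
with PERMANOVA. Per-taxon change is tested with paired t-tests on
log10-transformed relative abundance,
log10(count/total × average-library-size + 1), BH-corrected at FDR < 0.05,
with percent change reported on raw group-mean relative abundances.

## Worked example

```python
from micronet import PipelineConfig, run

report = run(PipelineConfig.fast(seed=1))
print(report["network"]["gain"]["percent_change"])
print(report["alpha_tests"]["gain"]["shannon"])
```

prints (about one minute on one CPU):

```
{'n_edges': -27.64, 'edge_density': -27.64, 'avg_clustering': -37.07}
{'mean_1m': 4.2494..., 'mean_6m': 3.8028..., 't': -4.170..., 'p': 0.000104..., 'n_pairs': 58}
```

The generated gain group loses about 28% of its network edges from 1 to 6
months (the planted correlation block shrinks at the second timepoint) and
its Shannon entropy drops by ~0.45 bits with a strongly significant paired
test — the two planted signatures of weight gain in the synthetic cohort.
The loss group, generated with a stable correlation block and no abundance
effects, shows no significant diversity change and zero BH-significant
taxa.

The same analysis is scriptable from a shell:

```sh
micronet simulate --out data/ --seed 1
micronet run --out results/ --seed 1
```

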