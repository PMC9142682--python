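# eqtlnet

Bipartite eQTL networks with FDR-based edge significance: degree centrality,
its reproducibility, and its relationship to genetic diversity and trait
heritability.

## The problem

Expression quantitative trait locus (eQTL) mapping associates SNP genotypes
with gene expression one pair at a time, but regulatory influence is a
network property: a SNP that perturbs many genes is biologically different
from one that perturbs a single transcript. `eqtlnet` casts the complete
matrix of SNP–gene association statistics as a bipartite network and asks
which definition of a network edge — and hence of node *degree* — yields a
reproducible, biologically meaningful centrality measure.

For SNP *i* and gene *j* the association is the covariate-adjusted linear
model

    G_j = X^T alpha + beta_ij * S_i,

with a Wald statistic z_ij = beta_hat/SE and two-sided p-value. Sparse
adjacency representations threshold a multiple-testing measure Y_ij:

    a_ij = |z_ij| * I{ Y_ij < tau },        tau in {0.05, 0.1, 0.15, 0.2},

where Y is a Storey q-value (QV), a local false discovery rate (LFDR), or a
streamed adaptation of Benjamini–Hochberg computed from the top-K p-values
out of N tests (BH): q_K = (N/K) p_K, q_i = min((N/i) p_i, q_{i+1}). The
dense representation keeps every nominal p-value (a_ij = p_ij) and defines
the non-null-proportion (NP) degree of a node as 1 − pi0_hat of its incident
p-values. Sparse degree is the sum of incident edge weights (binary or
|z|-weighted), split into cis (SNP within 1 Mb of the gene's TSS) and trans
parts.

Downstream analyses mirror how such a degree would be used:

* **Stability** — split the samples in half, run the full pipeline in each
  half, and correlate the two degree vectors (Spearman, five repeats);
  cross-network correlations are pooled with a Fisher-z DerSimonian–Laird
  random-effects meta-analysis.
* **Genetic diversity** — per-gene nucleotide diversity pi and Tajima's D,
  correlated with gene degree across datasets.
* **Heritability** — stratified LD-score regression
  E[chi2_j] = N * sum_c l(j,c) tau_c + 1 on annotations derived from degree
  (binary top-quartile SNP annotation; continuous gene-window annotation),
  reporting tau, the standardized tau* = tau sd(c)/(h2/M), and enrichment
  with block-jackknife errors.

Because the motivating datasets (population-scale genotype + RNA-seq
cohorts) are access-controlled, the package ships a first-class synthetic
data module: Hardy–Weinberg dosages with a MAF ≥ 0.05 filter, expression
with a sparse planted cis/trans eQTL architecture plus covariate structure,
neutral infinite-sites coalescent haplotypes, and GWAS chi-square statistics
drawn from the LD-score regression model. Every generator is deterministic
given a seed, so the whole analysis is reproducible end to end.

## Worked example

```python
import numpy as np
import eqtlnet as eq

# simulate a cohort: 400 samples, 200 common SNPs, 50 genes, 50 planted eQTLs
G = eq.simulate_genotypes(n_samples=400, n_snps=200, seed=11)
genes = eq.simulate_genes(50, seed=12)
X = eq.simulate_covariates(400, 3, seed=13)
arch = eq.random_architecture(G, genes, n_cis=30, n_trans=20,
                              beta_cis=1.0, beta_trans=0.5,
                              n_covariates=3, covariate_effect_sd=0.3, seed=14)
E = eq.simulate_expression(G, genes, arch, X, seed=15)

# map every SNP-gene pair and attach streamed-BH edge significance
res = eq.map_eqtls(G, E, X, cis_window=1_000_000)
meas = eq.compute_significance(res, kind="BH")
print(f"tests: {res.n_tests_cis} cis, {res.n_tests_trans} trans")

# |z|-weighted sparse network at tau = 0.05 and SNP degree
adj = eq.build_sparse_adjacency(res, meas, tau=0.05, weighted=True)
deg = eq.degree_sparse(adj, axis="SNP")
print(f"edges at tau=0.05: {len(adj.edges)}")
top = np.argmax(deg.total)
print(f"hub SNP {deg.node_ids[top]}: degree {deg.total[top]:.1f} "
      f"(cis {deg.cis_part[top]:.1f}, trans {deg.trans_part[top]:.1f})")

# split-sample reproducibility of the degree
rep = eq.split_sample_stability(
    G, E, X, eq.StabilityConfig(measures=("BH",), taus=(0.05,),
                                weighted=(True,)),
    n_repeats=5, seed=16)
s = rep.summary
rho = s[(s.axis == "SNP") & (s.stratum == "full")]["mean_rho"].iloc[0]
print(f"split-half degree Spearman rho (5 repeats): {rho:.3f}")
```

Output:

```
tests: 1387 cis, 8613 trans
edges at tau=0.05: 52
hub SNP snpchr2_590000: degree 19.8 (cis 19.8, trans 0.0)
split-half degree Spearman rho (5 repeats): 0.868
```

The mapping performed 10,000 Wald tests; 52 pairs survive the BH measure at
tau = 0.05. The highest-degree SNP accumulates |z| weight 19.8, all of it
from local (cis) genes. Splitting the 400 samples into independent halves
five times and rerunning the pipeline per half gives a mean Spearman
correlation of 0.87 between the halves' SNP degree vectors — the planted
regulatory architecture is recovered reproducibly.

## Command line

Every stage is also exposed as a subcommand over a YAML config
(`eqtlnet run-all --seed 1 --out runs/demo`); each run directory contains
TSV outputs plus a `manifest.json` with the config hash, per-stage seeds,
and a checksum per file, and reruns with the same config are bit-identical.

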