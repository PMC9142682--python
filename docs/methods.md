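# Methods

## Model and pipeline

The package analyses the bipartite network implied by exhaustive eQTL
mapping. Expression of gene *j* is regressed on the dosage of SNP *i* with
an intercept and a covariate matrix X (population-structure components, sex,
platform, latent expression factors — consumed as given, never estimated
here):

    G_j = X^T alpha + beta_ij S_i + e,    e ~ N(0, sigma^2).

Covariates are projected out of both expression and dosages once per data
set (QR projection); by Frisch–Waugh–Lovell the per-pair slope, its standard
error, and the Wald statistic z = beta_hat/SE are then single matrix
products, which is what makes the all-pairs scan cheap. Residual degrees of
freedom are r − c − 2 (intercept, c covariates, dosage). p-values are
two-sided standard normal by default so that they are exactly consistent
with the z-statistics used as edge weights; an exact t option exists and
matters only at small sample sizes. A pair is cis when the SNP lies on the
gene's chromosome within 1 Mb of its transcription start site, boundary
inclusive and strand ignored; everything else is trans. SNPs with zero
dosage variance after projection are flagged untestable and excluded from
the multiple-testing denominators.

### Edge significance measures

Four measures Y in [0, 1] define network edges; all are monotone
nondecreasing in p within their scope:

* **QV** — Storey q-value, q(p_i) = min_{t >= p_i} pi0_hat m t / #{p <= t}.
* **LFDR** — local FDR pi0 f0(z)/f(z); f is estimated by Lindsey's method
  (histogram counts over 120 bins fit by a Poisson GLM on a degree-7
  polynomial basis, giving a smooth log-density); f0 is the theoretical
  N(0,1) null by default, with an empirical-null option (median/central-
  quartile rescaling). Density estimation requires a configurable minimum
  number of statistics (200 by default). An optional isotonic step enforces
  lfdr nonincreasing in |z|.
* **BH** — the streamed Benjamini–Hochberg adaptation: for the K smallest
  p-values out of N tests, q_K = (N/K)p_K and q_i = min((N/i)p_i, q_{i+1}).
  Outputs are clamped to 1 (the raw recursion can exceed 1; clamping
  preserves FDR semantics). With K = N this is exactly the textbook step-up
  adjustment, which is asserted against an independent implementation in the
  tests. Because only N (a count) and the retained p-values are needed, BH
  is valid on threshold-streamed mapping output; QV/LFDR/NP require dense
  storage.
* **NP** — the non-null proportion 1 − pi0_hat of a p-value collection;
  used as the dense degree of a node from its complete incident p-vector
  (genome-wide only — no cis/trans split, since the dense representation is
  not stratified).

Default scoping follows the measures' intended use: QV and LFDR per SNP
(across that SNP's genes), BH globally per stratum; per-gene and global
scopes are exposed. In location-specific mode all measures are computed
separately for the cis and trans test sets; genome-wide mode pools them.

**pi0 estimation.** pi0(lambda) = #{p > lambda}/(m(1 − lambda)) is computed
over lambda = 0.05, 0.10, …, 0.95 and smoothed by a natural cubic smoothing
spline with ~3 effective degrees of freedom, evaluated at the largest grid
point — the convention of the standard q-value implementation. The
smoothing penalty that achieves df = 3 depends only on the grid, not the
data, so it is solved once by bisection on the smoother-matrix trace and
cached. A global cubic polynomial extrapolated to lambda = 1 was evaluated
as an alternative and rejected: its boundary extrapolation roughly doubles
the estimator's sampling standard deviation. Estimates are clamped to
(0, 1] with a floor of 1/m; degenerate fits fall back to the raw estimate
at the largest lambda.

### Networks and degree

Sparse edges exist where Y < tau strictly (the indicator is I{Y < tau}),
with weight |z| (weighted) or 1 (unweighted); tau sweeps
{0.05, 0.1, 0.15, 0.2}. Degree is the row/column sum of incident weights,
decomposed into cis and trans parts under location-specific scope. The
dense representation stores every nominal p-value; the NP degree applies
the pi0 machinery per node (minimum 10 incident tests, configurable).

Annotations derived from degree: (1) binary top-quartile — 1 iff degree is
at or above the 75th percentile (linear-interpolation quantile; all-equal
degrees degenerate to all-ones with a warning); (2) continuous gene-window —
each SNP inside a gene span ± 50 kb receives that gene's degree, overlaps
resolved by maximum (a deliberate tie-break; the alternative of summing
overlapping gene degrees would conflate window density with centrality).
Gene spans are used when provided, otherwise the TSS point. For comparison
with regulatory networks whose edge weights can be negative, the transform
W = ln(e^w + 1) is provided in overflow-safe log-sum-exp form.

### Stability protocol

Samples are randomly split into two disjoint, exhaustive halves (sizes
differ by at most one when r is odd); the full pipeline (mapping, measures,
adjacency, degree) runs independently per half; the Spearman correlation
between the halves' degree vectors is recorded per configuration
(measure × tau × weighting × stratum × axis) and averaged over five repeats
(configurable). Covariates are subset per half, not re-estimated. The node
inclusion rule defaults to every node testable in both halves, zero-degree
nodes included (average ranks handle the ties); a nonzero-in-either rule is
exposed. A network with no edges in any repeat yields an undefined (NaN)
correlation rather than an error.

Cross-network and cross-dataset correlations use the same Spearman-on-
shared-nodes machinery. Correlations are pooled by a random-effects
meta-analysis: Fisher z = atanh(rho) with variance 1/(n − 3), the
DerSimonian–Laird moment estimator for the between-study variance, inverse-
variance pooling, and tanh back-transformation of the estimate and its 95%
CI.

### Genetic diversity

For a haplotype alignment of h sequences with derived-allele count j_s at
site s, per-site nucleotide diversity is
pi = [sum_s 2 j_s (h − j_s)/(h(h−1))]/L, with monomorphic positions
contributing zero but counting in L. Tajima's D uses the standard
sample-size constants (a1, a2, b1, b2, c1, c2, e1, e2) with the per-locus
pairwise diversity in the numerator and is undefined (NaN) when there are
no segregating sites; it depends only on folded counts j(h − j) and is
therefore invariant to ancestral/derived relabelling. Both statistics are
checked against independently coded oracles (exhaustive pairwise
differences; a from-scratch constants implementation).

### Heritability enrichment

LD scores l(j,c) = sum_k a_ck r2_jk use unadjusted squared Pearson
correlations between dosage vectors within a 1 Mb window (self term
included), or a user-supplied r2 matrix. tau is estimated by least squares
on E[chi2_j] = N sum_c l(j,c) tau_c + 1 with the intercept fixed at 1 (a
free intercept is available for confounded scenarios); the regression is
unweighted by default. Standard errors for tau, tau*, and enrichment come
from a leave-one-block-out jackknife over contiguous SNP blocks (default
20 blocks at the problem sizes used here; reference implementations use
200, and the count is configurable). Jackknife blocks whose leave-out tau
implies non-positive total heritability contribute no enrichment
pseudo-value. Enrichment of the all-ones annotation is identically 1 by
construction, which the tests assert.

## Synthetic data: what it emulates and what it does not

The generators define the study conditions for every test:

* **Genotypes** — hard-called dosages as the sum of two Bernoulli(MAF)
  alleles (Hardy–Weinberg), MAF uniform on [0.05, 0.5], empirical MAF
  refiltered at 0.05. Hard calls keep Hardy–Weinberg checks exact;
  continuous (imputed) dosages are accepted on input but not generated.
  No linkage disequilibrium or population structure is simulated.
* **Expression** — planted sparse cis/trans effects plus Gaussian covariate
  structure and residual noise; trans edges are planted only across
  chromosomes so labels are unambiguous. Default architecture: 400 samples,
  200 SNPs × 50 genes, 40 cis (|beta| = 1.0) + 10 trans (|beta| = 0.5)
  effects, noise SD 1 — effect sizes chosen so that planted edges are
  individually detectable at the default sample sizes while trans signal is
  weaker and sparser than cis, the regime the stability comparisons probe.
  Values are emitted already normalized; no count-level noise model.
* **Haplotypes** — Kingman coalescent (exponential waiting times at rate
  k(k−1)/2) with Poisson mutations on branches under infinite sites, no
  recombination; sufficient for the pi and Tajima's D expectations
  (E[S] = theta sum 1/i, E[pi] = theta) at desk scale.
* **GWAS statistics** — independent 1-df noncentral chi-squares with mean
  N sum_c l(j,c) tau_c + 1; LD enters only through the mean, matching the
  regression model being tested without simulating correlated genotypes.

Passing tests therefore demonstrate correctness of the statistical
machinery and qualitative behaviours (right-skewed degree distributions,
higher stability with weighting and larger n, cis above trans), not
robustness to LD structure, expression normalization artefacts, or
population stratification in real cohorts.

## Numerical choices and degenerate inputs

* Strict inequality Y < tau at the threshold; ties at tau produce no edge.
* Zero-variance SNPs: untestable in mapping (excluded from N), excluded
  from LD partner sums with a warning.
* Constant vectors in Spearman give NaN with a warning; |rho| = 1 is nudged
  inside (−1, 1) before Fisher transformation.
* Adapted-BH and q-values clamped to [0, 1]; lfdr clamped to [0, 1].
* Collinear LD-score columns are rejected with the offending annotation
  named.
* Odd sample counts split into halves of size ceil(r/2) and floor(r/2).
* Per-stage seeds are derived deterministically from the master seed, so
  stage subsets reproduce full-run values and reruns are bit-identical.

## Problem sizes

Tests and the acceptance script run at desk scale: mapping instances up to
1,000 SNPs × 100 genes at n = 400–800 samples, 2,000 coalescent replicates
at n = 20/theta = 5, LD-score regressions at M = 10,000 SNPs over 50 seeds,
and 20-replicate stability sweeps over n ∈ {100, 200, 400, 800}. These
sizes were chosen so the full suite completes in minutes while keeping
Monte-Carlo error well inside the asserted tolerances.

## Known limitations

* No LD/recombination maps, no PEER/PC estimation, no permutation-based
  eQTL calling; covariates are consumed as given.
* The NP degree requires dense storage of all tests and is genome-wide
  only.
* The LFDR density fit can be unstable for very small or very heavy-tailed
  inputs; the minimum-statistics floor guards the common failure mode.
* Enrichment jackknife assumes contiguous blocks are approximately
  exchangeable; with strong long-range LD (not simulated here) block size
  would need care.
* The gene-window annotation resolves overlaps by maximum; other
  conventions (sum, closest gene) are not implemented.
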