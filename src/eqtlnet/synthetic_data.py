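"""Synthetic inputs for the eQTL-network pipeline.

Generates every input the downstream stages consume: biallelic SNP dosages
under Hardy-Weinberg equilibrium, normalized expression with a sparse planted
set of cis/trans eQTL effects plus covariate structure, neutral haplotype
alignments from an infinite-sites Kingman coalescent, and GWAS chi-square
statistics drawn from the stratified LD-score regression model
E[chi2_j] = N * sum_c l(j,c) tau_c + 1.

All generators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "GeneTable",
    "ExpressionMatrix",
    "CovariateMatrix",
    "PlantedArchitecture",
    "HaplotypeAlignment",
    "simulate_genotypes",
    "simulate_genes",
    "simulate_covariates",
    "random_architecture",
    "simulate_expression",
    "simulate_haplotypes",
    "simulate_gwas_chisq",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Samples x SNPs dosage matrix with coordinates and allele frequencies.

    Dosages are allele counts in [0, 2]. ``maf`` is the empirical minor
    allele frequency; retained SNPs satisfy maf >= 0.05 after filtering.
    """

    dosages: np.ndarray          # (r, n) float
    snp_ids: list[str]
    chrom: np.ndarray            # (n,) str
    pos: np.ndarray              # (n,) int, 1-based
    maf: np.ndarray              # (n,) float in (0, 0.5]
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.min(initial=0.0) < 0 or self.dosages.max(initial=0.0) > 2:
            raise ValueError("dosages must lie in [0, 2]")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("snp_ids must be unique")
        if not self.sample_ids:
            self.sample_ids = [f"sample{i}" for i in range(self.dosages.shape[0])]

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def subset_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages[idx], list(self.snp_ids), self.chrom.copy(),
            self.pos.copy(), self.maf.copy(),
            [self.sample_ids[i] for i in np.atleast_1d(idx)],
        )

    # -- I/O ----------------------------------------------------------------
    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.dosages.T, index=self.snp_ids, columns=self.sample_ids)
        df.index.name = "snp_id"
        df.to_csv(path, sep="\t")

    def to_vcf(self, path) -> None:
        """Write a minimal VCF (REF=A, ALT=G, GT from hard-called dosages)."""
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for c in dict.fromkeys(self.chrom.tolist()):
                fh.write(f"##contig=<ID={c}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(self.sample_ids) + "\n")
            for j in range(self.n_snps):
                calls = [gt_map[int(round(d))] for d in self.dosages[:, j]]
                fh.write(f"{self.chrom[j]}\t{self.pos[j]}\t{self.snp_ids[j]}"
                         f"\tA\tG\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n")


@dataclass
class GeneTable:
    """Gene identifiers with transcription start sites (1-based)."""

    gene_ids: list[str]
    chrom: np.ndarray
    tss: np.ndarray              # (m,) int, 1-based
    span_start: np.ndarray | None = None   # optional gene body, 1-based inclusive
    span_end: np.ndarray | None = None

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_bed(self, path) -> None:
        """4-column BED of TSS points (half-open, 0-based)."""
        with open(path, "w") as fh:
            for g, c, t in zip(self.gene_ids, self.chrom, self.tss):
                fh.write(f"{c}\t{t - 1}\t{t}\t{g}\n")


@dataclass
class ExpressionMatrix:
    """Samples x genes normalized expression, paired with a GenotypeMatrix."""

    values: np.ndarray           # (r, m)
    genes: GeneTable
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.isnan(self.values).any():
            raise ValueError("expression contains missing values")
        if not self.sample_ids:
            self.sample_ids = [f"sample{i}" for i in range(self.values.shape[0])]

    @property
    def gene_ids(self) -> list[str]:
        return self.genes.gene_ids

    def subset_samples(self, idx: np.ndarray) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[idx], self.genes,
                                [self.sample_ids[i] for i in np.atleast_1d(idx)])

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.values.T, index=self.genes.gene_ids,
                          columns=self.sample_ids)
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t")


@dataclass
class CovariateMatrix:
    """Samples x covariates design (intercept added downstream)."""

    values: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        r = self.values.shape[0]
        design = np.column_stack([np.ones(r), self.values])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError("covariate design is rank deficient with intercept")

    @property
    def n_covariates(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, idx: np.ndarray) -> "CovariateMatrix":
        return CovariateMatrix(self.values[idx], list(self.names))

    def to_tsv(self, path, sample_ids: Sequence[str] | None = None) -> None:
        ids = sample_ids or [f"sample{i}" for i in range(self.values.shape[0])]
        df = pd.DataFrame(self.values.T, index=self.names, columns=ids)
        df.index.name = "covariate"
        df.to_csv(path, sep="\t")


@dataclass
class PlantedArchitecture:
    """Ground-truth eQTL effects planted into simulated expression."""

    true_edges: list[tuple[int, int, float, bool]]   # (snp_idx, gene_idx, beta, cis)
    noise_sd: float
    covariate_effects: np.ndarray | None = None      # (c, m)

    def __post_init__(self) -> None:
        pairs = [(s, g) for s, g, _, _ in self.true_edges]
        if len(set(pairs)) != len(pairs):
            raise ValueError("each (snp, gene) pair may appear at most once")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    def to_tsv(self, path, snp_ids: Sequence[str], gene_ids: Sequence[str]) -> None:
        rows = [(snp_ids[s], gene_ids[g], b, int(c)) for s, g, b, c in self.true_edges]
        pd.DataFrame(rows, columns=["snp_id", "gene_id", "beta", "cis"]).to_csv(
            path, sep="\t", index=False)


@dataclass
class HaplotypeAlignment:
    """Binary haplotype matrix under the infinite-sites model.

    Rows are haplotypes, columns segregating sites; every column is
    polymorphic. ``positions`` lie in (0, locus_length].
    """

    haplotypes: np.ndarray       # (h, L) int8 in {0,1}
    locus_length: float
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.size:
            counts = self.haplotypes.sum(axis=0)
            h = self.haplotypes.shape[0]
            if ((counts == 0) | (counts == h)).any():
                raise ValueError("monomorphic column in haplotype alignment")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]


# ---------------------------------------------------------------------------
# genotype / expression generators
# ---------------------------------------------------------------------------

def simulate_genotypes(
    n_samples: int,
    n_snps: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    chrom_layout: Sequence[tuple[str, int, int]] | None = None,
    seed: int = 0,
) -> GenotypeMatrix:
    """Draw hard-called dosages as the sum of two Bernoulli(maf) alleles.

    Parameters
    ----------
    maf_range
        Interval the per-SNP allele frequency is drawn from; the lower bound
        must be >= 0.05 (the standard common-variant filter).
    chrom_layout
        Sequence of ``(chrom, n_snps_on_chrom, spacing_bp)``; defaults to the
        SNPs split evenly over two chromosomes at 10 kb spacing.

    SNPs whose empirical MAF falls below 0.05 are dropped, so the returned
    matrix always satisfies the MAF filter.
    """
    lo, hi = maf_range
    if lo > hi:
        raise ValueError("degenerate maf_range: lower bound exceeds upper")
    if lo < 0.05:
        raise ValueError("maf_range lower bound must be >= 0.05")
    if hi > 0.5:
        raise ValueError("maf_range upper bound must be <= 0.5")
    if n_samples < 2:
        raise ValueError("need at least two samples")

    if chrom_layout is None:
        half = n_snps - n_snps // 2
        chrom_layout = [("chr1", half, 10_000), ("chr2", n_snps - half, 10_000)]
    total = sum(k for _, k, _ in chrom_layout)
    if total != n_snps:
        raise ValueError("chrom_layout SNP counts must sum to n_snps")

    rng = np.random.default_rng(seed)
    maf_true = rng.uniform(lo, hi, size=n_snps)
    dosages = rng.binomial(2, maf_true[None, :], size=(n_samples, n_snps)).astype(float)

    chrom = np.concatenate([np.repeat(c, k) for c, k, _ in chrom_layout])
    pos = np.concatenate([
        (np.arange(k, dtype=np.int64) + 1) * sp for _, k, sp in chrom_layout
    ])

    p_hat = dosages.mean(axis=0) / 2.0
    maf = np.minimum(p_hat, 1.0 - p_hat)
    keep = maf >= 0.05
    snp_ids = [f"snp{c}_{p}" for c, p in zip(chrom, pos)]
    return GenotypeMatrix(
        dosages[:, keep],
        [s for s, k in zip(snp_ids, keep) if k],
        chrom[keep], pos[keep], maf[keep],
    )


def simulate_genes(
    n_genes: int,
    chrom_layout: Sequence[tuple[str, int, int]] | None = None,
    seed: int = 0,
    span_bp: int = 20_000,
) -> GeneTable:
    """Place gene TSSs on chromosomes; gene bodies extend span_bp downstream."""
    if chrom_layout is None:
        half = n_genes - n_genes // 2
        chrom_layout = [("chr1", half, 200_000), ("chr2", n_genes - half, 200_000)]
    rng = np.random.default_rng(seed)
    chrom = np.concatenate([np.repeat(c, k) for c, k, _ in chrom_layout])
    tss = np.concatenate([
        (np.arange(k, dtype=np.int64) + 1) * sp + rng.integers(0, sp // 4, size=k)
        for _, k, sp in chrom_layout
    ])
    gene_ids = [f"gene{i}" for i in range(len(chrom))]
    return GeneTable(gene_ids, chrom, tss, tss.copy(), tss + span_bp)


def simulate_covariates(n_samples: int, n_covariates: int, seed: int = 0) -> CovariateMatrix:
    """Generic standard-normal covariates (stand-ins for PCs/sex/PEER factors)."""
    rng = np.random.default_rng(seed)
    vals = rng.standard_normal((n_samples, n_covariates))
    return CovariateMatrix(vals, [f"cov{i}" for i in range(n_covariates)])


def random_architecture(
    G: GenotypeMatrix,
    genes: GeneTable,
    n_cis: int,
    n_trans: int,
    beta_cis: float = 0.8,
    beta_trans: float = 0.8,
    noise_sd: float = 1.0,
    covariate_effect_sd: float = 0.0,
    n_covariates: int = 0,
    cis_window: int = 1_000_000,
    seed: int = 0,
) -> PlantedArchitecture:
    """Sample a sparse planted eQTL architecture.

    Cis edges link SNP-gene pairs on the same chromosome within the window;
    trans edges are drawn only between different chromosomes so the labels
    are unambiguous.
    """
    rng = np.random.default_rng(seed)
    same = (G.chrom[:, None] == genes.chrom[None, :])
    dist = np.abs(G.pos[:, None].astype(np.int64) - genes.tss[None, :].astype(np.int64))
    cis_ok = same & (dist <= cis_window)
    trans_ok = ~same

    def _pick(mask: np.ndarray, k: int) -> list[tuple[int, int]]:
        snp_idx, gene_idx = np.nonzero(mask)
        if len(snp_idx) < k:
            raise ValueError(f"only {len(snp_idx)} eligible pairs for {k} edges")
        chosen = rng.choice(len(snp_idx), size=k, replace=False)
        return [(int(snp_idx[i]), int(gene_idx[i])) for i in chosen]

    edges: list[tuple[int, int, float, bool]] = []
    for s, g in _pick(cis_ok, n_cis):
        edges.append((s, g, float(rng.choice([-1, 1]) * beta_cis), True))
    for s, g in _pick(trans_ok, n_trans):
        edges.append((s, g, float(rng.choice([-1, 1]) * beta_trans), False))

    cov_fx = None
    if n_covariates > 0:
        cov_fx = rng.normal(0.0, covariate_effect_sd, size=(n_covariates, genes.n_genes))
    return PlantedArchitecture(edges, noise_sd, cov_fx)


def simulate_expression(
    G: GenotypeMatrix,
    genes: GeneTable,
    arch: PlantedArchitecture,
    X: CovariateMatrix | None = None,
    seed: int = 0,
) -> ExpressionMatrix:
    """Expression = planted genetic effects + covariate effects + Gaussian noise."""
    r, n = G.dosages.shape
    m = genes.n_genes
    rng = np.random.default_rng(seed)
    values = rng.normal(0.0, arch.noise_sd, size=(r, m))
    for s, g, beta, _ in arch.true_edges:
        if not (0 <= s < n and 0 <= g < m):
            raise IndexError(f"planted edge ({s}, {g}) out of range")
        values[:, g] += beta * G.dosages[:, s]
    if arch.covariate_effects is not None:
        if X is None:
            raise ValueError("architecture has covariate effects but X is None")
        c = X.n_covariates
        if arch.covariate_effects.shape != (c, m):
            raise ValueError("covariate_effects shape mismatch")
        values += X.values @ arch.covariate_effects
    return ExpressionMatrix(values, genes, list(G.sample_ids))


# ---------------------------------------------------------------------------
# neutral coalescent haplotypes
# ---------------------------------------------------------------------------

def simulate_haplotypes(
    n_haplotypes: int,
    theta: float,
    locus_length: float = 10_000.0,
    seed: int = 0,
) -> HaplotypeAlignment:
    """Neutral infinite-sites haplotypes from a Kingman coalescent.

    Coalescence times are exponential with rate k(k-1)/2 while k lineages
    remain; mutations fall on branches as a Poisson process with rate
    theta/2 per unit of coalescent branch length, each creating one new
    segregating site at a uniform position. No recombination.
    """
    if n_haplotypes < 2:
        raise ValueError("need at least two haplotypes")
    if theta <= 0:
        raise ValueError("theta must be positive")
    rng = np.random.default_rng(seed)
    n = n_haplotypes

    # active lineages carry the set of leaf indices below them
    node_time = {i: 0.0 for i in range(n)}
    leaves_below = {i: frozenset([i]) for i in range(n)}
    active = list(range(n))
    branches: list[tuple[frozenset, float]] = []   # (descendant leaves, length)
    t = 0.0
    next_node = n
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        for child in (a, b):
            branches.append((leaves_below[child], t - node_time[child]))
        node_time[next_node] = t
        leaves_below[next_node] = leaves_below[a] | leaves_below[b]
        active = [x for x in active if x not in (a, b)] + [next_node]
        next_node += 1

    lengths = np.array([ln for _, ln in branches])
    total_len = lengths.sum()
    n_mut = rng.poisson(theta / 2.0 * total_len)
    cols = []
    positions = []
    if n_mut > 0:
        which = rng.choice(len(branches), size=n_mut, p=lengths / total_len)
        site_pos = rng.uniform(0.0, locus_length, size=n_mut)
        for b_idx, posn in zip(which, site_pos):
            col = np.zeros(n, dtype=np.int8)
            col[list(branches[b_idx][0])] = 1
            cols.append(col)
            positions.append(posn)
    hap = (np.column_stack(cols) if cols else np.zeros((n, 0), dtype=np.int8))
    positions = np.asarray(positions, dtype=float)
    order = np.argsort(positions)
    return HaplotypeAlignment(hap[:, order], float(locus_length), positions[order])


# ---------------------------------------------------------------------------
# GWAS chi-square statistics under the S-LDSC model
# ---------------------------------------------------------------------------

def simulate_gwas_chisq(
    annotations: np.ndarray,
    tau: np.ndarray,
    n_gwas: int,
    ld_r2: np.ndarray | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-SNP chi-square statistics with E[chi2_j] = N * sum_c l(j,c) tau_c + 1.

    Each statistic is an independent 1-df noncentral chi-square whose
    noncentrality is the genetic contribution to the mean; LD enters only
    through the LD scores l(j,c) = sum_k a_ck r2_jk (identity if ``ld_r2``
    is None).
    """
    A = np.asarray(annotations, dtype=float)
    if A.ndim == 1:
        A = A[:, None]
    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    if A.shape[1] != tau.shape[0]:
        raise ValueError("annotation columns must match tau length")
    L = A if ld_r2 is None else np.asarray(ld_r2, dtype=float) @ A
    nc = n_gwas * (L @ tau)
    if (nc < -1e-12).any():
        raise ValueError("negative implied noncentrality: E[chi2] < 1")
    nc = np.clip(nc, 0.0, None)
    rng = np.random.default_rng(seed)
    # noncentral chi2 with 1 df: (Z + sqrt(nc))^2
    chisq = (rng.standard_normal(len(nc)) + np.sqrt(nc)) ** 2
    return pd.DataFrame({
        "snp_id": [f"snp{i}" for i in range(len(nc))],
        "chisq": chisq,
        "N": n_gwas,
    })
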