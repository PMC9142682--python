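"""Nucleotide diversity and Tajima's D, and their correlation with degree.

Per-site nucleotide diversity for a haplotype alignment of h sequences over
a locus of length L with derived-allele count j_s at segregating site s:

    pi = [ sum_s 2 j_s (h - j_s) / (h (h - 1)) ] / L

(monomorphic positions contribute 0 but count in L). Tajima's D contrasts
the per-locus pairwise diversity with Watterson's estimator S / a1 using the
standard sample-size constants (a1, a2, b1, b2, c1, c2, e1, e2):

    D = (pi_locus - S / a1) / sqrt(e1 S + e2 S (S - 1))

D is undefined (NaN) when there are no segregating sites, and is invariant
to relabelling ancestral/derived alleles since it depends only on the
folded products j (h - j).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import DegreeVector
from .stability import MetaAnalysisResult, random_effects_meta, spearman
from .synthetic_data import HaplotypeAlignment

__all__ = [
    "DiversityTable",
    "nucleotide_diversity",
    "tajimas_d",
    "tajima_constants",
    "correlate_degree_diversity",
]


@dataclass
class DiversityTable:
    """Per-gene diversity statistics."""

    table: pd.DataFrame   # gene_id, pi, tajima_d, n_segregating

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _pairwise_sum(hap: HaplotypeAlignment) -> float:
    """Sum over sites of 2 j (h - j) / (h (h - 1)) — per-locus diversity."""
    h = hap.n_haplotypes
    if h < 2:
        raise ValueError("need at least two haplotypes")
    j = hap.haplotypes.sum(axis=0).astype(float)
    return float(np.sum(2.0 * j * (h - j)) / (h * (h - 1)))


def nucleotide_diversity(hap: HaplotypeAlignment) -> float:
    """Per-site nucleotide diversity pi (per bp)."""
    if hap.locus_length <= 0:
        raise ValueError("locus_length must be positive")
    return _pairwise_sum(hap) / hap.locus_length


def tajima_constants(n: int) -> dict[str, float]:
    """Standard Tajima sample-size constants for n sequences."""
    a1 = np.sum(1.0 / np.arange(1, n))
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(hap: HaplotypeAlignment) -> float:
    """Tajima's D; NaN when there are no segregating sites."""
    h = hap.n_haplotypes
    if h < 2:
        raise ValueError("need at least two haplotypes")
    s = hap.n_sites
    if s == 0:
        return float("nan")
    k = tajima_constants(h)
    pi_locus = _pairwise_sum(hap)
    var = k["e1"] * s + k["e2"] * s * (s - 1)
    return float((pi_locus - s / k["a1"]) / np.sqrt(var))


def correlate_degree_diversity(
    gene_deg: DegreeVector,
    diversity_tables: list[DiversityTable],
    statistic: str = "pi",
) -> tuple[list[tuple[float, int]], MetaAnalysisResult]:
    """Spearman correlation of gene degree with a diversity statistic per
    dataset, pooled across datasets by random-effects meta-analysis."""
    deg = gene_deg.as_series()
    per_dataset: list[tuple[float, int]] = []
    for div in diversity_tables:
        tab = div.table.set_index("gene_id")
        common = deg.index.intersection(tab.index)
        if len(common) < 3:
            raise ValueError("fewer than 3 shared genes with diversity data")
        rho = spearman(deg.loc[common].to_numpy(),
                       tab.loc[common, statistic].to_numpy())
        per_dataset.append((rho, int(len(common))))
    meta = random_effects_meta(per_dataset)
    return per_dataset, meta
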