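"""Bipartite adjacency construction, degree centrality, and annotations.

The SNP-gene association results define a bipartite network. Two adjacency
representations are supported:

* sparse — an edge is present iff its significance measure Y is strictly
  below a threshold tau in {0.05, 0.1, 0.15, 0.2}; the weight is |z| for the
  weighted variant or 1 for the unweighted one (a_ij = |z_ij| I{Y_ij < tau}).
* dense — every tested pair is present with its nominal p-value as weight
  (a_ij = p_ij), enabling the non-null-proportion (NP) degree.

Degrees: the sparse degree of a node is the sum of its incident edge
weights, decomposed into cis and trans parts under location-specific scope;
the NP degree of a node is 1 - pi0_hat of its full incident p-value vector.

Annotations derived from degree: a binary top-quartile SNP annotation and a
continuous gene-window annotation assigning each SNP inside a gene span
(+/- 50 kb flank) the gene's degree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .eqtl_mapping import EqtlResultSet
from .significance import SignificanceTable, nonnull_proportion
from .synthetic_data import GeneTable, GenotypeMatrix

__all__ = [
    "AdjacencyView",
    "DegreeVector",
    "AnnotationVector",
    "build_sparse_adjacency",
    "build_dense_adjacency",
    "degree_sparse",
    "degree_np",
    "top_quartile_annotation",
    "gene_window_annotation",
    "transform_regulatory_weights",
]

SPARSE_TAUS = (0.05, 0.1, 0.15, 0.2)


@dataclass
class AdjacencyView:
    """Bipartite edge store (snp_id, gene_id, weight, cis)."""

    edges: pd.DataFrame
    representation: str               # sparse-unweighted | sparse-weighted | dense-p
    scope: str                        # genome-wide | location-specific
    measure_kind: str | None = None
    tau: float | None = None
    snp_ids: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.edges.duplicated(["snp_id", "gene_id"]).any():
            raise ValueError("duplicate (snp, gene) pairs in adjacency")

    def to_tsv(self, path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)


@dataclass
class DegreeVector:
    """Per-node degree with optional cis/trans decomposition."""

    node_ids: list[str]
    total: np.ndarray
    axis: str                         # SNP | gene
    definition: str                   # QV | LFDR | BH | NP
    weighted: bool
    cis_part: np.ndarray | None = None
    trans_part: np.ndarray | None = None

    def as_series(self, component: str = "total") -> pd.Series:
        vec = {"total": self.total, "cis": self.cis_part,
               "trans": self.trans_part}[component]
        if vec is None:
            raise ValueError(f"no {component} component on this degree vector")
        return pd.Series(vec, index=self.node_ids)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame({"node_id": self.node_ids, "axis": self.axis,
                           "total": self.total})
        if self.cis_part is not None:
            df["cis_part"] = self.cis_part
            df["trans_part"] = self.trans_part
        df.to_csv(path, sep="\t", index=False)


@dataclass
class AnnotationVector:
    """Per-SNP annotation values (binary or continuous)."""

    snp_ids: list[str]
    values: np.ndarray
    kind: str                         # snp-top-quartile | gene-window

    def to_tsv(self, path) -> None:
        pd.DataFrame({"snp_id": self.snp_ids, "value": self.values}).to_csv(
            path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# adjacency construction
# ---------------------------------------------------------------------------

def build_sparse_adjacency(
    results: EqtlResultSet,
    measures: SignificanceTable,
    tau: float,
    weighted: bool = True,
    scope: str = "location-specific",
) -> AdjacencyView:
    """Edges where Y < tau (strict); weight |z| if weighted else 1."""
    if not (0 < tau < 1):
        raise ValueError("tau must lie in (0, 1)")
    entries = results.entries
    if len(measures.values) != len(entries):
        raise ValueError("measures not aligned to results")
    mask = (measures.values.to_numpy() < tau)
    sel = entries.loc[mask, ["snp_id", "gene_id", "z", "cis"]].copy()
    sel["weight"] = np.abs(sel.pop("z")) if weighted else 1.0
    rep = "sparse-weighted" if weighted else "sparse-unweighted"
    return AdjacencyView(
        sel[["snp_id", "gene_id", "weight", "cis"]].reset_index(drop=True),
        rep, scope, measures.measure_kind, tau,
        list(results.snp_ids), list(results.gene_ids),
    )


def build_dense_adjacency(results: EqtlResultSet) -> AdjacencyView:
    """All tested pairs with weight p (requires dense storage)."""
    if results.store != "dense":
        raise ValueError("dense adjacency requires dense-stored results")
    edges = results.entries[["snp_id", "gene_id", "p", "cis"]].rename(
        columns={"p": "weight"}).reset_index(drop=True)
    return AdjacencyView(edges, "dense-p", "genome-wide", None, None,
                         list(results.snp_ids), list(results.gene_ids))


# ---------------------------------------------------------------------------
# degrees
# ---------------------------------------------------------------------------

def _node_universe(adj: AdjacencyView, axis: str) -> list[str]:
    ids = adj.snp_ids if axis == "SNP" else adj.gene_ids
    if ids:
        return list(ids)
    col = "snp_id" if axis == "SNP" else "gene_id"
    return sorted(adj.edges[col].unique().tolist())


def degree_sparse(adj: AdjacencyView, axis: str = "SNP") -> DegreeVector:
    """Sum of incident edge weights per node; absent nodes get degree 0.

    Under location-specific scope the cis and trans sums are reported
    separately and add up to the total.
    """
    if adj.representation.startswith("dense"):
        raise ValueError("degree_sparse requires a sparse representation")
    if axis not in ("SNP", "gene"):
        raise ValueError("axis must be 'SNP' or 'gene'")
    col = "snp_id" if axis == "SNP" else "gene_id"
    nodes = _node_universe(adj, axis)
    idx = pd.Index(nodes)

    def _sum(df: pd.DataFrame) -> np.ndarray:
        return (df.groupby(col, sort=False)["weight"].sum()
                .reindex(idx, fill_value=0.0).to_numpy())

    total = _sum(adj.edges)
    cis_part = trans_part = None
    if adj.scope == "location-specific":
        cis_part = _sum(adj.edges[adj.edges["cis"]])
        trans_part = _sum(adj.edges[~adj.edges["cis"]])
    return DegreeVector(nodes, total, axis, adj.measure_kind or "NA",
                        adj.representation == "sparse-weighted",
                        cis_part, trans_part)


def degree_np(adj: AdjacencyView, axis: str = "SNP", min_tests: int = 10) -> DegreeVector:
    """Non-null-proportion degree: 1 - pi0_hat of each node's p-vector.

    Requires the dense representation (complete per-node p-values); the
    dense degree is genome-wide only, with no cis/trans split.
    """
    if adj.representation != "dense-p":
        raise ValueError("NP degree requires the dense representation")
    col = "snp_id" if axis == "SNP" else "gene_id"
    nodes = _node_universe(adj, axis)
    grouped = adj.edges.groupby(col, sort=False)["weight"]
    values = {}
    for node, pvec in grouped:
        if len(pvec) < min_tests:
            raise ValueError(
                f"node {node!r} has {len(pvec)} tests (< {min_tests}); "
                "NP degree needs a complete p-vector")
        values[node] = nonnull_proportion(pvec.to_numpy())
    missing = set(nodes) - values.keys()
    if missing:
        raise ValueError(f"nodes missing from dense adjacency: {sorted(missing)[:5]}")
    total = np.array([values[n] for n in nodes])
    return DegreeVector(nodes, total, axis, "NP", False)


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def top_quartile_annotation(deg: DegreeVector) -> AnnotationVector:
    """Binary annotation: 1 iff degree >= the 75th percentile (linear
    interpolation); degenerate all-equal degrees annotate every node 1."""
    if len(deg.node_ids) < 4:
        raise ValueError("need at least 4 nodes for a quartile annotation")
    if np.ptp(deg.total) == 0:
        warnings.warn("all degrees equal; top-quartile annotation is all ones")
        return AnnotationVector(list(deg.node_ids),
                                np.ones(len(deg.node_ids)), "snp-top-quartile")
    q75 = np.quantile(deg.total, 0.75)
    return AnnotationVector(list(deg.node_ids),
                            (deg.total >= q75).astype(float), "snp-top-quartile")


def gene_window_annotation(
    gene_deg: DegreeVector,
    genes: GeneTable,
    snps: GenotypeMatrix,
    flank: int = 50_000,
) -> AnnotationVector:
    """Assign each SNP the degree of any gene whose span (or TSS point when
    no span is recorded) +/- ``flank`` contains it; overlaps resolve to the
    maximum degree, SNPs in no window get 0."""
    deg = gene_deg.as_series()
    if genes.span_start is not None and genes.span_end is not None:
        g_start, g_end = genes.span_start, genes.span_end
    else:
        g_start, g_end = genes.tss, genes.tss
    lo = g_start.astype(np.int64) - flank
    hi = g_end.astype(np.int64) + flank

    values = np.zeros(snps.n_snps)
    for chrom in np.unique(snps.chrom):
        s_mask = snps.chrom == chrom
        g_mask = genes.chrom == chrom
        if not g_mask.any():
            continue
        gl, gh = lo[g_mask], hi[g_mask]
        gd = deg.reindex(np.asarray(genes.gene_ids)[g_mask]).to_numpy()
        pos = snps.pos[s_mask].astype(np.int64)
        inside = (pos[:, None] >= gl[None, :]) & (pos[:, None] <= gh[None, :])
        contrib = np.where(inside, gd[None, :], -np.inf).max(axis=1)
        values[s_mask] = np.where(np.isfinite(contrib), contrib, 0.0)
    return AnnotationVector(list(snps.snp_ids), values, "gene-window")


def transform_regulatory_weights(w):
    """Map a (possibly negative) regulatory edge weight to a positive one:
    W = ln(e^w + 1), computed in overflow-safe log-sum-exp form."""
    return np.logaddexp(np.asarray(w, dtype=float), 0.0)
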