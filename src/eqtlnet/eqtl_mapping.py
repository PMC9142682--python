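"""Exhaustive covariate-adjusted linear-regression eQTL mapping.

For every SNP-gene pair, expression is regressed on dosage plus an intercept
and covariates (G_j = X^T alpha + beta_ij S_i); a Wald statistic
z = beta_hat / SE(beta_hat) and a two-sided p-value are reported, and the
pair is classified cis (SNP within a window of the gene's TSS on the same
chromosome, boundary inclusive) or trans.

Implementation: covariates are projected out of both expression and dosages
once (Frisch-Waugh-Lovell), after which per-pair slopes reduce to a single
matrix product. The residual degrees of freedom account for the intercept,
the covariates, and the dosage term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import CovariateMatrix, ExpressionMatrix, GenotypeMatrix

__all__ = ["EqtlResultSet", "map_eqtls", "classify_cis_trans"]

_ZERO_VAR_TOL = 1e-12


@dataclass
class EqtlResultSet:
    """Per-pair eQTL statistics with exact test counts per stratum.

    ``entries`` has columns snp_id, gene_id, beta, z, p, cis. In ``dense``
    storage every testable pair is present; in ``streamed`` storage only
    entries passing the retention rule are kept, but ``n_tests_cis`` /
    ``n_tests_trans`` record how many tests were actually performed.
    """

    entries: pd.DataFrame
    n_tests_cis: int
    n_tests_trans: int
    store: str                        # "dense" | "streamed"
    snp_ids: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)
    untestable_snps: list[str] = field(default_factory=list)

    @property
    def n_tests(self) -> int:
        return self.n_tests_cis + self.n_tests_trans

    def to_tsv(self, path) -> None:
        df = self.entries.sort_values(["cis", "p"], ascending=[False, True])
        df.to_csv(path, sep="\t", index=False)


def classify_cis_trans(
    snp_chrom,
    snp_pos,
    gene_tss_chrom,
    gene_tss_pos,
    window: int = 1_000_000,
):
    """True where the SNP is cis to the gene: same chromosome and
    |snp_pos - tss_pos| <= window (inclusive boundary)."""
    same = np.asarray(snp_chrom) == np.asarray(gene_tss_chrom)
    dist = np.abs(np.asarray(snp_pos, dtype=np.int64)
                  - np.asarray(gene_tss_pos, dtype=np.int64))
    return same & (dist <= window)


def _residualize(M: np.ndarray, X: np.ndarray | None) -> np.ndarray:
    """Project out an intercept and covariate columns via QR."""
    r = M.shape[0]
    design = np.ones((r, 1)) if X is None else np.column_stack([np.ones(r), X])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient covariate design")
    Q, _ = np.linalg.qr(design)
    return M - Q @ (Q.T @ M)


def map_eqtls(
    G: GenotypeMatrix,
    E: ExpressionMatrix,
    X: CovariateMatrix | None = None,
    cis_window: int = 1_000_000,
    store: str = "dense",
    p_keep: float | None = None,
    trans_p_keep: float = 1e-3,
    wald: str = "normal",
    snp_block: int = 2000,
) -> EqtlResultSet:
    """Map eQTLs for every SNP-gene pair.

    Parameters
    ----------
    store
        ``"dense"`` keeps every testable pair. ``"streamed"`` keeps, per SNP,
        all cis pairs plus trans pairs with p <= ``trans_p_keep`` — unless
        ``p_keep`` is given, in which case a single ceiling applies to both
        strata.
    wald
        ``"normal"`` (default) computes two-sided p from the standard normal,
        matching the z-statistic edge weights; ``"t"`` uses the exact
        t-distribution with the residual degrees of freedom.

    SNPs whose dosage has zero variance after covariate projection are
    flagged untestable and excluded from the test counts.
    """
    if G.sample_ids != E.sample_ids:
        raise ValueError("genotype and expression sample orderings differ")
    r, n = G.dosages.shape
    m = E.values.shape[1]
    c = 0 if X is None else X.n_covariates
    if r < c + 3:
        raise ValueError("need at least (covariates + 3) samples")
    dof = r - c - 2
    if store not in ("dense", "streamed"):
        raise ValueError(f"unknown store mode {store!r}")

    Xv = None if X is None else X.values
    E_res = _residualize(E.values, Xv)
    gg = np.einsum("ij,ij->j", E_res, E_res)

    cis_all = classify_cis_trans(
        G.chrom[:, None], G.pos[:, None],
        E.genes.chrom[None, :], E.genes.tss[None, :], cis_window,
    )  # (n, m) boolean

    frames: list[pd.DataFrame] = []
    untestable: list[str] = []
    n_cis = 0
    n_trans = 0
    snp_ids = np.asarray(G.snp_ids)
    gene_ids = np.asarray(E.genes.gene_ids)

    for start in range(0, n, snp_block):
        sl = slice(start, min(start + snp_block, n))
        S_res = _residualize(G.dosages[:, sl], Xv)
        ss = np.einsum("ij,ij->j", S_res, S_res)
        ok = ss > _ZERO_VAR_TOL * r
        if not ok.all():
            untestable.extend(snp_ids[sl][~ok].tolist())
        if not ok.any():
            continue
        S_ok = S_res[:, ok]
        ss_ok = ss[ok]
        num = S_ok.T @ E_res                       # (n_ok, m)
        beta = num / ss_ok[:, None]
        rss = np.maximum(gg[None, :] - num ** 2 / ss_ok[:, None], 0.0)
        sigma2 = rss / dof
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(sigma2 / ss_ok[:, None])
            z = np.where(se > 0, beta / se, np.inf * np.sign(beta))
        if wald == "t":
            p = 2.0 * stats.t.sf(np.abs(z), dof)
        else:
            p = 2.0 * stats.norm.sf(np.abs(z))
        cis_blk = cis_all[sl][ok]

        n_cis += int(cis_blk.sum())
        n_trans += int((~cis_blk).sum())

        if store == "dense":
            keep = np.ones_like(cis_blk, dtype=bool)
        elif p_keep is not None:
            keep = p <= p_keep
        else:
            keep = cis_blk | (p <= trans_p_keep)

        si, gi = np.nonzero(keep)
        snp_idx_global = np.nonzero(ok)[0][si]
        frames.append(pd.DataFrame({
            "snp_id": snp_ids[sl][snp_idx_global],
            "gene_id": gene_ids[gi],
            "beta": beta[si, gi],
            "z": z[si, gi],
            "p": p[si, gi],
            "cis": cis_blk[si, gi],
        }))

    entries = (pd.concat(frames, ignore_index=True) if frames
               else pd.DataFrame(columns=["snp_id", "gene_id", "beta", "z", "p", "cis"]))
    return EqtlResultSet(
        entries=entries,
        n_tests_cis=n_cis,
        n_tests_trans=n_trans,
        store=store,
        snp_ids=[s for s in G.snp_ids if s not in set(untestable)],
        gene_ids=list(E.genes.gene_ids),
        untestable_snps=untestable,
    )
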