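"""Stratified LD-score regression: LD scores, the chi-square regression,
standardized effect sizes, and heritability enrichment with block-jackknife
standard errors.

Model: each SNP's effect variance is a linear additive contribution of its
annotations, Var(beta_j) = sum_c a_cj tau_c, which implies for GWAS
chi-square statistics

    E[chi2_j] = N * sum_c l(j,c) tau_c + 1,

where N is the GWAS sample size and l(j,c) = sum_k a_ck r2_jk is the LD
score of SNP j for annotation c. tau_c is estimated by least squares (the
intercept fixed at 1 by default), with standard errors and p-values from a
leave-one-block-out jackknife over contiguous SNP blocks.

Derived quantities per annotation c:

* standardized effect size tau*_c = tau_c sd(c) / (h2_g / M) — the
  proportionate change in per-SNP heritability per 1 SD of the annotation;
* enrichment = [h2(C) / h2_g] / [sum_j a_jc / M] — the proportion of
  heritability captured by the annotation over its proportion of SNPs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from scipy import stats

__all__ = [
    "LdScoreTable",
    "EnrichmentResult",
    "compute_ld_scores",
    "sldsc_regress",
    "tau_star",
    "enrichment",
    "sldsc",
]


@dataclass
class LdScoreTable:
    """Per-SNP, per-annotation LD scores l(j,c) >= 0."""

    snp_ids: list[str]
    scores: np.ndarray           # (M, C)
    names: list[str]

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.scores, columns=self.names)
        df.insert(0, "snp_id", self.snp_ids)
        df.to_csv(path, sep="\t", index=False)


@dataclass
class EnrichmentResult:
    """Per-annotation tau, tau*, and enrichment with jackknife SEs."""

    table: pd.DataFrame          # annotation, tau, tau_se, tau_p, tau_star,
                                 # enrichment, enr_se, enr_p, prop_snps, prop_h2
    h2_total: float
    M: int

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# LD scores
# ---------------------------------------------------------------------------

def compute_ld_scores(
    annotations: np.ndarray,
    dosages: np.ndarray | None = None,
    r2: np.ndarray | None = None,
    pos: np.ndarray | None = None,
    chrom: np.ndarray | None = None,
    window: int = 1_000_000,
    snp_ids: list[str] | None = None,
    names: list[str] | None = None,
) -> LdScoreTable:
    """l(j,c) = sum_k a_ck r2_jk with the self term included (r2_jj = 1).

    Either a precomputed squared-correlation matrix ``r2`` or sample
    ``dosages`` (samples x SNPs; unadjusted squared Pearson within
    ``window`` bp) must be supplied. Zero-variance SNPs are excluded from
    partner sums with a warning (their own score keeps the self term).
    """
    A = np.asarray(annotations, dtype=float)
    if A.ndim == 1:
        A = A[:, None]
    M, C = A.shape
    if r2 is None:
        if dosages is None:
            raise ValueError("supply either r2 or dosages")
        D = np.asarray(dosages, dtype=float)
        if D.shape[1] != M:
            raise ValueError("annotation rows must match SNP count")
        sd = D.std(axis=0)
        bad = sd <= 0
        if bad.any():
            warnings.warn(f"{int(bad.sum())} zero-variance SNPs excluded from LD")
        Dc = D - D.mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            Z = np.where(sd > 0, Dc / sd, 0.0)
        r2 = (Z.T @ Z / D.shape[0]) ** 2
        np.fill_diagonal(r2, 1.0)
        r2[bad, :] = 0.0
        r2[:, bad] = 0.0
        np.fill_diagonal(r2, 1.0)
    else:
        r2 = np.asarray(r2, dtype=float)
    if pos is not None:
        pos = np.asarray(pos, dtype=np.int64)
        in_window = np.abs(pos[:, None] - pos[None, :]) <= window
        if chrom is not None:
            in_window &= np.asarray(chrom)[:, None] == np.asarray(chrom)[None, :]
        r2 = np.where(in_window, r2, 0.0)
    L = r2 @ A
    return LdScoreTable(
        snp_ids or [f"snp{i}" for i in range(M)],
        L,
        names or [f"annot{c}" for c in range(C)],
    )


# ---------------------------------------------------------------------------
# regression and jackknife
# ---------------------------------------------------------------------------

def _check_collinear(X: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(X) == X.shape[1]:
        return
    # name the first column lying in the span of its predecessors
    for c in range(1, X.shape[1]):
        sub = X[:, :c]
        resid = X[:, c] - sub @ np.linalg.lstsq(sub, X[:, c], rcond=None)[0]
        if np.linalg.norm(resid) < 1e-10 * max(1.0, np.linalg.norm(X[:, c])):
            raise ValueError(f"collinear LD-score columns involving {names[c]!r}")
    raise ValueError("collinear LD-score columns")


def sldsc_regress(
    chisq: np.ndarray,
    n_gwas: float,
    ldscores: LdScoreTable,
    intercept: str = "fixed",
    n_blocks: int = 20,
) -> dict:
    """Estimate tau by least squares with block-jackknife SEs.

    ``intercept="fixed"`` regresses (chi2 - 1) on N*l as the model prints;
    ``"free"`` adds an intercept column for confounding scenarios. Returns a
    dict with ``tau``, ``tau_se``, ``tau_p``, ``intercept`` (estimated or
    1.0), and the per-block leave-out estimates ``tau_blocks`` used
    downstream for jackknifing derived quantities.
    """
    y_raw = np.asarray(chisq, dtype=float)
    M = y_raw.size
    if M < 2 * n_blocks:
        raise ValueError("need at least 2 SNPs per jackknife block")
    L = ldscores.scores
    names = list(ldscores.names)
    if intercept == "fixed":
        X = n_gwas * L
        y = y_raw - 1.0
    elif intercept == "free":
        X = np.column_stack([np.ones(M), n_gwas * L])
        y = y_raw
        names = ["intercept"] + names
    else:
        raise ValueError(f"unknown intercept mode {intercept!r}")
    _check_collinear(X, names)

    def _fit(mask: np.ndarray) -> np.ndarray:
        return np.linalg.lstsq(X[mask], y[mask], rcond=None)[0]

    full = _fit(np.ones(M, dtype=bool))
    bounds = np.linspace(0, M, n_blocks + 1).astype(int)
    tau_blocks = np.empty((n_blocks, X.shape[1]))
    for b in range(n_blocks):
        mask = np.ones(M, dtype=bool)
        mask[bounds[b]:bounds[b + 1]] = False
        tau_blocks[b] = _fit(mask)
    mean_b = tau_blocks.mean(axis=0)
    se = np.sqrt((n_blocks - 1) / n_blocks
                 * np.sum((tau_blocks - mean_b) ** 2, axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        zstat = np.where(se > 0, full / se, np.inf * np.sign(full))
    pvals = 2.0 * stats.norm.sf(np.abs(zstat))

    if intercept == "free":
        return {"tau": full[1:], "tau_se": se[1:], "tau_p": pvals[1:],
                "intercept": float(full[0]), "tau_blocks": tau_blocks[:, 1:]}
    return {"tau": full, "tau_se": se, "tau_p": pvals,
            "intercept": 1.0, "tau_blocks": tau_blocks}


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------

def tau_star(tau_c: float, annotation: np.ndarray, h2: float, M: int) -> float:
    """Standardized effect size tau* = tau_c * sd(c) / (h2 / M)."""
    if h2 <= 0 or M <= 0:
        raise ValueError("h2 and M must be positive")
    sd = float(np.std(np.asarray(annotation, dtype=float), ddof=1))
    if sd == 0:
        warnings.warn("constant annotation: tau* set to 0")
        return 0.0
    return float(tau_c * sd / (h2 / M))


def enrichment(annotation: np.ndarray, annotations_all: np.ndarray,
               tau: np.ndarray) -> float:
    """Enrichment = [h2(C)/h2_g] / [sum_j a_jc / M] under the linear
    decomposition Var(beta_j) = sum_c a_cj tau_c."""
    a = np.asarray(annotation, dtype=float)
    A = np.asarray(annotations_all, dtype=float)
    if A.ndim == 1:
        A = A[:, None]
    M = A.shape[0]
    if a.sum() <= 0:
        raise ValueError("annotation covers no SNPs")
    var_j = A @ np.asarray(tau, dtype=float)
    h2 = var_j.sum()
    if h2 <= 0:
        raise ValueError("non-positive total heritability")
    prop_h2 = float(a @ var_j / h2)
    prop_snp = float(a.sum() / M)
    return prop_h2 / prop_snp


def sldsc(
    chisq: np.ndarray,
    n_gwas: float,
    ldscores: LdScoreTable,
    annotations: np.ndarray,
    intercept: str = "fixed",
    n_blocks: int = 20,
) -> EnrichmentResult:
    """Full S-LDSC driver: regression, tau*, enrichment, jackknife SEs.

    ``annotations`` is the M x C annotation-value matrix used both for the
    heritability decomposition and the SNP-proportion denominators (its
    columns correspond to ``ldscores.names``).
    """
    A = np.asarray(annotations, dtype=float)
    if A.ndim == 1:
        A = A[:, None]
    M, C = A.shape
    reg = sldsc_regress(chisq, n_gwas, ldscores, intercept, n_blocks)
    tau = reg["tau"]
    var_j = A @ tau
    h2 = float(var_j.sum())

    rows = []
    for c in range(C):
        a = A[:, c]
        enr = enrichment(a, A, tau)

        # jackknife the enrichment through the leave-out tau estimates;
        # blocks whose estimated h2 is non-positive give no usable ratio
        def _enr_block(tb: np.ndarray) -> float:
            var_b = A @ tb
            h2_b = var_b.sum()
            if h2_b <= 0:
                return float("nan")
            return float((a @ var_b / h2_b) / (a.sum() / M))

        enr_blocks = np.array([_enr_block(tb) for tb in reg["tau_blocks"]])
        enr_blocks = enr_blocks[np.isfinite(enr_blocks)]
        nb = len(enr_blocks)
        if nb >= 2:
            enr_se = float(np.sqrt((nb - 1) / nb
                                   * np.sum((enr_blocks - enr_blocks.mean()) ** 2)))
        else:
            enr_se = float("nan")
        enr_p = (2.0 * stats.norm.sf(abs(enr - 1.0) / enr_se)
                 if np.isfinite(enr_se) and enr_se > 0 else float("nan"))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ts = tau_star(tau[c], a, h2, M) if h2 > 0 else float("nan")
        rows.append({
            "annotation": ldscores.names[c],
            "tau": tau[c], "tau_se": reg["tau_se"][c], "tau_p": reg["tau_p"][c],
            "tau_star": ts,
            "enrichment": enr, "enr_se": enr_se, "enr_p": enr_p,
            "prop_snps": float(a.sum() / M),
            "prop_h2": float(a @ var_j / h2) if h2 > 0 else float("nan"),
        })
    return EnrichmentResult(pd.DataFrame(rows), h2, M)
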