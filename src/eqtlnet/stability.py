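"""Degree reproducibility: split-sample stability, cross-network correlation,
and random-effects meta-analysis of correlations.

The split-sample protocol randomly divides the samples of one dataset into
two (near-)equal halves, runs the full pipeline (eQTL mapping, significance
measures, adjacency, degree) independently in each half, and reports the
Spearman correlation between the two halves' degree vectors. Five repeats by
default; correlations are reported per configuration (measure, tau,
weighting, stratum, axis) and summarized by the across-configuration median
and interquartile range.

Correlations across datasets or network types are pooled with a
DerSimonian-Laird random-effects model on Fisher-z transformed values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .eqtl_mapping import map_eqtls
from .network import DegreeVector, build_dense_adjacency, build_sparse_adjacency, \
    degree_np, degree_sparse
from .significance import compute_significance
from .synthetic_data import CovariateMatrix, ExpressionMatrix, GenotypeMatrix

__all__ = [
    "SplitStabilityReport",
    "MetaAnalysisResult",
    "spearman",
    "split_sample_stability",
    "cross_network_correlation",
    "random_effects_meta",
    "summarize_median_iqr",
]


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def spearman(x, y) -> float:
    """Spearman rank correlation (Pearson on average ranks, ties averaged).

    Returns NaN with a warning when either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need paired vectors of equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: Spearman correlation undefined")
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def summarize_median_iqr(values) -> tuple[float, float]:
    """Median and interquartile range (linear-interpolation quantiles)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no values to summarize")
    return float(np.median(v)), float(np.quantile(v, 0.75) - np.quantile(v, 0.25))


# ---------------------------------------------------------------------------
# random-effects meta-analysis
# ---------------------------------------------------------------------------

@dataclass
class MetaAnalysisResult:
    """DerSimonian-Laird pooled correlation on the Fisher-z scale."""

    pooled: float
    ci_low: float
    ci_high: float
    tau2: float                        # between-study variance (z-scale)
    studies: list[tuple[float, int]]   # (rho, n)


def random_effects_meta(correlations: Sequence[tuple[float, int]]) -> MetaAnalysisResult:
    """Pool correlations with Fisher-z + DerSimonian-Laird random effects.

    Each study contributes z = atanh(rho) with variance 1/(n-3); the
    between-study variance tau2 is the DL moment estimator, the pooled value
    and its 95% CI are back-transformed with tanh.
    """
    studies = [(float(r), int(n)) for r, n in correlations]
    if len(studies) < 2:
        raise ValueError("need at least two studies")
    if any(n <= 3 for _, n in studies):
        raise ValueError("every study needs n >= 4")
    # |rho| = 1 has infinite Fisher z; nudge inside the open interval
    z = np.array([np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
                  for r, _ in studies])
    v = np.array([1.0 / (n - 3) for _, n in studies])
    w = 1.0 / v
    z_fixed = np.sum(w * z) / np.sum(w)
    q = np.sum(w * (z - z_fixed) ** 2)
    k = len(studies)
    denom = np.sum(w) - np.sum(w ** 2) / np.sum(w)
    tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (v + tau2)
    z_pooled = np.sum(w_star * z) / np.sum(w_star)
    se = np.sqrt(1.0 / np.sum(w_star))
    crit = stats.norm.ppf(0.975)
    return MetaAnalysisResult(
        pooled=float(np.tanh(z_pooled)),
        ci_low=float(np.tanh(z_pooled - crit * se)),
        ci_high=float(np.tanh(z_pooled + crit * se)),
        tau2=float(tau2),
        studies=studies,
    )


# ---------------------------------------------------------------------------
# cross-network correlation
# ---------------------------------------------------------------------------

def cross_network_correlation(
    deg_a: DegreeVector,
    deg_b: DegreeVector,
    inclusion: str = "shared",
    component: str = "total",
) -> tuple[float, int]:
    """Spearman correlation of two degree vectors on their shared nodes.

    ``inclusion="shared"`` keeps every node present in both vectors
    (zero-degree nodes included); ``"nonzero-any"`` drops nodes with zero
    degree in both networks.
    """
    a = deg_a.as_series(component)
    b = deg_b.as_series(component)
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError("no shared nodes between networks")
    a, b = a.loc[common], b.loc[common]
    if inclusion == "nonzero-any":
        keep = (a != 0) | (b != 0)
        a, b = a[keep], b[keep]
    elif inclusion != "shared":
        raise ValueError(f"unknown inclusion rule {inclusion!r}")
    if len(a) < 3:
        raise ValueError("fewer than 3 shared nodes after inclusion rule")
    return spearman(a.to_numpy(), b.to_numpy()), int(len(a))


# ---------------------------------------------------------------------------
# split-sample stability protocol
# ---------------------------------------------------------------------------

@dataclass
class StabilityConfig:
    """Which network configurations the split protocol sweeps."""

    measures: tuple[str, ...] = ("BH",)
    taus: tuple[float, ...] = (0.05,)
    weighted: tuple[bool, ...] = (True, False)
    axes: tuple[str, ...] = ("SNP", "gene")
    strata: tuple[str, ...] = ("full", "cis", "trans")
    cis_window: int = 1_000_000
    include_np: bool = False
    np_min_tests: int = 10
    inclusion: str = "shared"
    lfdr_min_stats: int = 50


@dataclass
class SplitStabilityReport:
    """Per-repeat split correlations plus summaries."""

    records: pd.DataFrame   # repeat, definition, tau, weighted, stratum, axis, rho, n
    n_repeats: int
    summary: pd.DataFrame = field(init=False)
    median: float = field(init=False)
    iqr: float = field(init=False)

    def __post_init__(self) -> None:
        self.summary = (self.records
                        .groupby(["definition", "tau", "weighted", "stratum", "axis"],
                                 dropna=False)["rho"]
                        .mean().rename("mean_rho").reset_index())
        defined = self.summary["mean_rho"].dropna().to_numpy()
        if defined.size:
            self.median, self.iqr = summarize_median_iqr(defined)
        else:
            # a network with no edges in any repeat has no degree variation
            # to correlate; the summary is undefined rather than an error
            self.median, self.iqr = float("nan"), float("nan")


def _half_degrees(G, E, X, cfg: StabilityConfig):
    """Run mapping -> measures -> adjacency -> degree for one half-sample."""
    res = map_eqtls(G, E, X, cis_window=cfg.cis_window, store="dense")
    out = {}
    for kind in cfg.measures:
        meas = compute_significance(res, kind=kind, stratified=True,
                                    lfdr_min_stats=cfg.lfdr_min_stats)
        for tau in cfg.taus:
            for weighted in cfg.weighted:
                adj = build_sparse_adjacency(res, meas, tau, weighted,
                                             scope="location-specific")
                for axis in cfg.axes:
                    out[(kind, tau, weighted, axis)] = degree_sparse(adj, axis)
    if cfg.include_np:
        dense = build_dense_adjacency(res)
        for axis in cfg.axes:
            out[("NP", np.nan, False, axis)] = degree_np(dense, axis,
                                                         cfg.np_min_tests)
    return out


def split_sample_stability(
    G: GenotypeMatrix,
    E: ExpressionMatrix,
    X: CovariateMatrix | None = None,
    config: StabilityConfig | None = None,
    n_repeats: int = 5,
    seed: int = 0,
) -> SplitStabilityReport:
    """Split-half degree reproducibility.

    For each repeat the samples are randomly split into two disjoint,
    exhaustive halves (sizes differing by at most one for odd counts); the
    full pipeline runs independently per half and the Spearman correlation
    between the halves' degree vectors is recorded for every configuration,
    axis, and stratum. Covariates are subset per half, not re-estimated.
    """
    cfg = config or StabilityConfig()
    r = G.n_samples
    if r < 6:
        raise ValueError("need at least 6 samples to split")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_repeats):
        perm = rng.permutation(r)
        half_a, half_b = perm[: (r + 1) // 2], perm[(r + 1) // 2:]
        degs = []
        for idx in (half_a, half_b):
            idx = np.sort(idx)
            Xi = None if X is None else X.subset_samples(idx)
            try:
                degs.append(_half_degrees(G.subset_samples(idx),
                                          E.subset_samples(idx), Xi, cfg))
            except Exception as exc:
                raise RuntimeError(f"pipeline failed in repeat {rep}") from exc
        da, db = degs
        for key in da:
            kind, tau, weighted, axis = key
            strata = ("full",) if kind == "NP" else cfg.strata
            for stratum in strata:
                comp = {"full": "total", "cis": "cis", "trans": "trans"}[stratum]
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    try:
                        rho, n = cross_network_correlation(
                            da[key], db[key], cfg.inclusion, comp)
                    except ValueError:
                        rho, n = float("nan"), 0
                rows.append({"repeat": rep, "definition": kind, "tau": tau,
                             "weighted": weighted, "stratum": stratum,
                             "axis": axis, "rho": rho, "n": n})
    return SplitStabilityReport(pd.DataFrame(rows), n_repeats)
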