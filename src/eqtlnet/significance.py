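"""Edge-significance measures for bipartite eQTL networks.

Four measures Y of eQTL significance are supported, each in [0, 1]:

* ``QV`` — Storey q-value: q(p_i) = min_{t >= p_i} FDR_hat(t) with
  FDR_hat(t) = pi0_hat * m * t / #{p <= t}.
* ``LFDR`` — local false discovery rate: pi0 * f0(z) / f(z), the posterior
  probability that the null is true given z; f is estimated by Lindsey's
  method (histogram counts fit by a log-polynomial Poisson regression).
* ``BH`` — a streamed adaptation of Benjamini-Hochberg applied to the top-K
  ascending p-values out of N total tests:
  q_K = (N/K) p_K, q_i = min((N/i) p_i, q_{i+1}).
* ``NP`` — the non-null proportion 1 - pi0_hat of a p-value collection
  (used as a dense degree rather than a per-edge measure).

Measures can be scoped per SNP, per gene, or globally, and computed
separately for cis and trans test sets or pooled genome-wide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .eqtl_mapping import EqtlResultSet

__all__ = [
    "SignificanceTable",
    "estimate_pi0",
    "storey_qvalue",
    "local_fdr",
    "bh_adapted",
    "nonnull_proportion",
    "compute_significance",
]

DEFAULT_LAMBDA_GRID = np.round(np.arange(0.05, 0.951, 0.05), 2)


# ---------------------------------------------------------------------------
# pi0 estimation (shared by QV and NP)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _df3_penalty(grid_key: tuple[float, ...]) -> float:
    """Smoothing-spline penalty giving ~3 effective degrees of freedom.

    The smoother matrix of a natural cubic smoothing spline does not depend
    on the response, so the penalty achieving trace(S) = 3 is a property of
    the lambda grid alone and can be cached.
    """
    from scipy.interpolate import make_smoothing_spline
    grid = np.asarray(grid_key)
    n = grid.size

    def _df(pen: float) -> float:
        tr = 0.0
        for i in range(n):
            y = np.zeros(n)
            y[i] = 1.0
            tr += float(make_smoothing_spline(grid, y, lam=pen)(grid[i]))
        return tr

    lo, hi = 1e-10, 1e3
    for _ in range(80):
        mid = np.sqrt(lo * hi)
        if _df(mid) > 3.0:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def estimate_pi0(
    p: np.ndarray,
    lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
    method: str = "smoother",
    pi0_fixed: float | None = None,
) -> float:
    """Estimate the null proportion pi0 from p-values.

    ``smoother`` fits a natural cubic smoothing spline with ~3 effective
    degrees of freedom to pi0(lambda) = #{p > lambda} / (m (1 - lambda))
    over the lambda grid and evaluates it at the largest grid value; if the
    fit misbehaves it falls back to the raw estimate at the largest lambda.
    The result is clamped to (0, 1] with a floor of 1/m.
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    if m == 0:
        raise ValueError("empty p-value list")
    if method == "fixed":
        if pi0_fixed is None:
            raise ValueError("method='fixed' requires pi0_fixed")
        return float(np.clip(pi0_fixed, 1.0 / m, 1.0))

    lam = np.asarray(lambda_grid, dtype=float)
    if lam.size == 0 or (lam < 0).any() or (lam >= 1).any():
        raise ValueError("lambda grid must lie in [0, 1)")
    lam = np.sort(lam)
    pi0_lam = np.array([(p > l).sum() / (m * (1.0 - l)) for l in lam])

    if lam.size >= 4:
        from scipy.interpolate import make_smoothing_spline
        pen = _df3_penalty(tuple(lam.tolist()))
        pi0 = float(make_smoothing_spline(lam, pi0_lam, lam=pen)(lam[-1]))
    else:
        pi0 = float(pi0_lam[-1])
    if not np.isfinite(pi0) or pi0 <= 0:
        pi0 = float(pi0_lam[-1])
    return float(np.clip(pi0, 1.0 / m, 1.0))


# ---------------------------------------------------------------------------
# Storey q-values
# ---------------------------------------------------------------------------

def storey_qvalue(
    p: np.ndarray,
    lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
    pi0_method: str = "smoother",
    pi0_fixed: float | None = None,
) -> tuple[np.ndarray, float]:
    """q-values in input order plus the pi0 estimate used.

    With pi0 forced to 1 the q-values coincide with Benjamini-Hochberg
    step-up adjusted p-values.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    pi0 = estimate_pi0(p, lambda_grid, pi0_method, pi0_fixed)
    order = np.argsort(p, kind="mergesort")
    p_sorted = p[order]
    fdr = pi0 * m * p_sorted / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, pi0


# ---------------------------------------------------------------------------
# local FDR (Lindsey's method)
# ---------------------------------------------------------------------------

def local_fdr(
    z: np.ndarray,
    null: str = "theoretical",
    pi0: float | None = None,
    bins: int = 120,
    poly_degree: int = 7,
    min_stats: int = 200,
    monotone: bool = False,
) -> tuple[np.ndarray, float]:
    """Local FDR pi0 * f0(z) / f(z) for each statistic, clamped to [0, 1].

    The marginal density f is estimated by Lindsey's method: histogram the
    statistics and fit the bin counts with a Poisson GLM on a polynomial
    basis in the bin midpoints, giving a smooth log-density. The null f0 is
    standard normal by default; ``null="empirical"`` recentres/rescales f0
    using a normal fit to the central half of the statistics. When ``pi0``
    is not supplied it is estimated from the two-sided p-values via
    :func:`estimate_pi0`. ``monotone=True`` enforces lfdr nonincreasing in
    |z| by isotonic regression.
    """
    z = np.asarray(z, dtype=float)
    if z.size < min_stats:
        raise ValueError(f"need at least {min_stats} statistics for density estimation")
    if np.ptp(z) <= 0:
        raise ValueError("degenerate (constant) z statistics")

    if pi0 is None:
        p = 2.0 * stats.norm.sf(np.abs(z))
        pi0 = estimate_pi0(p)

    lo, hi = z.min(), z.max()
    pad = 0.01 * (hi - lo)
    edges = np.linspace(lo - pad, hi + pad, bins + 1)
    counts, _ = np.histogram(z, bins=edges)
    mids = 0.5 * (edges[:-1] + edges[1:])
    width = edges[1] - edges[0]

    # log-linear Poisson fit on a standardized polynomial basis
    x = (mids - mids.mean()) / mids.std()
    basis = np.column_stack([x ** k for k in range(poly_degree + 1)])
    import statsmodels.api as sm
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(counts, basis, family=sm.families.Poisson()).fit()
    f_hat = fit.mu / (z.size * width)           # density at bin midpoints
    f_z = np.interp(z, mids, f_hat)
    f_z = np.maximum(f_z, 1e-300)

    if null == "empirical":
        central = z[(z > np.quantile(z, 0.25)) & (z < np.quantile(z, 0.75))]
        mu0, sd0 = (np.median(z), central.std() if central.size > 2 else z.std())
        f0 = stats.norm.pdf(z, mu0, max(sd0, 1e-8))
    else:
        f0 = stats.norm.pdf(z)

    lfdr = np.clip(pi0 * f0 / f_z, 0.0, 1.0)
    if monotone:
        from scipy.optimize import isotonic_regression
        order = np.argsort(np.abs(z))
        iso = isotonic_regression(lfdr[order][::-1], increasing=True)
        out = np.empty_like(lfdr)
        out[order] = iso.x[::-1]
        lfdr = np.clip(out, 0.0, 1.0)
    return lfdr, float(pi0)


# ---------------------------------------------------------------------------
# adapted (streamed) Benjamini-Hochberg
# ---------------------------------------------------------------------------

def bh_adapted(p_sorted_topk: np.ndarray, n_total: int) -> np.ndarray:
    """FDR for the top-K ascending p-values out of ``n_total`` tests.

    Exact recursion q_K = (N/K) p_K, q_i = min((N/i) p_i, q_{i+1}), with the
    output clamped to 1 to preserve FDR semantics. With K = N this equals
    the textbook BH step-up adjustment of the full vector.
    """
    p = np.asarray(p_sorted_topk, dtype=float)
    if p.size == 0:
        return p.copy()
    if (np.diff(p) < 0).any():
        raise ValueError("p-values must be sorted ascending")
    k = p.size
    if k > n_total:
        raise ValueError("K exceeds the total number of tests N")
    ranks = np.arange(1, k + 1)
    q = np.minimum.accumulate((n_total / ranks * p)[::-1])[::-1]
    return np.clip(q, 0.0, 1.0)


# ---------------------------------------------------------------------------
# non-null proportion
# ---------------------------------------------------------------------------

def nonnull_proportion(
    p: np.ndarray,
    lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
) -> float:
    """1 - pi0_hat for a p-value collection, clamped to [0, 1]."""
    pi0 = estimate_pi0(np.asarray(p, dtype=float), lambda_grid)
    return float(np.clip(1.0 - pi0, 0.0, 1.0))


# ---------------------------------------------------------------------------
# orchestration over an EqtlResultSet
# ---------------------------------------------------------------------------

@dataclass
class SignificanceTable:
    """Per-entry measure values aligned to an EqtlResultSet's entries."""

    values: pd.Series                 # Y in [0,1], index-aligned to entries
    measure_kind: str                 # QV | LFDR | BH
    scope: str                        # per-snp | per-gene | global
    stratified: bool                  # cis/trans separated?
    pi0: dict = field(default_factory=dict)   # group key -> pi0 used


def _groups(entries: pd.DataFrame, scope: str, stratified: bool):
    keys = []
    if scope == "per-snp":
        keys.append("snp_id")
    elif scope == "per-gene":
        keys.append("gene_id")
    elif scope != "global":
        raise ValueError(f"unknown scope {scope!r}")
    if stratified:
        keys.append("cis")
    if keys:
        return entries.groupby(keys, sort=False, observed=True)
    return [((), entries)]


def compute_significance(
    results: EqtlResultSet,
    kind: str = "BH",
    scope: str | None = None,
    stratified: bool = True,
    lfdr_min_stats: int = 200,
    lfdr_kwargs: dict | None = None,
) -> SignificanceTable:
    """Attach a significance measure Y to every retained eQTL entry.

    Default scoping follows the measures' intended use: QV and LFDR per SNP
    (across that SNP's genes), BH globally per stratum using the exact test
    counts (which makes BH valid on threshold-streamed results). Strata are
    cis and trans test sets when ``stratified``; pooled otherwise.
    """
    if scope is None:
        scope = "global" if kind == "BH" else "per-snp"
    entries = results.entries
    Y = pd.Series(np.nan, index=entries.index, dtype=float)
    pi0s: dict = {}

    if kind == "BH":
        # N per group = exact number of tests performed in that stratum
        for key, grp in _groups(entries, scope, stratified):
            if stratified and scope == "global":
                is_cis = key if np.isscalar(key) else key[-1]
                n_total = results.n_tests_cis if is_cis else results.n_tests_trans
            elif not stratified and scope == "global":
                n_total = results.n_tests
            else:
                if results.store != "dense":
                    raise ValueError(
                        "per-node BH requires dense storage for exact counts")
                n_total = len(grp)
            order = np.argsort(grp["p"].to_numpy(), kind="mergesort")
            q = np.empty(len(grp))
            q[order] = bh_adapted(grp["p"].to_numpy()[order], n_total)
            Y.loc[grp.index] = q
    elif kind == "QV":
        if results.store != "dense":
            raise ValueError("q-values require dense storage (complete p-vectors)")
        for key, grp in _groups(entries, scope, stratified):
            q, pi0 = storey_qvalue(grp["p"].to_numpy())
            Y.loc[grp.index] = q
            pi0s[key] = pi0
    elif kind == "LFDR":
        if results.store != "dense":
            raise ValueError("local FDR requires dense storage (complete z-vectors)")
        for key, grp in _groups(entries, scope, stratified):
            lf, pi0 = local_fdr(grp["z"].to_numpy(), min_stats=lfdr_min_stats,
                                **(lfdr_kwargs or {}))
            Y.loc[grp.index] = lf
            pi0s[key] = pi0
    else:
        raise ValueError(f"unknown measure kind {kind!r}")

    return SignificanceTable(Y, kind, scope, stratified, pi0s)
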