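"""LD scores, the stratified chi-square regression, tau*, and enrichment."""

import numpy as np
import pytest

import eqtlnet as eq
from eqtlnet.heritability import LdScoreTable


def _identity_ld(annotations, names=None):
    A = np.asarray(annotations, dtype=float)
    if A.ndim == 1:
        A = A[:, None]
    return LdScoreTable([f"s{i}" for i in range(A.shape[0])], A.copy(),
                        names or [f"a{c}" for c in range(A.shape[1])])


class TestLdScores:
    def test_independent_snps_all_ones_annotation(self):
        ld = eq.compute_ld_scores(np.ones(30), r2=np.eye(30))
        np.testing.assert_allclose(ld.scores[:, 0], 1.0)

    def test_perfectly_correlated_pair(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(500)
        D = np.column_stack([x, 2 * x + 5])
        ld = eq.compute_ld_scores(np.ones(2), dosages=D)
        np.testing.assert_allclose(ld.scores[:, 0], 2.0, atol=1e-10)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(2)
        r = rng.uniform(-1, 1, size=(5, 5))
        r2 = (r + r.T) ** 2 / 4
        np.fill_diagonal(r2, 1.0)
        A = rng.uniform(size=(5, 2))
        ld = eq.compute_ld_scores(A, r2=r2)
        oracle = np.zeros((5, 2))
        for j in range(5):
            for c in range(2):
                for k in range(5):
                    oracle[j, c] += A[k, c] * r2[j, k]
        np.testing.assert_allclose(ld.scores, oracle, atol=1e-12)

    def test_all_ones_scores_at_least_one(self):
        rng = np.random.default_rng(3)
        D = rng.binomial(2, 0.3, size=(100, 40)).astype(float)
        ld = eq.compute_ld_scores(np.ones(40), dosages=D)
        assert (ld.scores[:, 0] >= 1.0 - 1e-12).all()

    def test_window_restricts_partners(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(200)
        D = np.column_stack([x, x])                    # perfect LD
        pos = np.array([0, 5_000_000])                 # but far apart
        ld = eq.compute_ld_scores(np.ones(2), dosages=D, pos=pos,
                                  window=1_000_000)
        np.testing.assert_allclose(ld.scores[:, 0], 1.0)


class TestSldscRegress:
    def test_exact_recovery_on_noiseless_input(self):
        tau = 5e-6
        N = 10_000
        ld = _identity_ld(np.ones(400))
        chisq = N * ld.scores[:, 0] * tau + 1.0
        reg = eq.sldsc_regress(chisq, N, ld, n_blocks=20)
        assert reg["tau"][0] == pytest.approx(tau, abs=1e-12)

    def test_low_bias_on_stochastic_simulation(self):
        M, N, tau = 10_000, 10_000, 1e-4
        A = np.ones((M, 1))
        ld = _identity_ld(A)
        taus = []
        for s in range(50):
            gw = eq.simulate_gwas_chisq(A, np.array([tau]), N, seed=s)
            reg = eq.sldsc_regress(gw["chisq"].to_numpy(), N, ld, n_blocks=20)
            taus.append(reg["tau"][0])
        assert abs(np.mean(taus) - tau) / tau < 0.10

    def test_null_jackknife_pvalues_calibrated(self):
        M, N = 2_000, 10_000
        A = np.ones((M, 1))
        ld = _identity_ld(A)
        rejections = 0
        runs = 200
        for s in range(runs):
            gw = eq.simulate_gwas_chisq(A, np.array([0.0]), N, seed=1000 + s)
            reg = eq.sldsc_regress(gw["chisq"].to_numpy(), N, ld, n_blocks=20)
            rejections += reg["tau_p"][0] < 0.05
        assert abs(rejections / runs - 0.05) <= 0.04

    def test_collinear_columns_named_in_error(self):
        A = np.column_stack([np.ones(100), np.ones(100)])
        ld = LdScoreTable([f"s{i}" for i in range(100)], A, ["base", "dup"])
        with pytest.raises(ValueError, match="dup"):
            eq.sldsc_regress(np.ones(100) * 1.5, 1000, ld)

    def test_free_intercept_recovers_confounding(self):
        tau = 2e-5
        N = 10_000
        rng = np.random.default_rng(7)
        ld = _identity_ld(1.0 + rng.uniform(size=500))   # varying LD scores
        chisq = N * ld.scores[:, 0] * tau + 1.3          # inflated intercept
        reg = eq.sldsc_regress(chisq, N, ld, intercept="free", n_blocks=20)
        assert reg["intercept"] == pytest.approx(1.3, abs=1e-8)
        assert reg["tau"][0] == pytest.approx(tau, abs=1e-10)

    def test_jackknife_se_shrinks_with_snp_count(self):
        """SE should scale roughly like 1/sqrt(M) on independent SNPs."""
        N, tau = 10_000, 1e-4
        ses = []
        sizes = (2_000, 8_000, 32_000)
        for M in sizes:
            A = np.ones((M, 1))
            ld = _identity_ld(A)
            se_runs = []
            for s in range(5):
                gw = eq.simulate_gwas_chisq(A, np.array([tau]), N, seed=50 + s)
                reg = eq.sldsc_regress(gw["chisq"].to_numpy(), N, ld,
                                       n_blocks=20)
                se_runs.append(reg["tau_se"][0])
            ses.append(np.mean(se_runs))
        slope = np.polyfit(np.log(sizes), np.log(ses), 1)[0]
        assert -0.7 < slope < -0.3


class TestTauStarAndEnrichment:
    def test_tau_star_direct_arithmetic(self):
        # annotation with sample sd ~0.5, h2/M = 5e-8
        annot = np.tile([0.0, 1.0], 5_000)
        ts = eq.tau_star(2e-8, annot, h2=0.5, M=10_000_000)
        sd = np.std(annot, ddof=1)
        assert ts == pytest.approx(2e-8 * sd / 5e-8, rel=1e-12)
        assert ts == pytest.approx(0.2, rel=1e-3)

    def test_tau_zero_gives_zero(self):
        assert eq.tau_star(0.0, np.arange(10.0), 0.5, 100) == 0.0

    def test_linear_in_annotation_sd(self):
        a = np.arange(100.0)
        assert eq.tau_star(1e-8, 2 * a, 0.5, 1000) == pytest.approx(
            2 * eq.tau_star(1e-8, a, 0.5, 1000))

    def test_constant_annotation_warns_zero(self):
        with pytest.warns(UserWarning):
            assert eq.tau_star(1e-8, np.ones(10), 0.5, 100) == 0.0

    def test_all_snps_annotation_enrichment_is_one(self):
        rng = np.random.default_rng(5)
        A = np.column_stack([np.ones(200), rng.integers(0, 2, 200)])
        tau = np.array([1e-5, 3e-5])
        assert eq.enrichment(A[:, 0], A, tau) == pytest.approx(1.0, abs=1e-12)

    def test_quarter_coverage_fully_causal_enrichment_is_four(self):
        M = 400
        annot = (np.arange(M) % 4 == 0).astype(float)
        A = np.column_stack([np.ones(M), annot])
        tau = np.array([0.0, 1e-5])   # all heritability inside the annotation
        assert eq.enrichment(annot, A, tau) == pytest.approx(4.0, abs=1e-12)


class TestSldscDriver:
    def test_enrichment_ci_covers_analytic_value(self):
        M, N = 10_000, 10_000
        annot = (np.arange(M) % 4 == 0).astype(float)
        A = np.column_stack([np.ones(M), annot])
        ld = _identity_ld(A, ["base", "annot"])
        covered = 0
        runs = 50
        for s in range(runs):
            gw = eq.simulate_gwas_chisq(A, np.array([0.0, 4e-4]), N, seed=s)
            res = eq.sldsc(gw["chisq"].to_numpy(), N, ld, A, n_blocks=20)
            row = res.table.iloc[1]
            covered += (row.enrichment - 1.96 * row.enr_se <= 4.0
                        <= row.enrichment + 1.96 * row.enr_se)
        assert covered / runs >= 0.9

    def test_base_annotation_enrichment_always_one(self):
        M, N = 2_000, 10_000
        rng = np.random.default_rng(9)
        annot = rng.integers(0, 2, M).astype(float)
        A = np.column_stack([np.ones(M), annot])
        ld = _identity_ld(A, ["base", "annot"])
        gw = eq.simulate_gwas_chisq(A, np.array([5e-5, 1e-4]), N, seed=11)
        res = eq.sldsc(gw["chisq"].to_numpy(), N, ld, A, n_blocks=20)
        assert res.table.iloc[0].enrichment == pytest.approx(1.0, abs=1e-10)

    def test_h2_decomposition_consistent(self):
        M, N = 2_000, 10_000
        annot = (np.arange(M) % 2 == 0).astype(float)
        A = np.column_stack([np.ones(M), annot])
        ld = _identity_ld(A, ["base", "annot"])
        gw = eq.simulate_gwas_chisq(A, np.array([5e-5, 1e-4]), N, seed=12)
        res = eq.sldsc(gw["chisq"].to_numpy(), N, ld, A, n_blocks=20)
        # h2_total equals the sum over SNPs of the linear decomposition
        tau = res.table["tau"].to_numpy()
        assert res.h2_total == pytest.approx(float((A @ tau).sum()), abs=1e-8)
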