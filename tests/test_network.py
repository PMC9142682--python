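"""Adjacency construction, degree variants, annotations, and the
regulatory-network edge transform."""

import numpy as np
import pandas as pd
import pytest

import eqtlnet as eq
from eqtlnet.eqtl_mapping import EqtlResultSet


def _toy_results(p_matrix, z_matrix=None, chrom_snp=None):
    """Dense EqtlResultSet from explicit p (and optional z) matrices."""
    p = np.asarray(p_matrix, dtype=float)
    n, m = p.shape
    z = (np.asarray(z_matrix, dtype=float) if z_matrix is not None
         else np.abs(np.random.default_rng(0).standard_normal((n, m))))
    snp_ids = [f"s{i}" for i in range(n)]
    gene_ids = [f"g{j}" for j in range(m)]
    si, gi = np.meshgrid(np.arange(n), np.arange(m), indexing="ij")
    cis = (si + gi) % 2 == 0
    entries = pd.DataFrame({
        "snp_id": np.array(snp_ids)[si.ravel()],
        "gene_id": np.array(gene_ids)[gi.ravel()],
        "beta": z.ravel(), "z": z.ravel(), "p": p.ravel(),
        "cis": cis.ravel(),
    })
    return EqtlResultSet(entries, int(cis.sum()), int((~cis).sum()), "dense",
                         snp_ids, gene_ids)


def _measures_from(results, values):
    from eqtlnet.significance import SignificanceTable
    return SignificanceTable(pd.Series(values, index=results.entries.index),
                             "BH", "global", True)


class TestSparseAdjacency:
    def test_weight_is_abs_z_below_threshold(self):
        res = _toy_results([[0.5]], [[-3.2]])
        meas = _measures_from(res, [0.049])
        adj = eq.build_sparse_adjacency(res, meas, 0.05, weighted=True)
        assert len(adj.edges) == 1
        assert adj.edges["weight"].iloc[0] == pytest.approx(3.2)

    def test_strict_inequality_at_boundary(self):
        res = _toy_results([[0.5]], [[2.0]])
        meas = _measures_from(res, [0.05])
        adj = eq.build_sparse_adjacency(res, meas, 0.05)
        assert len(adj.edges) == 0

    def test_edge_sets_nested_across_thresholds(self, mapped_400):
        meas = eq.compute_significance(mapped_400, kind="BH")
        prev = None
        for tau in (0.05, 0.1, 0.15, 0.2):
            adj = eq.build_sparse_adjacency(mapped_400, meas, tau)
            cur = set(map(tuple, adj.edges[["snp_id", "gene_id"]].to_numpy()))
            if prev is not None:
                assert prev <= cur
            prev = cur

    def test_bh_edges_subset_of_qv_edges(self, mapped_400):
        """q-values are bounded by the BH adjustment (q_QV = pi0 * q_BH with
        pi0 <= 1), so the BH edge set nests inside the QV edge set."""
        bh = eq.compute_significance(mapped_400, kind="BH", scope="global",
                                     stratified=False)
        qv = eq.compute_significance(mapped_400, kind="QV", scope="global",
                                     stratified=False)
        assert (qv.values <= bh.values + 1e-12).all()
        adj_bh = eq.build_sparse_adjacency(mapped_400, bh, 0.05)
        adj_qv = eq.build_sparse_adjacency(mapped_400, qv, 0.05)
        e_bh = set(map(tuple, adj_bh.edges[["snp_id", "gene_id"]].to_numpy()))
        e_qv = set(map(tuple, adj_qv.edges[["snp_id", "gene_id"]].to_numpy()))
        assert e_bh <= e_qv

    def test_invalid_tau_rejected(self, mapped_400):
        meas = eq.compute_significance(mapped_400, kind="BH")
        with pytest.raises(ValueError):
            eq.build_sparse_adjacency(mapped_400, meas, 1.5)


class TestDenseAdjacency:
    def test_all_pairs_present_bit_exact(self):
        p = np.random.default_rng(1).uniform(size=(3, 2))
        res = _toy_results(p)
        adj = eq.build_dense_adjacency(res)
        assert len(adj.edges) == 6
        np.testing.assert_array_equal(
            adj.edges["weight"].to_numpy(), res.entries["p"].to_numpy())

    def test_streamed_input_rejected(self):
        res = _toy_results(np.random.default_rng(2).uniform(size=(2, 2)))
        res.store = "streamed"
        with pytest.raises(ValueError):
            eq.build_dense_adjacency(res)


class TestDegreeSparse:
    def test_weighted_and_unweighted_sums(self):
        res = _toy_results([[0.01, 0.01]], [[2.5, 3.5]])
        meas = _measures_from(res, [0.01, 0.01])
        for weighted, expected in ((True, 6.0), (False, 2.0)):
            adj = eq.build_sparse_adjacency(res, meas, 0.05, weighted=weighted)
            deg = eq.degree_sparse(adj, "SNP")
            assert deg.total[0] == pytest.approx(expected)

    def test_zero_degree_for_absent_nodes(self, mapped_400):
        meas = eq.compute_significance(mapped_400, kind="BH")
        adj = eq.build_sparse_adjacency(mapped_400, meas, 0.05)
        deg = eq.degree_sparse(adj, "SNP")
        connected = set(adj.edges["snp_id"])
        for node, d in zip(deg.node_ids, deg.total):
            if node not in connected:
                assert d == 0.0

    def test_equals_dense_matrix_oracle(self):
        """Row/column sums of the materialized adjacency matrix."""
        rng = np.random.default_rng(3)
        n, m = 150, 120
        p = rng.uniform(size=(n, m))
        z = rng.standard_normal((n, m))
        res = _toy_results(p, z)
        meas = _measures_from(res, p.ravel())   # use p itself as the measure
        tau = 0.2
        adj = eq.build_sparse_adjacency(res, meas, tau, weighted=True)
        dense = np.abs(z) * (p < tau)
        deg_snp = eq.degree_sparse(adj, "SNP")
        deg_gene = eq.degree_sparse(adj, "gene")
        np.testing.assert_allclose(deg_snp.total, dense.sum(axis=1), atol=1e-10)
        np.testing.assert_allclose(deg_gene.total, dense.sum(axis=0), atol=1e-10)

    def test_cis_trans_parts_sum_to_total(self, mapped_400):
        meas = eq.compute_significance(mapped_400, kind="BH")
        adj = eq.build_sparse_adjacency(mapped_400, meas, 0.2,
                                        scope="location-specific")
        for axis in ("SNP", "gene"):
            deg = eq.degree_sparse(adj, axis)
            np.testing.assert_allclose(deg.total, deg.cis_part + deg.trans_part)

    def test_weighted_unweighted_rank_agreement(self, mapped_400):
        """On simulated data the binary and |z|-weighted degrees rank nodes
        nearly identically."""
        meas = eq.compute_significance(mapped_400, kind="BH")
        adj_w = eq.build_sparse_adjacency(mapped_400, meas, 0.2, weighted=True)
        adj_u = eq.build_sparse_adjacency(mapped_400, meas, 0.2, weighted=False)
        dw = eq.degree_sparse(adj_w, "SNP").total
        du = eq.degree_sparse(adj_u, "SNP").total
        assert eq.spearman(dw, du) > 0.8

    def test_degree_distribution_right_skewed(self, mapped_400):
        from scipy.stats import skew
        meas = eq.compute_significance(mapped_400, kind="BH")
        adj = eq.build_sparse_adjacency(mapped_400, meas, 0.05)
        deg = eq.degree_sparse(adj, "SNP")
        assert skew(deg.total) > 0


class TestDegreeNp:
    def test_null_node_near_zero(self):
        rng = np.random.default_rng(4)
        res = _toy_results(rng.uniform(size=(1, 24_000)))
        deg = eq.degree_np(eq.build_dense_adjacency(res), "SNP")
        assert deg.total[0] <= 0.05

    def test_saturated_node_near_one(self):
        res = _toy_results(np.full((1, 100), 1e-9))
        deg = eq.degree_np(eq.build_dense_adjacency(res), "SNP")
        assert deg.total[0] >= 0.95

    def test_bounded_in_unit_interval(self, mapped_400):
        deg = eq.degree_np(eq.build_dense_adjacency(mapped_400), "SNP")
        assert ((deg.total >= 0) & (deg.total <= 1)).all()

    def test_insufficient_tests_rejected(self):
        res = _toy_results(np.random.default_rng(5).uniform(size=(2, 4)))
        with pytest.raises(ValueError, match="tests"):
            eq.degree_np(eq.build_dense_adjacency(res), "SNP", min_tests=10)


class TestAnnotations:
    def test_top_quartile_on_integer_degrees(self):
        deg = eq.DegreeVector([f"s{i}" for i in range(8)],
                              np.arange(1.0, 9.0), "SNP", "BH", True)
        annot = eq.top_quartile_annotation(deg)
        np.testing.assert_array_equal(annot.values,
                                      [0, 0, 0, 0, 0, 0, 1, 1])

    def test_all_equal_degrees_degenerate(self):
        deg = eq.DegreeVector(["a", "b", "c", "d"], np.ones(4), "SNP", "BH", True)
        with pytest.warns(UserWarning):
            annot = eq.top_quartile_annotation(deg)
        assert annot.values.sum() == 4

    def test_annotation_mean_near_quarter(self):
        rng = np.random.default_rng(6)
        n = 200
        deg = eq.DegreeVector([f"s{i}" for i in range(n)],
                              rng.uniform(size=n), "SNP", "BH", True)
        mean = eq.top_quartile_annotation(deg).values.mean()
        assert 0.25 - 2 / n <= mean <= 0.25 + 2 / n

    def test_gene_window_assignment(self):
        genes = eq.GeneTable(["gA", "gB"], np.array(["chr1", "chr1"]),
                             np.array([100_000, 130_000]),
                             np.array([100_000, 130_000]),
                             np.array([120_000, 150_000]))
        G = eq.GenotypeMatrix(
            np.zeros((2, 3)) + 1.0, ["up10kb", "overlap", "far"],
            np.array(["chr1"] * 3),
            np.array([90_000, 135_000, 300_000]), np.array([0.2] * 3))
        deg = eq.DegreeVector(["gA", "gB"], np.array([3.0, 5.0]), "gene", "BH", True)
        annot = eq.gene_window_annotation(deg, genes, G, flank=50_000)
        assert annot.values[0] == 3.0 or annot.values[0] == 5.0  # in gA window
        assert annot.values[1] == 5.0    # overlapping windows -> max rule
        assert annot.values[2] == 0.0    # outside all windows

    def test_snp_just_outside_flank_gets_zero(self):
        genes = eq.GeneTable(["gA"], np.array(["chr1"]), np.array([100_000]),
                             np.array([100_000]), np.array([100_000]))
        G = eq.GenotypeMatrix(np.ones((2, 1)), ["s"], np.array(["chr1"]),
                              np.array([160_001]), np.array([0.2]))
        deg = eq.DegreeVector(["gA"], np.array([2.0]), "gene", "BH", True)
        annot = eq.gene_window_annotation(deg, genes, G, flank=50_000)
        assert annot.values[0] == 0.0


class TestRegulatoryTransform:
    @pytest.mark.parametrize("w,expected", [
        (0.0, np.log(2)),
        (10.0, 10.0000454),
        (-10.0, 4.5399e-5),
    ])
    def test_closed_form_values(self, w, expected):
        assert eq.transform_regulatory_weights(w) == pytest.approx(expected,
                                                                   rel=1e-4)

    def test_positive_increasing_no_overflow(self):
        w = np.array([-700.0, -1.0, 0.0, 1.0, 800.0])
        out = eq.transform_regulatory_weights(w)
        assert (out > 0).all()
        assert (np.diff(out) > 0).all()
        assert np.isfinite(out).all()
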