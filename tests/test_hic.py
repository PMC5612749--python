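import numpy as np
import pytest

from codomains.coexpression import build_coexpression_matrix
from codomains.hic import (
    HiCMatrix,
    binned_connectivity_vs_coexpression,
    cod_connectivity_comparison,
    gene_pair_connectivity,
    kr_balance,
    observed_over_expected,
    profile_correlation,
)
from codomains.cod_caller import call_cods
from codomains.cod_stats import cod_coexpression_summary
from codomains.io import make_annotation, order_genes
from codomains.synthetic import HiCSpec, SyntheticSpec, generate_expression, generate_hic


def sinkhorn_oracle(A, iters=200_000, tol=1e-13):
    """Plain alternating scaling run to convergence (the independent oracle)."""
    x = np.ones(A.shape[0])
    for _ in range(iters):
        s = x * (A @ x)
        if np.ptp(s) < tol:
            break
        x = x / np.sqrt(s)
    return x


class TestKRBalance:
    def test_uniform_matrix_constant_vector(self):
        A = np.ones((6, 6)) - np.eye(6)
        v, B, inc = kr_balance(A)
        assert inc.all()
        assert np.allclose(v, v[0])
        assert np.allclose(B[inc].sum(axis=1), 1.0, atol=1e-8)

    def test_3x3_agrees_with_sinkhorn_oracle(self):
        A = np.array([[0.0, 2, 1], [2, 0, 4], [1, 4, 0]])
        v, B, inc = kr_balance(A, tol=1e-10)
        x = sinkhorn_oracle(A)
        assert np.ptp(B.sum(axis=1)) < 1e-8
        assert np.allclose(v / v[0], x / x[0], atol=1e-6)

    def test_zero_row_excluded_remainder_balanced(self):
        A = np.array([[0.0, 2, 1, 0], [2, 0, 4, 0], [1, 4, 0, 0], [0, 0, 0, 0]])
        v, B, inc = kr_balance(A)
        assert list(inc) == [True, True, True, False]
        assert np.isnan(v[3])
        assert np.ptp(B[np.ix_(inc, inc)].sum(axis=1)) < 1e-6

    def test_row_sums_equal_on_random_matrices(self, rng):
        for _ in range(5):
            A = rng.random((50, 50))
            A = A + A.T
            v, B, inc = kr_balance(A)
            assert np.ptp(B[np.ix_(inc, inc)].sum(axis=1)) < 1e-6

    def test_doubling_counts_leaves_balanced_matrix(self, rng):
        A = rng.random((20, 20))
        A = A + A.T
        _, B1, _ = kr_balance(A, tol=1e-10)
        _, B2, _ = kr_balance(2 * A, tol=1e-10)
        assert np.allclose(B1, B2, atol=1e-6)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            kr_balance(np.array([[0.0, -1], [-1, 0]]))

    def test_vector_positive_on_included_bins(self, rng):
        A = rng.random((30, 30))
        A = A + A.T
        v, _, inc = kr_balance(A)
        assert (v[inc] > 0).all()


class TestObservedOverExpected:
    def test_constant_diagonals_give_unit_oe(self):
        n = 6
        M = np.fromfunction(lambda i, j: 10.0 / (1 + abs(i - j)), (n, n))
        oe = observed_over_expected(M)
        assert np.allclose(oe, 1.0)

    def test_hand_computed_toy(self):
        M = np.zeros((5, 5))
        vals = [2.0, 4.0, 2.0, 4.0]
        for k, v in enumerate(vals):
            M[k, k + 1] = M[k + 1, k] = v
        np.fill_diagonal(M, 1.0)
        oe = observed_over_expected(M)
        got = [oe[k, k + 1] for k in range(4)]
        assert got == pytest.approx([2 / 3, 4 / 3, 2 / 3, 4 / 3])

    def test_per_diagonal_mean_is_one(self, rng):
        M = rng.random((40, 40))
        M = M + M.T
        oe = observed_over_expected(M)
        for d in range(1, 40):
            diag = np.diagonal(oe, d)
            diag = diag[~np.isnan(diag)]
            if diag.size:
                assert abs(diag.mean() - 1.0) < 1e-9


class TestProfileCorrelation:
    def test_duplicate_and_negated_rows(self, rng):
        base = rng.random(8)
        oe = np.outer(np.ones(8), base)  # every row a copy of base
        oe[3] = -base + 2 * base.mean()  # row 3: negation about the mean
        pc = profile_correlation(oe)
        assert pc[0, 1] == pytest.approx(1.0, abs=1e-9)
        assert pc[0, 3] == pytest.approx(-1.0, abs=1e-9)

    def test_matches_bruteforce_pairwise_pearson(self, rng):
        oe = rng.random((6, 6))
        oe = (oe + oe.T) / 2
        pc = profile_correlation(oe)
        for i in range(6):
            for j in range(i + 1, 6):
                mask = np.ones(6, bool)
                mask[[i, j]] = False
                a, b = oe[i, mask], oe[j, mask]
                r = np.corrcoef(a, b)[0, 1]
                assert pc[i, j] == pytest.approx(r, abs=1e-12)
        assert np.allclose(pc, pc.T, equal_nan=True)
        assert np.allclose(np.diag(pc), 1.0)

    def test_constant_row_flagged_nan(self):
        oe = np.ones((5, 5))
        pc = profile_correlation(oe)
        assert np.isnan(pc[0, 1])


class TestGenePairConnectivity:
    def annot(self):
        return order_genes(
            make_annotation(
                [("a", "1", 140_000, 160_000), ("b", "1", 410_000, 430_000), ("c", "1", 150_000, 170_000)]
            )
        )

    def test_bins_by_midpoint_division(self):
        pc = np.arange(36, dtype=float).reshape(6, 6)
        conn = gene_pair_connectivity(self.annot(), pc, 100_000, "1")
        # ranks: a=0 (bin 1), c=1 (bin 1), b=2 (bin 4)
        assert conn[0, 2] == pc[1, 4]

    def test_same_bin_pair_is_unity(self):
        pc = np.zeros((6, 6))
        conn = gene_pair_connectivity(self.annot(), pc, 100_000, "1")
        assert conn[0, 1] == 1.0  # a and c share bin 1

    def test_gene_beyond_matrix_skipped(self, caplog):
        annot = order_genes(
            make_annotation([("a", "1", 0, 100_000), ("b", "1", 10_000_000, 10_100_000)])
        )
        with caplog.at_level("WARNING", logger="codomains"):
            conn = gene_pair_connectivity(annot, np.zeros((3, 3)), 100_000, "1")
        assert np.isnan(conn[0, 1])
        assert "beyond" in caplog.text


@pytest.fixture(scope="module")
def compartment_cohort():
    spec = SyntheticSpec(
        seed=1,
        coupled_groups=[((0, 1, 2, 3, 4), 0.3)],
        hic=HiCSpec(compartment_boost=2.0, depth=200.0),
    )
    expr, annot, truth = generate_expression(spec)
    counts, labels = generate_hic(spec, "cod_coupled")
    hm = HiCMatrix("1", spec.hic.resolution, counts).process()
    cm = build_coexpression_matrix(expr, annot, "1")
    return spec, annot, truth, cm, hm, labels


class TestEndToEnd:
    def test_checkerboard_sign_recovery(self, compartment_cohort):
        *_, hm, labels = compartment_cohort
        iu, ju = np.triu_indices(len(labels), k=1)
        vals = hm.profile_corr[iu, ju]
        ok = ~np.isnan(vals)
        same = labels[iu] == labels[ju]
        assert (vals[ok & same] > 0).mean() > 0.9
        assert (vals[ok & ~same] < 0).mean() > 0.9

    def test_unstructured_map_has_no_compartments(self):
        spec = SyntheticSpec(seed=2, hic=HiCSpec(compartment_boost=1.0, depth=200.0))
        counts, _ = generate_hic(spec, "none")
        hm = HiCMatrix("1", spec.hic.resolution, counts).process()
        iu, ju = np.triu_indices(hm.n_bins, k=1)
        vals = hm.profile_corr[iu, ju]
        assert abs(np.nanmean(vals)) < 0.2

    def test_connectivity_curve_tracks_coexpression(self, compartment_cohort):
        spec, annot, truth, cm, hm, labels = compartment_cohort
        conn = gene_pair_connectivity(annot, hm.profile_corr, spec.hic.resolution, "1")
        binned = binned_connectivity_vs_coexpression(conn, cm, 20)
        assert binned.n_bins == 20
        assert binned.pair_count.max() - binned.pair_count.min() <= 1
        # top-connectivity bins are the coupled-compartment pairs
        assert binned.mean_coexpression[-1] > binned.mean_coexpression[0] + 0.1
        assert np.all(np.diff(binned.mean_connectivity) >= 0)

    def test_identity_coupling_bins_agree(self):
        expr, annot, _ = generate_expression(SyntheticSpec(n_genes=10, blocks=[], seed=0))
        cm = build_coexpression_matrix(expr, annot, "1")
        conn = cm.C.copy()  # connectivity == coexpression exactly
        binned = binned_connectivity_vs_coexpression(conn, cm, 5)
        assert np.allclose(binned.mean_connectivity, binned.mean_coexpression)

    def test_cod_connectivity_comparison(self, compartment_cohort):
        spec, annot, truth, cm, hm, labels = compartment_cohort
        cods, _ = call_cods(cm, annot)
        _, pair_stats, _ = cod_coexpression_summary(cods, cm)
        conn = gene_pair_connectivity(annot, hm.profile_corr, spec.hic.resolution, "1")
        groups, table = cod_connectivity_comparison(cods, pair_stats, conn, annot)
        assert np.median(groups["intra"]) > np.median(groups["rest"])
        row = table.set_index(["group_a", "group_b"]).loc[("intra", "rest")]
        assert row["p_bonferroni"] < 0.01

    def test_empty_cod_set_yields_empty_tables(self, compartment_cohort):
        spec, annot, *_ = compartment_cohort
        from codomains.io import DomainSet

        groups, table = cod_connectivity_comparison(
            DomainSet("1", [], kind="COD"), [], np.zeros((2, 2)), annot
        )
        assert groups == {} and table.empty


class TestTripletIO:
    def test_round_trip(self, tmp_path, rng):
        from codomains.synthetic import write_hic_triplets

        A = rng.integers(0, 20, (8, 8)).astype(float)
        A = np.triu(A) + np.triu(A, 1).T
        p = tmp_path / "m.txt"
        write_hic_triplets(A, p)
        hm = HiCMatrix.from_triplets(p, 100_000, "1", n_bins=8)
        assert np.allclose(hm.counts, A)

    def test_bp_coordinates_detected(self, tmp_path):
        p = tmp_path / "m.txt"
        p.write_text("0\t100000\t5\n100000\t200000\t7\n")
        hm = HiCMatrix.from_triplets(p, 100_000, "1")
        assert hm.counts[0, 1] == 5 and hm.counts[1, 2] == 7 and hm.n_bins == 3
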