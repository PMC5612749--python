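import numpy as np
import pytest

from codomains.coexpression import CoexpressionMatrix, build_coexpression_matrix
from codomains.cod_caller import (
    BinSignalTrack,
    CODCallConfig,
    boundary_test,
    call_cods,
    compute_binsignal,
    window_sweep,
)
from codomains.io import ExpressionMatrix
from codomains.synthetic import SyntheticSpec, generate_expression, evaluate_recovery


def matrix_from(C, chrom="1"):
    C = np.asarray(C, dtype=float)
    n = C.shape[0]
    return CoexpressionMatrix(chrom, [f"g{i}" for i in range(n)], C, np.ones(n, bool))


def constant_matrix(n, c):
    C = np.full((n, n), c)
    np.fill_diagonal(C, 1.0)
    return matrix_from(C)


def binsignal_brute(C, w):
    """Direct double-sum evaluation of the windowed average (the oracle)."""
    n = C.shape[0]
    out = np.full(n, np.nan)
    for i in range(n):
        block = [
            C[l, m]
            for l in range(max(0, i - w + 1), i + 1)
            for m in range(i + 1, min(n, i + w + 1))
            if not np.isnan(C[l, m])
        ]
        if block:
            out[i] = np.mean(block)
    return out


class TestBinsignal:
    def test_constant_matrix_gives_constant_signal(self):
        cm = constant_matrix(12, 0.3)
        track = compute_binsignal(cm, 4)
        # the U x D block never touches the diagonal, so every defined value is c
        assert np.allclose(track.values[:-1], 0.3)
        assert np.isnan(track.values[-1])

    def test_w1_degenerates_to_adjacent_entry(self, rng):
        C = rng.uniform(-1, 1, (8, 8))
        C = (C + C.T) / 2
        np.fill_diagonal(C, 1.0)
        cm = matrix_from(C)
        track = compute_binsignal(cm, 1)
        for i in range(7):
            assert track.values[i] == pytest.approx(C[i, i + 1])

    def test_planted_block_peaks_at_center(self):
        C = np.zeros((12, 12))
        C[3:9, 3:9] = 0.8
        np.fill_diagonal(C, 1.0)
        cm = matrix_from(C)
        track = compute_binsignal(cm, 4)
        expect = binsignal_brute(C, 4)
        assert np.allclose(track.values, expect, equal_nan=True)
        center = track.values[5]
        assert center >= track.values[3] and center >= track.values[8]

    def test_matches_bruteforce_on_random_matrices(self, rng):
        for _ in range(50):
            C = rng.uniform(-1, 1, (30, 30))
            C = (C + C.T) / 2
            np.fill_diagonal(C, 1.0)
            track = compute_binsignal(matrix_from(C), 4)
            assert np.allclose(track.values, binsignal_brute(C, 4), atol=1e-12, equal_nan=True)

    def test_invalid_genes_shrink_the_window(self):
        C = np.full((10, 10), 0.4)
        np.fill_diagonal(C, 1.0)
        C[5, :] = C[:, 5] = np.nan  # zero-variance gene keeps its rank
        valid = np.ones(10, bool)
        valid[5] = False
        cm = CoexpressionMatrix("1", [f"g{i}" for i in range(10)], C, valid)
        track = compute_binsignal(cm, 4)
        assert np.allclose(track.values[:-1], 0.4)


class TestBoundaryTest:
    def test_identical_windows_give_p_one(self):
        track = BinSignalTrack("1", 4, np.array([0.3] * 8))
        assert boundary_test(track, 3) == 1.0

    def test_matches_pooled_variance_formula(self):
        up = np.array([0.50, 0.60, 0.55, 0.50])
        down = np.array([0.05, 0.00, 0.02, 0.03])
        track = BinSignalTrack("1", 4, np.concatenate([up, down]))
        p = boundary_test(track, 3)
        # textbook pooled t with 6 degrees of freedom as the oracle
        sp2 = (up.var(ddof=1) * 3 + down.var(ddof=1) * 3) / 6
        t = (up.mean() - down.mean()) / np.sqrt(sp2 * (1 / 4 + 1 / 4))
        from scipy.stats import t as tdist

        p_oracle = 2 * tdist.sf(abs(t), 6)
        assert p < 0.05
        assert p == pytest.approx(p_oracle, rel=1e-12)

    def test_two_sided_symmetry_under_window_swap(self):
        up = np.array([0.50, 0.60, 0.55, 0.50])
        down = np.array([0.05, 0.00, 0.02, 0.03])
        t1 = BinSignalTrack("1", 4, np.concatenate([up, down]))
        t2 = BinSignalTrack("1", 4, np.concatenate([down, up]))
        assert boundary_test(t1, 3) == pytest.approx(boundary_test(t2, 3))

    def test_short_window_undefined(self):
        track = BinSignalTrack("1", 4, np.array([0.1, 0.2, 0.3]))
        assert np.isnan(boundary_test(track, 0))


class TestCallCods:
    def test_no_signal_no_cods(self):
        cods, bounds = call_cods(constant_matrix(30, 0.0))
        assert len(cods) == 0

    def test_small_block_discarded_by_min_size(self):
        C = np.zeros((20, 20))
        C[8:11, 8:11] = 0.9  # 3-gene block: below the 4-gene floor
        np.fill_diagonal(C, 1.0)
        cods, _ = call_cods(matrix_from(C))
        assert len(cods) == 0

    def test_two_planted_blocks_recovered_within_one_gene(self):
        spec = SyntheticSpec(
            n_genes=44,
            n_samples=200,
            blocks=[(8, 17, 0.7), (26, 35, 0.7)],
            seed=5,
        )
        expr, annot, truth = generate_expression(spec)
        cm = build_coexpression_matrix(expr, annot, "1")
        cods, _ = call_cods(cm, annot)
        assert len(cods) == 2
        for called, true in zip(cods.domains, truth.domains):
            assert abs(called.first_rank - true.first_rank) <= 1
            assert abs(called.last_rank - true.last_rank) <= 1

    def test_short_chromosome_yields_empty_set(self):
        cods, bounds = call_cods(constant_matrix(6, 0.5))
        assert len(cods) == 0 and bounds == []

    def test_every_cod_satisfies_contract(self, default_cohort):
        _, _, annot, _, cm = default_cohort
        cfg = CODCallConfig()
        track = compute_binsignal(cm, cfg.w)
        cods, _ = call_cods(cm, annot, cfg)
        assert len(cods) > 0
        for d in cods.domains:
            assert d.n_genes >= cfg.min_cod_genes
            inner = track.values[d.first_rank : d.last_rank]  # junctions inside
            below = inner < cfg.threshold
            # no >= 2 consecutive below-threshold junctions strictly inside
            assert not any(below[i] and below[i + 1] for i in range(len(below) - 1))

    def test_calls_invariant_to_sample_permutation_and_offset(self, default_cohort):
        spec, expr, annot, _, cm = default_cohort
        cods1, _ = call_cods(cm, annot)
        rng = np.random.default_rng(1)
        values = expr.values[:, rng.permutation(expr.n_samples)].copy()
        values[:, 0] += 7.5  # constant shift of one sample
        expr2 = ExpressionMatrix(expr.genes, expr.samples, values)
        cm2 = build_coexpression_matrix(expr2, annot, "1")
        cods2, _ = call_cods(cm2, annot)
        assert [(d.first_rank, d.last_rank) for d in cods1.domains] == [
            (d.first_rank, d.last_rank) for d in cods2.domains
        ]

    def test_gene_order_shuffle_destroys_cods(self, default_cohort):
        """Scrambling gene order flattens binsignal and COD calls vanish."""
        _, _, _, _, cm = default_cohort
        counts = []
        for seed in range(20):
            perm = np.random.default_rng(seed).permutation(cm.n_genes)
            shuffled = CoexpressionMatrix(
                "1",
                [cm.gene_ids[i] for i in perm],
                cm.C[np.ix_(perm, perm)],
                cm.valid_mask[perm],
            )
            cods, _ = call_cods(shuffled)
            counts.append(len(cods))
        assert np.mean(counts) <= 1.0

    def test_boundary_f1_nondecreasing_in_rho(self):
        """Stronger planted correlation never hurts boundary recovery (fixed seeds)."""
        mean_f1 = []
        for rho in (0.2, 0.4, 0.6, 0.8):
            f1s = []
            for seed in (1, 2, 3, 4, 5):
                spec = SyntheticSpec(
                    seed=seed,
                    blocks=[(b0, b1, rho) for b0, b1, _ in SyntheticSpec().blocks],
                )
                expr, annot, truth = generate_expression(spec)
                cm = build_coexpression_matrix(expr, annot, "1")
                cods, _ = call_cods(cm, annot)
                f1s.append(evaluate_recovery(cods, truth, 1).boundary_f1)
            mean_f1.append(np.mean(f1s))
        assert all(b >= a - 1e-9 for a, b in zip(mean_f1, mean_f1[1:]))


class TestWindowSweep:
    def test_windows_3_to_6_agree(self, default_cohort):
        _, _, annot, truth, cm = default_cohort
        tab = window_sweep(cm, [3, 4, 5, 6], annot)
        assert list(tab["n_cods"]) == [5, 5, 5, 5]
        spread = tab["mean_intra_coexpression"].max() - tab["mean_intra_coexpression"].min()
        assert spread < 0.05

    def test_w1_noisier_segmentation_than_w4(self):
        # single-junction binsignal is noisy: on a weaker cohort w=1 either
        # miscounts domains or absorbs background (lower intra purity)
        from codomains.synthetic import blocks_with_gaps

        blocks = [(b0, b1, 0.4) for b0, b1, _ in blocks_with_gaps(5, 10, 6, 0.4)]
        expr, annot, truth = generate_expression(
            SyntheticSpec(seed=11, n_samples=60, blocks=blocks)
        )
        cm = build_coexpression_matrix(expr, annot, "1")
        tab = window_sweep(cm, [1, 4], annot).set_index("w")
        assert tab.loc[4, "n_cods"] == len(truth.domains)
        assert (
            tab.loc[1, "n_cods"] != tab.loc[4, "n_cods"]
            or tab.loc[1, "mean_intra_coexpression"] < tab.loc[4, "mean_intra_coexpression"]
        )

    def test_empty_window_list(self, default_cohort):
        _, _, annot, _, cm = default_cohort
        assert len(window_sweep(cm, [], annot)) == 0
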