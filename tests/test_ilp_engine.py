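"""Direct and refinement ILPs against brute-force optimality oracles."""

import numpy as np
import pytest

from recticluster import ilp_engine as ie
from recticluster import rect_partition as rp

from conftest import random_similarity_tensor


def solve_direct(S, lam, transitivity="full"):
    prog = ie.build_direct_program(S, lam, transitivity=transitivity)
    res = ie.solve(prog)
    assert res.status == "optimal" and res.gap == 0.0
    return res, ie.decode_direct(res, S.shape[:2])


class TestBuildDirect:
    def test_2x2_variable_and_row_counts(self):
        S = np.zeros((2, 2, 2, 2))
        S[:] = np.eye(4).reshape(2, 2, 2, 2)
        prog = ie.build_direct_program(S, 0.5)
        assert prog.n_vars == 6  # C(4,2) unordered cell pairs
        # closed-form as-built count: 3*C(4,3) transitivity + 5*C(2,2)^2 rect
        assert prog.n_rows == ie.built_row_count(2, 2) == 12 + 5

    def test_negative_lambda_rejected(self):
        with pytest.raises(ie.ProgramError, match="non-negative"):
            ie.build_direct_program(np.zeros((2, 2, 2, 2)), -0.1)

    def test_asymmetric_similarity_rejected(self):
        S = np.zeros((2, 1, 2, 1))
        S[0, 0, 1, 0] = 0.7  # missing the mirrored entry
        with pytest.raises(ie.ProgramError, match="symmetric"):
            ie.build_direct_program(S, 0.0)

    def test_written_row_count_exceeds_one_million_for_study_grid(self):
        assert ie.written_row_count(36, 14) > 1_000_000

    def test_lambda_zero_nonneg_similarity_single_cluster_optimal(self):
        rng = np.random.default_rng(5)
        S = random_similarity_tensor(2, 2, rng)
        _, part = solve_direct(S, 0.0)
        # 1-X = all-ones maximizes <S, 1-X> when S >= 0
        assert ie.objective_direct(S, part, 0.0) == pytest.approx(float(S.sum()))


class TestWorkedInstance:
    def test_row_split_at_lambda_half(self, orthogonal_rows_similarity, row_split_2x2):
        res, part = solve_direct(orthogonal_rows_similarity, 0.5)
        assert res.objective_value == pytest.approx(12.0)
        assert part.same_partition(row_split_2x2)

    def test_singletons_at_lambda_two(self, orthogonal_rows_similarity):
        res, part = solve_direct(orthogonal_rows_similarity, 2.0)
        assert res.objective_value == pytest.approx(28.0)  # 4 + 2*12
        assert part.m == 4

    def test_objective_direct_examples(self, orthogonal_rows_similarity, row_split_2x2):
        ones = np.ones((2, 2, 2, 2))
        whole = rp.RectangularPartition(
            (2, 2), ((frozenset({0, 1}), frozenset({0, 1})),)
        )
        assert ie.objective_direct(ones, whole, 0.0) == pytest.approx(16.0)
        assert ie.objective_direct(
            orthogonal_rows_similarity, row_split_2x2, 0.5
        ) == pytest.approx(12.0)
        # zero off-diagonal: value = n1*n2 diagonal terms for any partition
        diag_only = np.eye(4).reshape(2, 2, 2, 2)
        for part in rp.enumerate_rectangular_partitions(2, 2):
            assert ie.objective_direct(diag_only, part, 0.0) == pytest.approx(4.0)

    def test_shape_mismatch_rejected(self, row_split_2x2):
        with pytest.raises(ie.ProgramError, match="mismatch"):
            ie.objective_direct(np.zeros((3, 2, 3, 2)), row_split_2x2, 0.0)


class TestOracleEquivalence:
    @pytest.mark.parametrize("grid", [(2, 2), (3, 2), (2, 3)])
    @pytest.mark.parametrize("lam", [0.0, 0.5, 2.0])
    def test_solver_matches_brute_force(self, grid, lam):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            S = random_similarity_tensor(*grid, rng)
            res, _ = solve_direct(S, lam)
            _, brute = ie.brute_force_direct(S, lam)
            assert res.objective_value == pytest.approx(brute, abs=1e-9)

    def test_lazy_and_full_modes_agree(self):
        rng = np.random.default_rng(11)
        S = random_similarity_tensor(3, 3, rng)
        full, _ = solve_direct(S, 0.5, transitivity="full")
        lazy, part = solve_direct(S, 0.5, transitivity="lazy")
        assert lazy.objective_value == pytest.approx(full.objective_value, abs=1e-9)
        assert rp.validate_partition(part) == []

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        S = random_similarity_tensor(3, 2, rng)
        perm_r, perm_c = [2, 0, 1], [1, 0]
        S_perm = S[np.ix_(perm_r, perm_c, perm_r, perm_c)]
        res, part = solve_direct(S, 0.7)
        res_p, part_p = solve_direct(S_perm, 0.7)
        assert res.objective_value == pytest.approx(res_p.objective_value, abs=1e-9)
        # permuting the grid permutes the optimal partition
        g = part.membership_grid()[np.ix_(perm_r, perm_c)]
        g_p = part_p.membership_grid()
        from conftest import rand_index

        assert rand_index(g, g_p) == 1.0

    def test_lambda_monotone_between_pair_count(self):
        rng = np.random.default_rng(21)
        S = random_similarity_tensor(2, 3, rng)
        between = []
        for lam in [0.0, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0]:
            _, part = solve_direct(S, lam)
            between.append(int(rp.partition_to_x(part).sum()))
        assert all(a <= b for a, b in zip(between, between[1:]))


class TestRefine:
    def test_rectangular_w_is_fixed_point(self):
        part = rp.RectangularPartition(
            (3, 2), ((frozenset({0, 2}), frozenset({0, 1})),
                     (frozenset({1}), frozenset({0, 1})))
        )
        W = rp.partition_to_y(part, m=2)
        prog = ie.build_refine_program(W)
        res = ie.solve(prog)
        assert res.objective_value == pytest.approx(6.0)  # n1*n2, all unchanged
        assert ie.decode_refine(res, (3, 2), 2).same_partition(part)

    def test_anti_diagonal_agreement_two(self):
        W = np.zeros((2, 2, 2), dtype=int)
        W[0, 0, 0] = W[1, 1, 0] = 1
        W[0, 1, 1] = W[1, 0, 1] = 1
        res = ie.solve(ie.build_refine_program(W))
        assert res.objective_value == pytest.approx(2.0)
        part = ie.decode_refine(res, (2, 2), 2)
        assert rp.validate_partition(part) == []
        _, brute = ie.brute_force_refine(W)
        assert brute == pytest.approx(2.0)

    def test_interpretability_row_count_formula(self):
        assert ie.refine_row_count(36, 14, 5) == 36**2 * 14**2 * 5
        W = np.zeros((3, 2, 2), dtype=int)
        W[:, :, 0] = 1
        prog = ie.build_refine_program(W)
        # as-built: n1(n1-1) n2(n2-1) m interpretability + n1 n2 assignment rows
        assert prog.n_rows == ie.refine_row_count(3, 2, 2, as_written=False) + 6

    def test_invalid_w_rejected(self):
        W = np.zeros((2, 2, 2), dtype=int)  # rows sum to 0
        with pytest.raises(ie.ProgramError, match="sum to 1"):
            ie.build_refine_program(W)

    def test_refinement_upper_bound_and_oracle_cross_check(self):
        rng = np.random.default_rng(9)
        for seed in range(6):
            labels = rng.integers(0, 3, size=(3, 2))
            W = rp.labels_to_w(labels, 3)
            res = ie.solve(ie.build_refine_program(W))
            _, brute = ie.brute_force_refine(W)
            assert res.objective_value == pytest.approx(brute, abs=1e-9)
            assert res.objective_value <= 6.0 + 1e-9
            part = ie.decode_refine(res, (3, 2), 3)
            assert rp.validate_partition(part) == []

    def test_agreement_equals_grid_size_iff_w_rectangular(self):
        # non-rectangular W must lose at least one assignment
        W = np.zeros((2, 2, 2), dtype=int)
        W[0, 0, 0] = W[0, 1, 0] = W[1, 0, 0] = 1  # L-shape
        W[1, 1, 1] = 1
        res = ie.solve(ie.build_refine_program(W))
        assert res.objective_value < 4.0


class TestSuggestLambda:
    def test_bimodal_split(self):
        # two planted blocks: within 1, across 0 -> lambda strictly between
        g = np.array([[0, 0], [1, 1]])
        S = (g[:, :, None, None] == g[None, None, :, :]).astype(float)
        lam = ie.suggest_lambda(S)
        assert 0.0 < lam < 1.0

    def test_trimodal_lands_above_all_cross_modes(self):
        N = 12
        g = np.repeat([0, 1, 2], 4)
        Smat = np.full((N, N), 0.7)
        Smat[(g[:, None] == 0) & (g[None, :] == 1)] = 0.0
        Smat[(g[:, None] == 1) & (g[None, :] == 0)] = 0.0
        Smat[g[:, None] == g[None, :]] = 1.0
        lam = ie.suggest_lambda(Smat.reshape(4, 3, 4, 3))
        assert 0.7 < lam < 1.0


def test_export_lp_smoke(tmp_path, orthogonal_rows_similarity):
    prog = ie.build_direct_program(orthogonal_rows_similarity, 0.5)
    path = tmp_path / "direct.lp"
    ie.export_lp(prog, path)
    text = path.read_text()
    assert "Maximize" in text and "x_0_3" in text and "Binary" in text
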