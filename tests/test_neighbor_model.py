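import numpy as np
import pytest
from scipy.optimize import nnls

from oracles import brute_force_weight_system, enumerate_active_sets, qp_objective

from ncfger import (
    NeighborConfig,
    ResponseMatrix,
    SimilarityMatrix,
    WeightSystem,
    build_weight_system,
    predict_entry,
    response_pcc,
    select_neighbors,
    shrink_similarity,
    solve_nonnegative_weights,
)


class TestSelectNeighbors:
    def _setup(self):
        V = np.full((3, 6), 1.0)
        V[0, 4] = np.nan
        R = ResponseMatrix.from_array(V)
        S = np.eye(6)
        S[0, [1, 2, 5]] = S[[1, 2, 5], 0] = [0.9, 0.9, 0.2]
        sim = SimilarityMatrix([f"D{i}" for i in range(6)], 0.5 * (S + S.T), "RPCC")
        return R, sim

    def test_fewer_candidates_than_k(self):
        R, sim = self._setup()
        got = select_neighbors((0, 0), R, sim, k=10, orientation="drug")
        assert len(got) == 4  # drug 0 is the target, drug 4 unobserved for the cell line

    def test_tie_broken_by_ascending_index(self):
        R, sim = self._setup()
        got = select_neighbors((0, 0), R, sim, k=3, orientation="drug")
        assert got == [1, 2, 5]  # 0.9 tie between 1 and 2, then 0.2

    def test_unobserved_counterpart_excluded(self):
        R, sim = self._setup()
        got = select_neighbors((0, 0), R, sim, k=10, orientation="drug")
        assert 4 not in got

    def test_zero_candidates(self):
        V = np.full((2, 2), np.nan)
        V[0, 0] = 1.0
        R = ResponseMatrix.from_array(V)
        sim = SimilarityMatrix(["D0", "D1"], np.eye(2), "RPCC")
        assert select_neighbors((1, 1), R, sim, k=5, orientation="drug") == []

    def test_cell_line_orientation_uses_column_mask(self):
        V = np.full((4, 2), 1.0)
        V[2, 0] = np.nan
        R = ResponseMatrix.from_array(V)
        sim = SimilarityMatrix([f"C{i}" for i in range(4)], np.eye(4), "RPCC")
        got = select_neighbors((0, 0), R, sim, k=10, orientation="cell_line")
        assert got == [1, 3]


class TestBuildWeightSystem:
    def test_matches_double_loop_oracle(self, rng):
        V = rng.normal(size=(8, 4))
        R = ResponseMatrix.from_array(V)
        neighbors = [0, 1, 3]
        system = build_weight_system((2, 2), neighbors, R, beta=5.0)
        A_bar, b_bar, A_hat, b_hat, avg = brute_force_weight_system(R, 2, 2, neighbors, 5.0)
        assert np.abs(system.A_bar - A_bar).max() < 1e-12
        assert np.abs(system.b_bar - b_bar).max() < 1e-12
        assert np.abs(system.A_hat - A_hat).max() < 1e-12
        assert np.abs(system.b_hat - b_hat).max() < 1e-12
        assert system.avg == pytest.approx(avg, abs=1e-12)

    def test_matches_oracle_on_sparse_data(self, rng):
        V = rng.normal(size=(12, 6))
        V[rng.random((12, 6)) < 0.4] = np.nan
        R = ResponseMatrix.from_array(V)
        neighbors = [1, 4, 5]
        system = build_weight_system((3, 0), neighbors, R, beta=7.5)
        _, _, A_hat, b_hat, _ = brute_force_weight_system(R, 3, 0, neighbors, 7.5)
        assert np.abs(system.A_hat - A_hat).max() < 1e-12
        assert np.abs(system.b_hat - b_hat).max() < 1e-12

    def test_beta_zero_no_shrinkage(self, rng):
        V = rng.normal(size=(9, 5))
        R = ResponseMatrix.from_array(V)
        system = build_weight_system((0, 0), [1, 2, 3], R, beta=0.0)
        assert np.array_equal(system.A_hat, system.A_bar)
        assert np.array_equal(system.b_hat, system.b_bar)

    def test_beta_infinity_limit_is_avg(self, rng):
        V = rng.normal(size=(9, 5))
        R = ResponseMatrix.from_array(V)
        system = build_weight_system((0, 0), [1, 2, 3], R, beta=1e9)
        assert np.abs(system.A_hat - system.avg).max() < 1e-6 * abs(system.avg)
        assert np.abs(system.b_hat - system.avg).max() < 1e-6 * abs(system.avg)

    def test_zero_support_pair_shrinks_to_avg(self):
        # drugs 0 and 1 never co-observed away from the target cell line
        V = np.array(
            [[1.0, 1.0, 1.0],
             [2.0, np.nan, 1.0],
             [np.nan, 3.0, 2.0],
             [1.5, np.nan, 0.5]]
        )
        R = ResponseMatrix.from_array(V)
        system = build_weight_system((0, 2), [0, 1], R, beta=4.0)
        assert system.supports[0, 1] == 0
        assert system.A_bar[0, 1] == 0.0
        assert system.A_hat[0, 1] == pytest.approx(system.avg)

    def test_target_row_excluded_from_sums(self, rng):
        V = rng.normal(size=(6, 4))
        R = ResponseMatrix.from_array(V)
        system = build_weight_system((1, 0), [1, 2], R, beta=0.0)
        poisoned = V.copy()
        poisoned[1, :] = 1e3  # anything in the target row must not matter
        system2 = build_weight_system((1, 0), [1, 2], ResponseMatrix.from_array(poisoned), beta=0.0)
        assert np.allclose(system.A_hat, system2.A_hat, atol=1e-8)
        assert np.allclose(system.b_hat, system2.b_hat, atol=1e-8)

    def test_empty_neighbor_list_rejected(self, rng):
        R = ResponseMatrix.from_array(rng.normal(size=(4, 4)))
        with pytest.raises(ValueError):
            build_weight_system((0, 0), [], R, beta=1.0)


class TestSolveNonnegativeWeights:
    def _system(self, A, b):
        A = np.asarray(A, float)
        b = np.asarray(b, float)
        K = len(b)
        return WeightSystem(
            A_bar=A, b_bar=b, A_hat=A, b_hat=b, avg=0.0,
            supports=np.ones((K, K), int), b_supports=np.ones(K, int),
        )

    def test_scalar_closed_form(self):
        w = solve_nonnegative_weights(self._system([[4.0]], [2.0]))
        assert w == pytest.approx([0.5])

    def test_scalar_nonnegativity_active(self):
        w = solve_nonnegative_weights(self._system([[4.0]], [-2.0]))
        assert w == pytest.approx([0.0])

    def test_matches_active_set_enumeration(self, rng):
        for _ in range(100):
            M = rng.normal(size=(5, 3))
            A = M.T @ M + 0.1 * np.eye(3)
            b = rng.normal(size=3)
            system = self._system(A, b)
            w = solve_nonnegative_weights(system)
            _, best_obj = enumerate_active_sets(A, b)
            assert (w >= 0).all()
            assert qp_objective(w, system) <= best_obj + 1e-9

    def test_non_finite_system_rejected(self):
        with pytest.raises(ValueError):
            solve_nonnegative_weights(self._system([[np.inf]], [1.0]))

    def test_all_zero_system(self):
        w = solve_nonnegative_weights(self._system(np.zeros((3, 3)), np.zeros(3)))
        assert np.array_equal(w, np.zeros(3))

    def test_indefinite_system_stays_bounded(self):
        # shrinkage toward a negative avg can make A indefinite
        A = np.full((3, 3), -0.5) + 0.01 * np.eye(3)
        w = solve_nonnegative_weights(self._system(A, np.full(3, -0.4)))
        assert (w >= 0).all() and np.abs(w).max() < 1e3

    def test_beta_zero_dense_matches_generic_nnls(self, rng):
        # with beta=0 and full observation the QP is the NNLS of the target
        # column on the neighbor columns (rows without the target cell line)
        V = rng.normal(size=(15, 6))
        R = ResponseMatrix.from_array(V)
        u, i, neighbors = 4, 0, [1, 2, 3, 5]
        system = build_weight_system((u, i), neighbors, R, beta=0.0)
        w = solve_nonnegative_weights(system)
        rows = [v for v in range(15) if v != u]
        X, y = V[np.ix_(rows, neighbors)], V[rows, i]
        w_ref, _ = nnls(X, y)
        scale = len(rows)
        obj = qp_objective(w, system)
        obj_ref = (w_ref @ (X.T @ X) @ w_ref - 2 * (X.T @ y) @ w_ref) / scale
        assert obj <= obj_ref + 1e-9


class TestPredictEntry:
    def _similarities(self, R):
        S_d = shrink_similarity(response_pcc(R, axis="drugs", min_overlap=2), 1.0)
        S_c = shrink_similarity(response_pcc(R, axis="cell_lines", min_overlap=2), 1.0)
        return S_c, S_d

    def test_rank_one_duplicated_column_recovered_exactly(self):
        # noiseless rank-1 matrix, drug 1 duplicates drug 0; no global effects
        a = np.array([1.0, 2.0, 0.5, 1.5, 3.0, 2.5, 0.8, 1.2])
        c = np.array([1.0, 1.0, 0.7, 1.3, 0.9])
        V = np.outer(a, c)
        V[0, 0] = np.nan  # hold out (0, 0); duplicate column 1 remains
        R = ResponseMatrix.from_array(V)
        S_c, S_d = self._similarities(R)
        cfg = NeighborConfig(k=3, beta=0.0, orientation="drug")
        pred = predict_entry((0, 0), R, None, S_c, S_d, cfg)
        assert pred.final_value == pytest.approx(a[0] * c[0], abs=1e-6)

    def test_hybrid_is_mean_of_orientations(self, small_dataset):
        R = small_dataset["response"]
        S_c, S_d = self._similarities(R)
        u, i = map(int, np.argwhere(~R.observed)[0])
        parts = []
        for orientation in ("drug", "cell_line"):
            cfg = NeighborConfig(k=5, beta=50.0, orientation=orientation)
            parts.append(predict_entry((u, i), R, None, S_c, S_d, cfg).residual_value)
        cfg = NeighborConfig(k=5, beta=50.0, orientation="hybrid")
        hybrid = predict_entry((u, i), R, None, S_c, S_d, cfg)
        assert hybrid.residual_value == pytest.approx(np.mean(parts), abs=1e-12)

    def test_no_neighbors_falls_back_to_global_effects(self):
        V = np.array([[np.nan, np.nan], [np.nan, 4.0]])
        R = ResponseMatrix.from_array(V)
        sim = SimilarityMatrix(["a", "b"], np.eye(2), "RPCC")
        cfg = NeighborConfig(k=2, beta=1.0, orientation="hybrid")
        # target (0, 0): cell 0 has no other observed drug and drug 0 has no
        # other observed cell line, so both orientations are empty
        pred = predict_entry((0, 0), R, None, sim, sim, cfg)
        assert pred.fallback and pred.final_value == 0.0

    def test_prediction_invariant_to_neighbor_order(self, small_dataset):
        R = small_dataset["response"]
        S_c, S_d = self._similarities(R)
        u, i = map(int, np.argwhere(~R.observed)[1])
        neighbors = select_neighbors((u, i), R, S_d, 5, "drug")
        vals = []
        for order in (neighbors, neighbors[::-1]):
            system = build_weight_system((u, i), order, R, beta=50.0)
            w = solve_nonnegative_weights(system)
            vals.append(float(w @ np.nan_to_num(R.values[u, order])))
        assert vals[0] == pytest.approx(vals[1], abs=1e-9)

    def test_weights_nonnegative_across_many_targets(self, small_dataset):
        R = small_dataset["response"]
        S_c, S_d = self._similarities(R)
        cfg = NeighborConfig(k=6, beta=100.0, orientation="hybrid")
        for u, i in np.argwhere(~R.observed)[:20]:
            pred = predict_entry((int(u), int(i)), R, None, S_c, S_d, cfg)
            for w in pred.weights.values():
                assert (np.asarray(w) >= 0).all()
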