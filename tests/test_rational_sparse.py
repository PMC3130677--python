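"""Exact sparse elimination against a naive dense rational oracle."""

from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluxkernel import (EliminationResult, RationalSparseMatrix,
                        gauss_jordan_eliminate, max_coefficient_bits,
                        read_mtx, replay_row_ops, sparsity, write_mtx)
from conftest import dense_rref, to_sparse

F = Fraction


class TestMatrixContainer:
    def test_zero_assignment_deletes_entry(self):
        m = RationalSparseMatrix(2, 2, {(0, 0): 3, (1, 1): "1/2"})
        assert m.nnz == 2 and m[1, 1] == F(1, 2)
        m[0, 0] = 0
        assert m.nnz == 1 and (0, 0) not in m.entries

    def test_float_coefficients_convert_by_decimal_literal(self):
        m = RationalSparseMatrix(1, 1, {(0, 0): 0.1})
        assert m[0, 0] == F(1, 10)

    def test_out_of_range_index_rejected(self):
        m = RationalSparseMatrix(2, 3)
        with pytest.raises(IndexError):
            m[2, 0] = 1

    def test_exact_matmul(self):
        a = to_sparse([[1, F(1, 3)], [0, 2]])
        b = to_sparse([[3, 0], [1, F(1, 2)]])
        assert a.matmul(b) == to_sparse([[F(10, 3), F(1, 6)], [2, 1]])

    @pytest.mark.parametrize("dense, expected", [
        ([[0, 0], [0, 0]], F(1)),
        ([[1, 0], [0, 1]], F(1, 2)),
    ])
    def test_sparsity_values(self, dense, expected):
        assert sparsity(to_sparse(dense)) == expected

    def test_sparsity_symmetric_under_transpose(self):
        m = to_sparse([[1, 0, 2], [0, 0, -1]])
        assert sparsity(m) == sparsity(m.transpose())

    def test_sparsity_of_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            sparsity(RationalSparseMatrix(0, 4))


class TestElimination:
    def test_already_reduced_single_row(self):
        e = gauss_jordan_eliminate(to_sparse([[1, -1]]))
        assert e.echelon == to_sparse([[1, -1]])
        assert e.pivot_columns == [0]
        assert e.free_columns == [1]
        assert e.rank == 1

    def test_rank_deficient_pair_of_rows(self):
        # second row is the negation of the first: rank 1, row 2 zeroed
        e = gauss_jordan_eliminate(to_sparse([[1, -1], [-1, 1]]))
        assert e.rank == 1
        assert len(e.pivot_columns) == 1 and len(e.free_columns) == 1
        assert 1 not in e.echelon.rows

    def test_unit_pivot_columns(self):
        e = gauss_jordan_eliminate(to_sparse([[2, 3, 1], [4, 1, 0],
                                              [0, 5, 7]]))
        for k, pc in enumerate(e.pivot_columns):
            col = [e.echelon[i, pc] for i in range(3)]
            assert col[k] == 1 and sum(1 for v in col if v) == 1

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            gauss_jordan_eliminate(RationalSparseMatrix(0, 3))

    def test_overlapping_preference_sets_rejected(self):
        with pytest.raises(ValueError):
            gauss_jordan_eliminate(to_sparse([[1, 2]]),
                                   preferred_dependent=[0],
                                   forbidden_pivot_cols={0})

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(
        st.lists(st.integers(min_value=-4, max_value=4),
                 min_size=1, max_size=8),
        min_size=1, max_size=8).filter(
            lambda rows: len({len(r) for r in rows}) == 1))
    def test_matches_dense_oracle_with_natural_column_order(self, rows):
        """With leftmost-preference the reduction is the canonical RREF."""
        m = to_sparse(rows)
        e = gauss_jordan_eliminate(
            m, preferred_dependent=range(m.n_cols))
        rref, pivots = dense_rref([[F(v) for v in r] for r in rows])
        assert e.pivot_columns == pivots
        assert e.echelon == to_sparse(rref)
        assert e.rank + len(e.free_columns) == m.n_cols

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(
        st.lists(st.integers(min_value=-4, max_value=4),
                 min_size=2, max_size=8),
        min_size=1, max_size=8).filter(
            lambda rows: len({len(r) for r in rows}) == 1))
    def test_markowitz_default_rank_and_replay(self, rows):
        """Sparsity-driven pivoting changes the basis, not rank or log."""
        m = to_sparse(rows)
        e = gauss_jordan_eliminate(m)
        _, pivots = dense_rref([[F(v) for v in r] for r in rows])
        assert e.rank == len(pivots)
        assert e.rank + len(e.free_columns) == m.n_cols
        assert sorted(e.pivot_columns + e.free_columns) == \
            list(range(m.n_cols))
        assert replay_row_ops(e.row_ops, m) == e.echelon

    def test_idempotent_on_echelon_form(self):
        m = to_sparse([[2, 1, 0, 3], [1, 0, 2, 1], [0, 1, 1, 4]])
        e = gauss_jordan_eliminate(m)
        again = gauss_jordan_eliminate(e.echelon,
                                       preferred_dependent=e.pivot_columns)
        assert again.echelon == e.echelon
        assert again.pivot_columns == e.pivot_columns

    def test_deterministic(self):
        m = to_sparse([[0, 2, 1], [3, 0, 1], [3, 2, 2]])
        a = gauss_jordan_eliminate(m)
        b = gauss_jordan_eliminate(m)
        assert a.echelon == b.echelon and a.row_ops == b.row_ops


class TestPivotSteering:
    def test_feasible_preferred_columns_become_pivots(self):
        m = to_sparse([[1, 1, 0], [0, 1, 1]])
        e = gauss_jordan_eliminate(m, preferred_dependent=[2, 1])
        assert set(e.pivot_columns) == {1, 2}
        assert e.forced_pivots == []

    def test_forbidden_columns_avoided_when_possible(self):
        m = to_sparse([[1, 1, 0], [0, 1, 1]])
        e = gauss_jordan_eliminate(m, forbidden_pivot_cols={0})
        assert 0 in e.free_columns
        assert e.forced_pivots == []

    def test_infeasible_forbidden_set_triggers_documented_move(self):
        # both columns forbidden: one must still carry the pivot
        m = to_sparse([[1, -1]])
        e = gauss_jordan_eliminate(m, forbidden_pivot_cols={0, 1})
        assert e.rank == 1
        assert e.forced_pivots == e.pivot_columns
        assert len(e.forced_pivots) == 1

    def test_partial_infeasibility_moves_minimum_needed(self):
        # cols 1 and 2 are equal; forbidding both forces exactly one back
        m = to_sparse([[1, 2, 2], [1, 0, 0]])
        e = gauss_jordan_eliminate(m, forbidden_pivot_cols={1, 2})
        assert e.rank == 2
        assert len(e.forced_pivots) == 1
        assert e.forced_pivots[0] in (1, 2)


class TestReplay:
    def test_replay_on_identity_yields_transformation_matrix(self):
        m = to_sparse([[2, 4, 1], [1, 2, 0], [0, 3, 5]])
        e = gauss_jordan_eliminate(m)
        t = replay_row_ops(e.row_ops, RationalSparseMatrix.identity(3))
        assert t.matmul(m) == e.echelon

    def test_empty_log_is_identity_operation(self):
        m = to_sparse([[1, 2], [3, 4]])
        assert replay_row_ops([], m) == m

    def test_replay_on_augmented_columns(self):
        """Reducing [A | B] pivoting only in A = replaying A's log on B."""
        a = to_sparse([[2, 1], [4, 1]])
        b = to_sparse([[5], [6]])
        e = gauss_jordan_eliminate(a, preferred_dependent=range(2))
        aug = RationalSparseMatrix(2, 3)
        for i, j, v in a.items():
            aug[i, j] = v
        for i, j, v in b.items():
            aug[i, 2 + j] = v
        e_aug = gauss_jordan_eliminate(aug, preferred_dependent=range(2),
                                       forbidden_pivot_cols={2})
        replayed = replay_row_ops(e.row_ops, b)
        for i in range(2):
            assert replayed[i, 0] == e_aug.echelon[i, 2]

    def test_row_count_mismatch_rejected(self):
        e = gauss_jordan_eliminate(to_sparse([[1, 2], [3, 4]]))
        with pytest.raises(ValueError):
            replay_row_ops(e.row_ops, RationalSparseMatrix(1, 2))


class TestSerialization:
    def test_mtx_round_trip_preserves_fractions(self, tmp_path):
        m = to_sparse([[F(1, 3), 0], [-2, F(7, 5)]])
        path = tmp_path / "m.mtx"
        write_mtx(m, path)
        assert read_mtx(path) == m
        assert "rational" in path.read_text().splitlines()[0]

    def test_elimination_result_json_round_trip(self):
        e = gauss_jordan_eliminate(to_sparse([[2, 1, 1], [0, 1, 3]]))
        back = EliminationResult.loads(e.dumps())
        assert back.echelon == e.echelon
        assert back.pivot_columns == e.pivot_columns
        assert back.row_ops == e.row_ops
        assert back.rank == e.rank


def test_no_coefficient_explosion_on_fixture_suite(small_fixture_matrices):
    """Sparse small-integer inputs keep elimination coefficients short."""
    ceiling = 64  # bits; inputs start below 8
    for _, matrix, _ in small_fixture_matrices:
        e = gauss_jordan_eliminate(matrix)
        assert max_coefficient_bits(e.echelon) <= ceiling
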