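"""Shared helpers: a deliberately naive dense rational oracle.

The oracle eliminates with plain leftmost-column pivoting over dense lists
of Fractions -- no sparsity structure, no pivot heuristics, no shared code
with the package -- so it can stand as an independent reference for the
sparse elimination and its kernel.
"""

from fractions import Fraction

import pytest

from fluxkernel import FixtureSpec, RationalSparseMatrix, random_network


def dense_rref(mat: list[list[Fraction]]) -> tuple[list[list[Fraction]], list[int]]:
    """Reduced row-echelon form with leftmost-column pivoting."""
    work = [list(row) for row in mat]
    n_cols = len(work[0]) if work else 0
    pivots: list[int] = []
    row = 0
    for col in range(n_cols):
        piv = next((i for i in range(row, len(work)) if work[i][col]), None)
        if piv is None:
            continue
        work[row], work[piv] = work[piv], work[row]
        inv = Fraction(1) / work[row][col]
        work[row] = [x * inv for x in work[row]]
        prow = work[row]
        for i in range(len(work)):
            if i != row and work[i][col]:
                f = work[i][col]
                work[i] = [a - f * b for a, b in zip(work[i], prow)]
        pivots.append(col)
        row += 1
    return work, pivots


def dense_nullspace(mat: list[list[Fraction]]) -> list[list[Fraction]]:
    """Nullspace basis vectors (one per free column) from the dense RREF."""
    rref, pivots = dense_rref(mat)
    n_cols = len(mat[0]) if mat else 0
    free = [c for c in range(n_cols) if c not in pivots]
    basis = []
    for fc in free:
        v = [Fraction(0)] * n_cols
        v[fc] = Fraction(1)
        for k, pc in enumerate(pivots):
            v[pc] = -rref[k][fc]
        basis.append(v)
    return basis


def rational_rank(vectors: list[list[Fraction]]) -> int:
    if not vectors:
        return 0
    _, pivots = dense_rref(vectors)
    return len(pivots)


def same_span(a: list[list[Fraction]], b: list[list[Fraction]]) -> bool:
    """Exact column/row span equality via rank comparisons."""
    ra, rb = rational_rank(a), rational_rank(b)
    return ra == rb == rational_rank(a + b)


def fixture_suite(n: int = 200, base_seed: int = 0) -> list[FixtureSpec]:
    """The seeded random-matrix suite: mixed sizes up to 60 x 100."""
    shapes = [
        (4, 6, 3), (5, 8, 5), (8, 12, 6), (10, 10, 9), (12, 20, 10),
        (20, 30, 18), (30, 40, 25), (40, 60, 35), (50, 80, 45), (60, 100, 55),
    ]
    specs = []
    for k in range(n):
        m, nc, r = shapes[k % len(shapes)]
        specs.append(FixtureSpec(m, nc, r, seed=base_seed + k,
                                 sparsity_target=0.85))
    return specs


@pytest.fixture(scope="session")
def small_fixture_matrices():
    """A couple dozen seeded matrices with known nullity, for reuse."""
    out = []
    for spec in fixture_suite(24):
        matrix, nullity = random_network(spec)
        out.append((spec, matrix, nullity))
    return out


def to_sparse(dense) -> RationalSparseMatrix:
    return RationalSparseMatrix.from_dense(dense)
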