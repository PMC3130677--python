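"""Exact sparse rational matrices and Gauss-Jordan elimination.

The stoichiometric matrices of metabolic networks are extremely sparse and
their entries are small integers or simple decimal fractions.  This module
provides a sparse 2-D container over :class:`fractions.Fraction` (so all
arithmetic is exact, never rounded) and a Gauss-Jordan elimination routine
that

* preserves sparsity through a Markowitz-style pivot rule,
* lets the caller steer the pivot choice (preferred dependent columns,
  columns to avoid), and
* records every elementary row operation so the same reduction can be
  replayed on other matrices with the same row count (e.g. appended
  exchange-reaction columns).

Nothing in this module knows about metabolism; it is plain exact linear
algebra over Q.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "Rational",
    "RationalSparseMatrix",
    "RowOperation",
    "EliminationResult",
    "gauss_jordan_eliminate",
    "replay_row_ops",
    "sparsity",
    "max_coefficient_bits",
    "write_mtx",
    "read_mtx",
]

#: The exact rational scalar type used throughout the package.
Rational = Fraction

_ZERO = Fraction(0)
_ONE = Fraction(1)


def _as_fraction(value) -> Fraction:
    """Coerce ints, Fractions and decimal-literal strings exactly.

    Floats are converted through their shortest round-tripping decimal
    representation so that 0.1 becomes 1/10, not the binary artefact
    3602879701896397/36028797018963968.
    """
    if isinstance(value, Fraction):
        return value
    if isinstance(value, int):
        return Fraction(value)
    if isinstance(value, float):
        if value != value or value in (float("inf"), float("-inf")):
            raise ValueError(f"non-finite coefficient: {value!r}")
        return Fraction(repr(value))
    if isinstance(value, str):
        return Fraction(value)
    raise TypeError(f"cannot interpret {value!r} as an exact rational")


class RationalSparseMatrix:
    """A sparse ``n_rows x n_cols`` matrix of exact rationals.

    Only nonzero entries are stored; assigning zero deletes the entry.
    """

    __slots__ = ("n_rows", "n_cols", "rows")

    def __init__(self, n_rows: int, n_cols: int,
                 entries: Mapping[tuple[int, int], object] | None = None):
        if n_rows < 0 or n_cols < 0:
            raise ValueError("matrix dimensions must be nonnegative")
        self.n_rows = n_rows
        self.n_cols = n_cols
        # row index -> {col index -> Fraction}; rows with no entries absent
        self.rows: dict[int, dict[int, Fraction]] = {}
        if entries:
            for (i, j), v in entries.items():
                self[i, j] = v

    # -- construction helpers ------------------------------------------------

    @classmethod
    def from_dense(cls, dense: Sequence[Sequence[object]]) -> "RationalSparseMatrix":
        n_rows = len(dense)
        n_cols = len(dense[0]) if n_rows else 0
        m = cls(n_rows, n_cols)
        for i, row in enumerate(dense):
            if len(row) != n_cols:
                raise ValueError("ragged dense input")
            for j, v in enumerate(row):
                fv = _as_fraction(v)
                if fv:
                    m.rows.setdefault(i, {})[j] = fv
        return m

    @classmethod
    def identity(cls, n: int) -> "RationalSparseMatrix":
        m = cls(n, n)
        for i in range(n):
            m.rows[i] = {i: _ONE}
        return m

    def copy(self) -> "RationalSparseMatrix":
        out = RationalSparseMatrix(self.n_rows, self.n_cols)
        out.rows = {i: dict(r) for i, r in self.rows.items()}
        return out

    # -- element access ------------------------------------------------------

    def _check(self, i: int, j: int) -> None:
        if not (0 <= i < self.n_rows and 0 <= j < self.n_cols):
            raise IndexError(f"index ({i}, {j}) outside "
                             f"{self.n_rows}x{self.n_cols} matrix")

    def __getitem__(self, key: tuple[int, int]) -> Fraction:
        i, j = key
        self._check(i, j)
        return self.rows.get(i, {}).get(j, _ZERO)

    def __setitem__(self, key: tuple[int, int], value) -> None:
        i, j = key
        self._check(i, j)
        fv = _as_fraction(value)
        if fv:
            self.rows.setdefault(i, {})[j] = fv
        else:
            row = self.rows.get(i)
            if row and j in row:
                del row[j]
                if not row:
                    del self.rows[i]

    def items(self) -> Iterator[tuple[int, int, Fraction]]:
        """Iterate ``(row, col, value)`` over nonzero entries, sorted."""
        for i in sorted(self.rows):
            row = self.rows[i]
            for j in sorted(row):
                yield i, j, row[j]

    @property
    def entries(self) -> dict[tuple[int, int], Fraction]:
        return {(i, j): v for i, j, v in self.items()}

    @property
    def nnz(self) -> int:
        return sum(len(r) for r in self.rows.values())

    # -- algebra -------------------------------------------------------------

    def transpose(self) -> "RationalSparseMatrix":
        out = RationalSparseMatrix(self.n_cols, self.n_rows)
        for i, j, v in self.items():
            out.rows.setdefault(j, {})[i] = v
        return out

    def matmul(self, other: "RationalSparseMatrix") -> "RationalSparseMatrix":
        """Exact matrix product ``self @ other``."""
        if self.n_cols != other.n_rows:
            raise ValueError("inner dimensions do not match")
        out = RationalSparseMatrix(self.n_rows, other.n_cols)
        for i, row in self.rows.items():
            acc: dict[int, Fraction] = {}
            for k, a in row.items():
                orow = other.rows.get(k)
                if not orow:
                    continue
                for j, b in orow.items():
                    s = acc.get(j, _ZERO) + a * b
                    if s:
                        acc[j] = s
                    elif j in acc:
                        del acc[j]
            if acc:
                out.rows[i] = acc
        return out

    __matmul__ = matmul

    def is_zero(self) -> bool:
        return not self.rows

    def to_dense(self) -> list[list[Fraction]]:
        out = [[_ZERO] * self.n_cols for _ in range(self.n_rows)]
        for i, j, v in self.items():
            out[i][j] = v
        return out

    def to_float_array(self):
        import numpy as np

        a = np.zeros((self.n_rows, self.n_cols), dtype=float)
        for i, j, v in self.items():
            a[i, j] = float(v)
        return a

    def __eq__(self, other) -> bool:
        if not isinstance(other, RationalSparseMatrix):
            return NotImplemented
        return (self.n_rows == other.n_rows and self.n_cols == other.n_cols
                and {i: r for i, r in self.rows.items()}
                == {i: r for i, r in other.rows.items()})

    def __repr__(self) -> str:
        return (f"RationalSparseMatrix({self.n_rows}x{self.n_cols}, "
                f"nnz={self.nnz})")


def sparsity(matrix: RationalSparseMatrix) -> Fraction:
    """Fraction of zero entries, ``1 - nnz / (rows * cols)``, exact."""
    if matrix.n_rows == 0 or matrix.n_cols == 0:
        raise ValueError("sparsity is undefined for a zero-sized matrix")
    return _ONE - Fraction(matrix.nnz, matrix.n_rows * matrix.n_cols)


def max_coefficient_bits(matrix: RationalSparseMatrix) -> int:
    """Largest bit length among all numerators and denominators.

    A regression guard against coefficient explosion during exact
    elimination; sparse small-integer inputs should keep this small.
    """
    best = 0
    for _, _, v in matrix.items():
        best = max(best, v.numerator.bit_length(), v.denominator.bit_length())
    return best


# -- row operations ----------------------------------------------------------

@dataclass(frozen=True)
class RowOperation:
    """One elementary row operation.

    kind:
      * ``swap``          -- exchange ``target_row`` and ``source_row``
      * ``scale``         -- multiply ``target_row`` by ``factor`` (nonzero)
      * ``add_multiple``  -- add ``factor * source_row`` to ``target_row``
    """

    kind: str
    target_row: int
    source_row: int | None = None
    factor: Fraction | None = None

    def __post_init__(self):
        if self.kind not in ("swap", "scale", "add_multiple"):
            raise ValueError(f"unknown row-operation kind {self.kind!r}")
        if self.kind == "scale" and not self.factor:
            raise ValueError("scale factor must be nonzero")
        if self.kind in ("swap", "add_multiple") and self.source_row is None:
            raise ValueError(f"{self.kind} requires a source row")

    def to_json(self) -> dict:
        d: dict = {"kind": self.kind, "target_row": self.target_row}
        if self.source_row is not None:
            d["source_row"] = self.source_row
        if self.factor is not None:
            d["factor"] = str(self.factor)
        return d

    @classmethod
    def from_json(cls, d: Mapping) -> "RowOperation":
        factor = d.get("factor")
        return cls(kind=d["kind"], target_row=d["target_row"],
                   source_row=d.get("source_row"),
                   factor=Fraction(factor) if factor is not None else None)


def _apply_op(rows: dict[int, dict[int, Fraction]], op: RowOperation) -> None:
    if op.kind == "swap":
        a, b = op.target_row, op.source_row
        ra, rb = rows.pop(a, None), rows.pop(b, None)
        if rb is not None:
            rows[a] = rb
        if ra is not None:
            rows[b] = ra
    elif op.kind == "scale":
        row = rows.get(op.target_row)
        if row:
            for j in row:
                row[j] = row[j] * op.factor
    else:  # add_multiple
        src = rows.get(op.source_row)
        if not src:
            return
        tgt = rows.setdefault(op.target_row, {})
        for j, v in src.items():
            s = tgt.get(j, _ZERO) + op.factor * v
            if s:
                tgt[j] = s
            elif j in tgt:
                del tgt[j]
        if not tgt:
            del rows[op.target_row]


def replay_row_ops(row_ops: Sequence[RowOperation],
                   matrix: RationalSparseMatrix) -> RationalSparseMatrix:
    """Apply a recorded operation log to another matrix, exactly.

    Replaying the log recorded while eliminating ``A`` on ``A`` itself
    reproduces the echelon form bit for bit; replaying it on an identity
    matrix yields the transformation matrix ``T`` with ``T @ A`` equal to
    the echelon form; replaying it on appended columns performs the same
    reduction on the augmented system.
    """
    max_row = -1
    for op in row_ops:
        max_row = max(max_row, op.target_row,
                      op.source_row if op.source_row is not None else -1)
    if max_row >= matrix.n_rows:
        raise ValueError(
            f"operation log addresses row {max_row} but matrix has only "
            f"{matrix.n_rows} rows")
    out = matrix.copy()
    for op in row_ops:
        _apply_op(out.rows, op)
    return out


# -- elimination -------------------------------------------------------------

@dataclass
class EliminationResult:
    """Reduced row-echelon form with pivot bookkeeping.

    ``pivot_columns[k]`` is the column of the pivot sitting in row ``k`` of
    ``echelon`` (pivots are reordered into staircase form, ascending by
    column).  ``free_columns`` are the remaining columns; their count is the
    number of independent variables of the homogeneous system.
    ``forced_pivots`` lists columns the caller asked to keep pivot-free that
    had to be used anyway because the admissible columns could not span the
    row space.
    """

    echelon: RationalSparseMatrix
    pivot_columns: list[int]
    free_columns: list[int]
    row_ops: list[RowOperation]
    rank: int
    forced_pivots: list[int] = field(default_factory=list)

    def to_json(self) -> dict:
        return {
            "n_rows": self.echelon.n_rows,
            "n_cols": self.echelon.n_cols,
            "echelon": [[i, j, str(v)] for i, j, v in self.echelon.items()],
            "pivot_columns": list(self.pivot_columns),
            "free_columns": list(self.free_columns),
            "row_ops": [op.to_json() for op in self.row_ops],
            "rank": self.rank,
            "forced_pivots": list(self.forced_pivots),
        }

    @classmethod
    def from_json(cls, d: Mapping) -> "EliminationResult":
        ech = RationalSparseMatrix(d["n_rows"], d["n_cols"])
        for i, j, v in d["echelon"]:
            ech[i, j] = Fraction(v)
        return cls(echelon=ech,
                   pivot_columns=list(d["pivot_columns"]),
                   free_columns=list(d["free_columns"]),
                   row_ops=[RowOperation.from_json(o) for o in d["row_ops"]],
                   rank=d["rank"],
                   forced_pivots=list(d.get("forced_pivots", [])))

    def dumps(self) -> str:
        return json.dumps(self.to_json())

    @classmethod
    def loads(cls, s: str) -> "EliminationResult":
        return cls.from_json(json.loads(s))


def gauss_jordan_eliminate(
        matrix: RationalSparseMatrix,
        preferred_dependent: Sequence[int] = (),
        forbidden_pivot_cols: Iterable[int] = ()) -> EliminationResult:
    """Reduce to reduced row-echelon form with steerable pivot choice.

    Pivot selection, in order of priority:

    1. *Preferred dependent columns* are tried first, in the caller's
       preference order; within such a column the pivot row with the fewest
       nonzeros wins (ties: smallest row index).
    2. Otherwise a Markowitz-style rule picks the admissible nonzero entry
       minimizing ``(nnz(row) - 1) * (nnz(col) - 1)``, ties broken by
       smallest column index then smallest row index.  This is the standard
       sparsity-preserving heuristic: it minimizes the worst-case fill-in
       of the elimination step.
    3. *Forbidden columns* (the caller's requested independent variables)
       are used only when no admissible column has a nonzero left, i.e.
       when the requested independent set cannot remain independent; such
       forced pivots are reported in ``forced_pivots``.

    The routine is fully deterministic and never fails on rank-deficient
    input.  Every step is logged so it can be replayed with
    :func:`replay_row_ops`.
    """
    if matrix.n_rows < 1 or matrix.n_cols < 1:
        raise ValueError("matrix must have at least one row and one column")
    n_rows, n_cols = matrix.n_rows, matrix.n_cols

    preferred = list(preferred_dependent)
    forbidden = set(forbidden_pivot_cols)
    for c in list(preferred) + list(forbidden):
        if not (0 <= c < n_cols):
            raise IndexError(f"column index {c} out of range")
    if forbidden.intersection(preferred):
        raise ValueError("preferred_dependent and forbidden_pivot_cols "
                         "must be disjoint")

    work = matrix.copy()
    rows = work.rows
    # column -> set of rows holding a nonzero there (kept in sync below)
    col_rows: dict[int, set[int]] = {}
    for i, row in rows.items():
        for j in row:
            col_rows.setdefault(j, set()).add(i)

    ops: list[RowOperation] = []
    unused_rows = set(range(n_rows))
    pivots: list[tuple[int, int]] = []   # (row, col) in elimination order
    pivot_col_set: set[int] = set()
    forced: list[int] = []

    def available_rows(col: int) -> list[int]:
        s = col_rows.get(col)
        return [r for r in s if r in unused_rows] if s else []

    def eliminate_at(pr: int, pc: int) -> None:
        val = rows[pr][pc]
        if val != 1:
            f = _ONE / val
            ops.append(RowOperation("scale", pr, factor=f))
            prow = rows[pr]
            for j in list(prow):
                prow[j] = prow[j] * f  # scaling never zeroes an entry
        prow = rows[pr]
        targets = sorted(r for r in col_rows.get(pc, ()) if r != pr)
        for r in targets:
            f = -rows[r][pc]
            ops.append(RowOperation("add_multiple", r, pr, f))
            trow = rows.setdefault(r, {})
            for j, v in prow.items():
                s = trow.get(j, _ZERO) + f * v
                if s:
                    if j not in trow:
                        col_rows.setdefault(j, set()).add(r)
                    trow[j] = s
                else:
                    if j in trow:
                        del trow[j]
                        col_rows[j].discard(r)
            if not trow:
                del rows[r]

    while True:
        choice: tuple[int, int] | None = None
        # 1. preferred columns, in preference order
        for c in preferred:
            if c in pivot_col_set:
                continue
            cand = available_rows(c)
            if cand:
                pr = min(cand, key=lambda r: (len(rows[r]), r))
                choice = (pr, c)
                break
        was_forced = False
        if choice is None:
            # 2. Markowitz over admissible columns
            best = None
            for c, rs in col_rows.items():
                if c in forbidden or c in pivot_col_set:
                    continue
                cnt = 0
                for r in rs:
                    if r in unused_rows:
                        cnt += 1
                if not cnt:
                    continue
                for r in rs:
                    if r not in unused_rows:
                        continue
                    score = (len(rows[r]) - 1) * (cnt - 1)
                    key = (score, c, r)
                    if best is None or key < best:
                        best = key
            if best is not None:
                choice = (best[2], best[1])
        if choice is None and forbidden:
            # 3. fallback: forbidden columns must become pivots
            best = None
            for c in sorted(forbidden):
                if c in pivot_col_set:
                    continue
                cand = available_rows(c)
                cnt = len(cand)
                for r in cand:
                    score = (len(rows[r]) - 1) * (cnt - 1)
                    key = (score, c, r)
                    if best is None or key < best:
                        best = key
            if best is not None:
                choice = (best[2], best[1])
                was_forced = True
        if choice is None:
            break
        pr, pc = choice
        eliminate_at(pr, pc)
        unused_rows.discard(pr)
        pivots.append((pr, pc))
        pivot_col_set.add(pc)
        if was_forced:
            forced.append(pc)

    # reorder rows into staircase form: pivot rows first, ascending by
    # pivot column, then the all-zero rows in ascending original position
    pivots.sort(key=lambda rc: rc[1])
    order = [pr for pr, _ in pivots] + sorted(unused_rows)
    current = list(range(n_rows))  # current[k] = original row now at slot k
    slot_of = {r: k for k, r in enumerate(current)}
    for target_slot in range(n_rows):
        wanted = order[target_slot]
        cur_slot = slot_of[wanted]
        if cur_slot != target_slot:
            other = current[target_slot]
            ops.append(RowOperation("swap", target_slot, cur_slot))
            _apply_op(rows, RowOperation("swap", target_slot, cur_slot))
            current[target_slot], current[cur_slot] = wanted, other
            slot_of[wanted], slot_of[other] = target_slot, cur_slot

    pivot_columns = [pc for _, pc in pivots]
    free_columns = [c for c in range(n_cols) if c not in pivot_col_set]
    return EliminationResult(
        echelon=work,
        pivot_columns=pivot_columns,
        free_columns=free_columns,
        row_ops=ops,
        rank=len(pivot_columns),
        forced_pivots=forced,
    )


# -- MatrixMarket I/O --------------------------------------------------------
#
# Coordinate format with a "rational" field: each data line is
# "row col p/q" (1-based indices, exact fraction).  Standard MatrixMarket
# readers do not define a rational field; this dialect is documented in the
# README and is read back losslessly by read_mtx.

def write_mtx(matrix: RationalSparseMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("%%MatrixMarket matrix coordinate rational general\n")
        fh.write(f"{matrix.n_rows} {matrix.n_cols} {matrix.nnz}\n")
        for i, j, v in matrix.items():
            fh.write(f"{i + 1} {j + 1} {v.numerator}/{v.denominator}\n")


def read_mtx(path) -> RationalSparseMatrix:
    with open(path) as fh:
        header = fh.readline()
        if "matrix" not in header or "coordinate" not in header:
            raise ValueError(f"not a coordinate MatrixMarket file: {header!r}")
        line = fh.readline()
        while line.startswith("%"):
            line = fh.readline()
        n_rows, n_cols, nnz = (int(t) for t in line.split())
        m = RationalSparseMatrix(n_rows, n_cols)
        for _ in range(nnz):
            i, j, val = fh.readline().split()
            m[int(i) - 1, int(j) - 1] = Fraction(val)
        return m
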