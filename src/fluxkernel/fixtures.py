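"""Synthetic networks and matrices with known answers.

Everything here is generated programmatically so the whole package can be
exercised without downloading curated models:

* :func:`random_network` -- seeded random sparse integer stoichiometric
  matrices of known rank (hence known kernel dimension), built as a
  product of full-rank sparse factors the way genome-scale matrices look:
  mostly zeros, entries drawn from small integers such as 1 and -1;
* :func:`double_network` -- the scaling construction that stacks a matrix
  block-diagonally (two independent copies of the same metabolism) and
  shuffles the columns, which doubles the nullity and thins the sparsity
  as (1 + s) / 2 per doubling;
* :func:`toy_pathways` -- tiny hand-checked networks (a linear chain, a
  branch point, a two-compartment shuttle loop) shipped together with
  their hand-derived kernels for oracle tests.

All randomness is integer-only through :class:`random.Random` with an
explicit seed, so identical seeds give identical artifacts on every
platform.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

from .network_io import MetabolicNetwork, Reaction, Species
from .rational_sparse import RationalSparseMatrix

__all__ = ["FixtureSpec", "random_network", "double_network",
           "toy_pathways", "ToyPathway"]


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one random stoichiometric matrix."""

    n_species: int
    n_reactions: int
    target_rank: int
    coefficient_pool: tuple[int, ...] = (-2, -1, 1, 2)
    sparsity_target: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if self.target_rank > min(self.n_species, self.n_reactions):
            raise ValueError(
                f"target_rank {self.target_rank} exceeds "
                f"min(n_species, n_reactions) = "
                f"{min(self.n_species, self.n_reactions)}")
        if self.target_rank < 0 or self.n_species < 1 or self.n_reactions < 1:
            raise ValueError("dimensions must be positive, rank nonnegative")
        if not all(c for c in self.coefficient_pool):
            raise ValueError("coefficient pool must not contain zero")
        if not 0.0 <= self.sparsity_target < 1.0:
            raise ValueError("sparsity_target must be in [0, 1)")


def random_network(spec: FixtureSpec) -> tuple[RationalSparseMatrix, int]:
    """A random sparse integer matrix with rank exactly ``target_rank``.

    The matrix is ``A @ B`` with A (m x r) of full column rank and B
    (r x n) of full row rank, each an identity block plus sparse random
    small-integer fill, so the rank -- and with it the true nullity
    ``n - r`` -- is guaranteed by construction.  Row and column orders are
    shuffled so the identity blocks are not in a recognisable position.
    """
    m, n, r = spec.n_species, spec.n_reactions, spec.target_rank
    rng = random.Random(spec.seed)
    pool = list(spec.coefficient_pool)
    if r == 0:
        return RationalSparseMatrix(m, n), n

    density = max(0.0, 1.0 - spec.sparsity_target)
    # per-row extra nonzeros in the random fill, at least sparse-matrix thin
    fill = max(1, round(density * r))

    def sparse_row(width: int, k: int) -> dict[int, int]:
        cols = rng.sample(range(width), min(k, width))
        return {c: rng.choice(pool) for c in cols}

    a_rows: list[dict[int, int]] = [{i: rng.choice(pool)} for i in range(r)]
    a_rows += [sparse_row(r, fill) for _ in range(m - r)]
    rng.shuffle(a_rows)

    b_cols: list[dict[int, int]] = [{i: rng.choice(pool)} for i in range(r)]
    b_cols += [sparse_row(r, fill) for _ in range(n - r)]
    rng.shuffle(b_cols)

    out = RationalSparseMatrix(m, n)
    for i, arow in enumerate(a_rows):
        for j, bcol in enumerate(b_cols):
            s = 0
            for k, av in arow.items():
                bv = bcol.get(k)
                if bv is not None:
                    s += av * bv
            if s:
                out[i, j] = Fraction(s)
    return out, n - r


def double_network(matrix: RationalSparseMatrix, copies: int = 2,
                   seed: int = 0, shuffle: bool = True,
                   ) -> RationalSparseMatrix:
    """Block-diagonal replication with a seeded column shuffle.

    ``copies`` independent replicas of the same metabolism: rows and
    columns are stacked block-diagonally, then the columns are permuted
    (arbitrary column order is how real curated models arrive).  Nullity
    scales by ``copies``; for 2 copies the sparsity moves to
    ``(1 + s) / 2`` exactly.
    """
    if copies < 2:
        raise ValueError("copies must be >= 2")
    m, n = matrix.n_rows, matrix.n_cols
    out = RationalSparseMatrix(m * copies, n * copies)
    perm = list(range(n * copies))
    if shuffle:
        random.Random(seed).shuffle(perm)
    for k in range(copies):
        for i, j, v in matrix.items():
            out[k * m + i, perm[k * n + j]] = v
    return out


@dataclass(frozen=True)
class ToyPathway:
    """A hand-built network with its hand-derived kernel."""

    name: str
    network: MetabolicNetwork
    #: kernel of the *open* network matrix, columns = independent fluxes
    expected_kernel: RationalSparseMatrix
    expected_independent: tuple[int, ...]
    description: str = ""


def _net(species: Sequence[tuple[str, str, bool]],
         reactions: Sequence[tuple[str, dict, dict]]) -> MetabolicNetwork:
    sp = tuple(Species(id=i, compartment=c, is_external=e)
               for i, c, e in species)
    rx = tuple(Reaction(id=rid,
                        reactants={k: Fraction(v) for k, v in rea.items()},
                        products={k: Fraction(v) for k, v in pro.items()})
               for rid, rea, pro in reactions)
    return MetabolicNetwork(species=sp, reactions=rx)


def toy_pathways() -> list[ToyPathway]:
    """Small opened networks whose kernels were derived by hand."""
    toys = []

    # linear chain: ->A->B->C->   (already open: uptake and export present)
    # every flux equal: kernel = column of ones, any single flux independent
    chain = _net(
        [("A", "c", False), ("B", "c", False), ("C", "c", False)],
        [("v_in", {}, {"A": 1}),
         ("v1", {"A": 1}, {"B": 1}),
         ("v2", {"B": 1}, {"C": 1}),
         ("v_out", {"C": 1}, {})])
    k = RationalSparseMatrix.from_dense([[1], [1], [1], [1]])
    toys.append(ToyPathway(
        name="chain", network=chain, expected_kernel=k,
        expected_independent=(3,),
        description="A->B->C with uptake and export; one degree of freedom, "
                    "all fluxes equal"))

    # branch point: ->A, A->B->, A->C->
    # two degrees of freedom: the two branch fluxes
    branch = _net(
        [("A", "c", False), ("B", "c", False), ("C", "c", False)],
        [("v_in", {}, {"A": 1}),
         ("vAB", {"A": 1}, {"B": 1}),
         ("vAC", {"A": 1}, {"C": 1}),
         ("v_outB", {"B": 1}, {}),
         ("v_outC", {"C": 1}, {})])
    # independent: vAC (col 2) and v_outC? choose free = (vAC, v_outB)?
    # With plain elimination the free columns are the last two reactions:
    # v_outB (col 3) and v_outC (col 4); then
    #   v_in = v_outB + v_outC, vAB = v_outB, vAC = v_outC
    k = RationalSparseMatrix.from_dense(
        [[1, 1], [1, 0], [0, 1], [1, 0], [0, 1]])
    toys.append(ToyPathway(
        name="branch", network=branch, expected_kernel=k,
        expected_independent=(3, 4),
        description="A feeding two exits; the two export fluxes span the "
                    "steady-state space"))

    # two-compartment shuttle: G_c <-> G_m carried by paired antiport
    # reactions, mimicking the glutamate/oxoglutarate coupling: an internal
    # cycle flux exists on top of the throughput flux
    shuttle = _net(
        [("G_c", "c", False), ("G_m", "m", False)],
        [("v_in", {}, {"G_c": 1}),
         ("t_fwd", {"G_c": 1}, {"G_m": 1}),
         ("t_rev", {"G_m": 1}, {"G_c": 1}),
         ("v_out", {"G_m": 1}, {})])
    # free = (t_rev, v_out): v_in = v_out, t_fwd = t_rev + v_out
    k = RationalSparseMatrix.from_dense([[0, 1], [1, 1], [1, 0], [0, 1]])
    toys.append(ToyPathway(
        name="shuttle", network=shuttle, expected_kernel=k,
        expected_independent=(2, 3),
        description="two-compartment shuttle with a futile-cycle degree of "
                    "freedom (internal loop) plus throughput"))
    return toys
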