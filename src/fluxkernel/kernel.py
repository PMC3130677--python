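"""Steady-state kernel construction and flux relations.

At steady state the flux vector v of an m x n stoichiometric matrix N
satisfies N v = 0.  After Gauss-Jordan elimination the reactions split into
r *dependent* (pivot) and f = n - r *independent* (free) fluxes.  The
kernel matrix R (n x f) expresses every flux as an exact linear
combination of the independent ones:

    v = R v_indep,    N R = 0,    R[independent rows] = identity.

Because R comes from exact elimination its columns are sparse and align
with actual metabolic processes: the nonzero entries of one column mark
the sub-network of dependent reactions controlled by that independent
flux.  This module builds R, renders the per-dependent-flux relations,
substitutes measured values, and extracts those controlled sub-networks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

from .rational_sparse import (EliminationResult, RationalSparseMatrix,
                              _as_fraction)

__all__ = [
    "FluxPartition",
    "KernelResult",
    "FluxRelation",
    "SubnetworkDecomposition",
    "build_kernel",
    "flux_relations",
    "substitute",
    "identify_subnetworks",
    "solve_network",
    "format_relation",
    "write_relations_tsv",
]


@dataclass(frozen=True)
class FluxPartition:
    """Ordered dependent / independent flux index sets over n fluxes."""

    dependent: tuple[int, ...]
    independent: tuple[int, ...]

    def __post_init__(self):
        overlap = set(self.dependent) & set(self.independent)
        if overlap:
            raise ValueError(f"indices in both partitions: {sorted(overlap)}")

    @property
    def n(self) -> int:
        return len(self.dependent) + len(self.independent)

    @property
    def r(self) -> int:
        return len(self.dependent)

    @property
    def f(self) -> int:
        return len(self.independent)

    @property
    def permutation(self) -> tuple[int, ...]:
        """Column permutation placing dependent columns first."""
        return self.dependent + self.independent


@dataclass(frozen=True)
class KernelResult:
    """Kernel R (n x f) with its partition; source 'gje' or 'svd'."""

    partition: FluxPartition
    R: RationalSparseMatrix
    source: str = "gje"
    #: requested-independent columns that had to become dependent
    moved_independents: tuple[int, ...] = ()

    def __post_init__(self):
        if self.R.n_rows != self.partition.n or \
                self.R.n_cols != self.partition.f:
            raise ValueError(
                f"kernel shape {self.R.n_rows}x{self.R.n_cols} inconsistent "
                f"with partition (n={self.partition.n}, f={self.partition.f})")


def build_kernel(elimination: EliminationResult,
                 n_fluxes: int) -> KernelResult:
    """Compose the kernel from a reduced row-echelon form.

    For dependent flux d with pivot row k, the relation row is
    ``v_d = -sum_j echelon[k, free_j] * v_free_j``; independent rows carry
    the f x f identity.  Everything is exact.
    """
    ech = elimination.echelon
    if n_fluxes != ech.n_cols:
        raise ValueError(
            f"n_fluxes={n_fluxes} but elimination ran on {ech.n_cols} columns")
    free = elimination.free_columns
    f = len(free)
    col_of = {c: j for j, c in enumerate(free)}
    R = RationalSparseMatrix(n_fluxes, f)
    for j, c in enumerate(free):
        R[c, j] = 1
    for k, pivot_col in enumerate(elimination.pivot_columns):
        row = ech.rows.get(k, {})
        for c, v in row.items():
            if c == pivot_col:
                continue
            j = col_of.get(c)
            if j is None:
                raise ValueError(
                    f"echelon row {k} has a nonzero in non-free, non-pivot "
                    f"column {c}; not a reduced echelon form")
            R[pivot_col, j] = -v
    partition = FluxPartition(dependent=tuple(elimination.pivot_columns),
                              independent=tuple(free))
    return KernelResult(partition=partition, R=R, source="gje",
                        moved_independents=tuple(elimination.forced_pivots))


@dataclass(frozen=True)
class FluxRelation:
    """One dependent flux as an affine function of independent fluxes.

    ``v_dep = sum_j terms[j] * v_j + constant``; the constant is zero until
    measured values are substituted.
    """

    dependent_flux: str
    terms: Mapping[str, Fraction] = field(default_factory=dict)
    constant: Fraction = Fraction(0)

    @property
    def fully_determined(self) -> bool:
        return not self.terms


def flux_relations(kernel: KernelResult,
                   flux_ids: Sequence[str]) -> list[FluxRelation]:
    """One relation per dependent flux, in original reaction order."""
    if len(flux_ids) != kernel.partition.n:
        raise ValueError(
            f"{len(flux_ids)} flux ids for {kernel.partition.n} fluxes")
    indep_ids = [flux_ids[c] for c in kernel.partition.independent]
    relations = []
    for d in sorted(kernel.partition.dependent):
        row = kernel.R.rows.get(d, {})
        terms = {indep_ids[j]: v for j, v in sorted(row.items())}
        relations.append(FluxRelation(dependent_flux=flux_ids[d],
                                      terms=terms))
    return relations


def substitute(relations: Sequence[FluxRelation],
               assignments: Mapping[str, object],
               independent_ids: Iterable[str] | None = None,
               ) -> tuple[list[FluxRelation], set[str], set[str]]:
    """Fold measured independent-flux values into the relations.

    Returns ``(updated relations, fully_determined dependent ids,
    still_free independent ids)``.  Assigning a dependent flux id is an
    error: bounds on dependent fluxes belong to the constraint system, not
    to direct substitution.

    ``independent_ids`` fixes the universe of independent fluxes;  when
    omitted it is taken as every id appearing in a relation term (an
    independent flux whose kernel column is all zero on the dependent rows
    would then go unreported in ``still_free``).
    """
    dependents = {rel.dependent_flux for rel in relations}
    assigned = {}
    for fid, val in assignments.items():
        if fid in dependents:
            raise ValueError(
                f"{fid!r} is a dependent flux; constrain it via the "
                f"constraint system instead of substituting a value")
        assigned[fid] = _as_fraction(val)
    if independent_ids is None:
        universe = set()
        for rel in relations:
            universe |= set(rel.terms)
        universe |= set(assigned)
    else:
        universe = set(independent_ids)
        stray = set(assigned) - universe
        if stray:
            raise ValueError(f"assignments for unknown independent fluxes: "
                             f"{sorted(stray)}")

    updated = []
    fully = set()
    for rel in relations:
        terms = dict(rel.terms)
        constant = rel.constant
        for fid, val in assigned.items():
            if fid in terms:
                constant += terms.pop(fid) * val
        new = FluxRelation(dependent_flux=rel.dependent_flux,
                           terms=terms, constant=constant)
        if new.fully_determined:
            fully.add(new.dependent_flux)
        updated.append(new)
    still_free = universe - set(assigned)
    return updated, fully, still_free


@dataclass(frozen=True)
class SubnetworkDecomposition:
    """Dependent fluxes controlled by each independent flux.

    ``per_independent[j]`` is the set of dependent flux ids with a nonzero
    entry in independent flux j's kernel column; ``components`` merges the
    sets that share a dependent flux (connected components of the bipartite
    sharing graph), each component listing all its flux ids.
    """

    per_independent: Mapping[str, frozenset[str]]
    components: tuple[frozenset[str], ...]


def identify_subnetworks(kernel: KernelResult, flux_ids: Sequence[str],
                         restrict_to: Iterable[str] | None = None,
                         ) -> SubnetworkDecomposition:
    """Sub-networks controlled by (a subset of) the independent fluxes."""
    if kernel.source != "gje":
        raise ValueError(
            "sub-network decomposition requires the sparse identity-block "
            "kernel from exact elimination; an SVD kernel is dense and has "
            "no such interpretation")
    if len(flux_ids) != kernel.partition.n:
        raise ValueError(
            f"{len(flux_ids)} flux ids for {kernel.partition.n} fluxes")
    indep = list(kernel.partition.independent)
    indep_ids = [flux_ids[c] for c in indep]
    if restrict_to is not None:
        keep = set(restrict_to)
        unknown = keep - set(indep_ids)
        if unknown:
            raise ValueError(f"not independent fluxes: {sorted(unknown)}")
    else:
        keep = None
    dep_set = set(kernel.partition.dependent)

    per: dict[str, frozenset[str]] = {}
    for j, c in enumerate(indep):
        fid = indep_ids[j]
        if keep is not None and fid not in keep:
            continue
        deps = frozenset(flux_ids[i] for i in dep_set
                         if kernel.R[i, j] != 0)
        per[fid] = deps

    # union-find over independents sharing dependents
    parent = {fid: fid for fid in per}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    owner: dict[str, str] = {}
    for fid, deps in per.items():
        for d in deps:
            if d in owner:
                ra, rb = find(owner[d]), find(fid)
                if ra != rb:
                    parent[rb] = ra
            else:
                owner[d] = fid
    groups: dict[str, set[str]] = {}
    for fid in per:
        groups.setdefault(find(fid), set()).add(fid)
    components = tuple(sorted(
        (frozenset(set().union(*(per[fid] for fid in members)) | members)
         for members in groups.values()),
        key=lambda comp: sorted(comp)))
    return SubnetworkDecomposition(per_independent=per,
                                   components=components)


def solve_network(matrix: RationalSparseMatrix,
                  preferred_independent: Sequence[int] = (),
                  preferred_dependent: Sequence[int] = ()) -> KernelResult:
    """Eliminate a stoichiometric matrix and build its kernel.

    ``preferred_independent`` columns are kept out of the pivot set when
    the remaining columns can span the row space; infeasible requests are
    honoured as far as possible and the moved columns reported in
    ``moved_independents``.
    """
    from .rational_sparse import gauss_jordan_eliminate

    elim = gauss_jordan_eliminate(matrix,
                                  preferred_dependent=preferred_dependent,
                                  forbidden_pivot_cols=preferred_independent)
    return build_kernel(elim, matrix.n_cols)


# -- reporting ---------------------------------------------------------------

def format_relation(rel: FluxRelation, decimals: int = 6) -> str:
    """Human-readable relation, e.g. ``v_PGI = v_EX_glc - 2*v_ZWF``."""
    parts = []
    if rel.constant:
        parts.append(_fmt_coeff(rel.constant, lead=not parts))
    for fid, coeff in rel.terms.items():
        sign = "-" if coeff < 0 else ("+" if parts else "")
        mag = abs(coeff)
        factor = "" if mag == 1 else f"{_plain(mag)}*"
        sep = " " if parts else ""
        parts.append(f"{sign}{sep}{factor}v_{fid}".strip())
    rhs = " ".join(parts) if parts else "0"
    return f"v_{rel.dependent_flux} = {rhs}"


def _plain(q: Fraction) -> str:
    return str(q.numerator) if q.denominator == 1 else \
        f"{q.numerator}/{q.denominator}"


def _fmt_coeff(q: Fraction, lead: bool) -> str:
    s = _plain(abs(q))
    if q < 0:
        return f"-{s}" if lead else f"- {s}"
    return s if lead else f"+ {s}"


def write_relations_tsv(relations: Sequence[FluxRelation], path) -> None:
    """Long-format TSV: dependent_id, independent_id, coefficient.

    The constant of a (partially) substituted relation is written with the
    reserved independent id ``_constant``.  Rational values come with a
    decimal approximation alongside for readability.
    """
    with open(path, "w") as fh:
        fh.write("dependent_id\tindependent_id\tcoefficient\t"
                 "coefficient_decimal\n")
        for rel in relations:
            for fid, coeff in rel.terms.items():
                fh.write(f"{rel.dependent_flux}\t{fid}\t{_plain(coeff)}\t"
                         f"{float(coeff):.12g}\n")
            if rel.constant or not rel.terms:
                fh.write(f"{rel.dependent_flux}\t_constant\t"
                         f"{_plain(rel.constant)}\t"
                         f"{float(rel.constant):.12g}\n")


def subnetworks_to_json(decomp: SubnetworkDecomposition) -> str:
    return json.dumps({
        "per_independent": {fid: sorted(deps)
                            for fid, deps in decomp.per_independent.items()},
        "components": [sorted(c) for c in decomp.components],
    }, indent=2, sort_keys=True)
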