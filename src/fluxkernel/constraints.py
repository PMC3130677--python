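"""Constraints on independent fluxes and exact polytope reduction.

Measured values of independent fluxes (equalities ``G v_indep = b``) and
sign knowledge about dependent fluxes -- e.g. the net direction of
irreversible reactions -- translate, through the kernel rows
``v_dep = R_dep v_indep``, into a system of linear equalities and
inequalities on the independent fluxes alone.  That system describes a
convex polyhedron which is typically highly redundant.  Redundancy is
removed geometrically: enumerate the vertices and rays of the polyhedron
(V-representation), then enumerate the facets of that generator set
(H-representation).  The resulting inequality set is minimal and the
intermediate vertices/rays are kept, since they are directly useful for
volume-scanning applications.

Both enumeration directions run on one exact-rational double description
routine (:func:`extreme_rays`): vertex enumeration works on the
homogenization of the inequality system, facet enumeration on the dual
cone of the generators.  All arithmetic is over ``fractions.Fraction``;
no tolerance enters anywhere.  The intended problem sizes are the handful
of dimensions left after substituting measured fluxes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations
from typing import Iterable, Mapping, Sequence

from .kernel import KernelResult
from .rational_sparse import _as_fraction

__all__ = [
    "ConstraintSystem",
    "Polytope",
    "InfeasibleSystemError",
    "assemble_system",
    "reduce_system",
    "bounds_per_flux",
    "extreme_rays",
]

_ZERO = Fraction(0)
Vec = tuple[Fraction, ...]


class InfeasibleSystemError(ValueError):
    """The constraint system has no feasible point."""


# -- small dense exact linear algebra ---------------------------------------

def _dot(a: Sequence[Fraction], b: Sequence[Fraction]) -> Fraction:
    return sum((x * y for x, y in zip(a, b)), _ZERO)


def _rank(rows: Sequence[Sequence[Fraction]], dim: int) -> int:
    """Rank over Q by plain elimination (no pivot heuristics)."""
    work = [list(r) for r in rows if any(r)]
    rank = 0
    for col in range(dim):
        piv = next((i for i in range(rank, len(work)) if work[i][col]), None)
        if piv is None:
            continue
        work[rank], work[piv] = work[piv], work[rank]
        prow = work[rank]
        inv = 1 / prow[col]
        for i in range(len(work)):
            if i != rank and work[i][col]:
                f = work[i][col] * inv
                work[i] = [a - f * b for a, b in zip(work[i], prow)]
        rank += 1
        if rank == len(work):
            break
    return rank


def _normalize_ray(v: Sequence[Fraction]) -> Vec | None:
    """Scale by a positive rational to a primitive integer vector."""
    from math import gcd, lcm

    if not any(v):
        return None
    den = lcm(*(x.denominator for x in v)) if len(v) else 1
    ints = [int(x * den) for x in v]
    g = gcd(*(abs(i) for i in ints))
    return tuple(Fraction(i, g) for i in ints)


# -- double description core -------------------------------------------------

def extreme_rays(rows: Sequence[Sequence[Fraction]], dim: int,
                 ) -> tuple[list[Vec], list[Vec]]:
    """Minimal generators of the cone ``{x : row . x >= 0 for all rows}``.

    Returns ``(lineality_basis, rays)``: the cone equals the span of the
    lineality basis (both directions) plus nonnegative combinations of the
    rays, and the rays are extreme modulo the lineality space.

    Incremental double description: the lineality space starts as all of
    ``R^dim`` and shrinks as constraints arrive; once a constraint cuts the
    pointed part, new rays arise from algebraically adjacent
    positive/negative ray pairs (common tight set of rank
    ``dim - dim(lineality) - 2``), the exact-rational form of the classical
    algorithm.
    """
    lineality: list[list[Fraction]] = [
        [Fraction(int(i == j)) for j in range(dim)] for i in range(dim)]
    rays: list[list[Fraction]] = []
    processed: list[Vec] = []

    for raw in rows:
        m = tuple(_as_fraction(c) for c in raw)
        if len(m) != dim:
            raise ValueError(f"row of length {len(m)}, expected {dim}")
        if not any(m):
            continue
        interacting = next((l for l in lineality if _dot(m, l)), None)
        if interacting is not None:
            l0 = interacting if _dot(m, interacting) > 0 else \
                [-x for x in interacting]
            d0 = _dot(m, l0)
            lineality = [
                [a - (_dot(m, l) / d0) * b for a, b in zip(l, l0)]
                for l in lineality if l is not interacting]
            rays = [[a - (_dot(m, r) / d0) * b for a, b in zip(r, l0)]
                    for r in rays]
            rays.append(l0)
        else:
            scored = [(_dot(m, r), r) for r in rays]
            pos = [(d, r) for d, r in scored if d > 0]
            zero = [r for d, r in scored if d == 0]
            neg = [(d, r) for d, r in scored if d < 0]
            tight = {id(r): frozenset(
                i for i, p in enumerate(processed) if _dot(p, r) == 0)
                for _, r in scored}
            lin_dim = len(lineality)
            target = dim - lin_dim - 2
            new_rays = [r for _, r in pos] + zero
            for dp, rp in pos:
                for dn, rn in neg:
                    common = tight[id(rp)] & tight[id(rn)]
                    if target >= 0 and _rank(
                            [processed[i] for i in common], dim) != target:
                        continue
                    combo = [dp * b - dn * a for a, b in zip(rp, rn)]
                    new_rays.append(combo)
            rays = new_rays
        processed.append(m)

    # canonical form: bring the lineality basis to RREF, reduce every ray
    # modulo the lineality space (rays are only defined modulo it), then
    # dedupe and apply a final extremality filter
    lin_rref: list[list[Fraction]] = []
    lin_pivots: list[int] = []
    for l in lineality:
        v = list(l)
        for p, basis in zip(lin_pivots, lin_rref):
            if v[p]:
                f = v[p]
                v = [a - f * b for a, b in zip(v, basis)]
        piv = next((i for i, x in enumerate(v) if x), None)
        if piv is None:
            continue
        v = [x / v[piv] for x in v]
        for k, (p, basis) in enumerate(zip(lin_pivots, lin_rref)):
            if basis[piv]:
                f = basis[piv]
                lin_rref[k] = [a - f * b for a, b in zip(basis, v)]
        lin_rref.append(v)
        lin_pivots.append(piv)

    def mod_lineality(r: Sequence[Fraction]) -> list[Fraction]:
        v = list(r)
        for p, basis in zip(lin_pivots, lin_rref):
            if v[p]:
                f = v[p]
                v = [a - f * b for a, b in zip(v, basis)]
        return v

    lin_out = [n for n in (_normalize_ray(l) for l in lin_rref)
               if n is not None]
    lin_dim = len(lin_out)
    seen: set[Vec] = set()
    rays_out: list[Vec] = []
    for r in rays:
        n = _normalize_ray(mod_lineality(r))
        if n is None or n in seen:
            continue
        tight_rows = [p for p in processed if _dot(p, n) == 0]
        if _rank(tight_rows, dim) < dim - lin_dim - 1:
            continue  # not extreme modulo lineality
        seen.add(n)
        rays_out.append(n)
    return lin_out, rays_out


# -- polyhedron representations ----------------------------------------------

@dataclass(frozen=True)
class Polytope:
    """A convex polyhedron over the independent fluxes, both ways.

    ``vertices`` may contain a single interior anchor point instead of true
    vertices when the polyhedron has a lineality space (it then has no
    vertices at all); together with ``rays`` and ``lineality`` they always
    generate the set exactly.  ``h_rep`` rows are
    ``(coefficients, rhs, sense)`` meaning ``coeffs . x  sense  rhs`` with
    sense ``"ge"`` or ``"eq"``; after reduction it contains no redundant
    row.
    """

    dim: int
    vertices: tuple[Vec, ...]
    rays: tuple[Vec, ...]
    lineality: tuple[Vec, ...]
    h_rep: tuple[tuple[Vec, Fraction, str], ...]
    feasible: bool = True

    def to_json(self) -> dict:
        def vec(v):
            return [str(x) for x in v]

        return {
            "dim": self.dim,
            "feasible": self.feasible,
            "vertices": [vec(v) for v in self.vertices],
            "rays": [vec(v) for v in self.rays],
            "lineality": [vec(v) for v in self.lineality],
            "h_rep": [{"coefficients": vec(a), "rhs": str(b), "sense": s}
                      for a, b, s in self.h_rep],
        }


def _h_to_v(ineqs: Sequence[tuple[Vec, Fraction]], dim: int,
            ) -> tuple[list[Vec], list[Vec], list[Vec], bool]:
    """Vertex enumeration for ``{x : a . x >= rhs}`` systems.

    Homogenize over (x, t): each inequality becomes ``a . x - rhs t >= 0``
    plus ``t >= 0``; generators with positive t are points (vertices, or a
    single anchor when lineality is present), generators with t = 0 are
    recession directions.
    """
    rows = [tuple(a) + (-rhs,) for a, rhs in ineqs]
    rows.append(tuple([_ZERO] * dim) + (Fraction(1),))
    lin, rays = extreme_rays(rows, dim + 1)
    # lineality vectors are tight on t >= 0, so their t component is 0
    points: list[Vec] = []
    directions: list[Vec] = []
    for r in rays:
        t = r[dim]
        if t > 0:
            points.append(tuple(x / t for x in r[:dim]))
        elif any(r[:dim]):
            directions.append(r[:dim])
    lineality = [l[:dim] for l in lin if any(l[:dim])]
    feasible = bool(points)
    return points, directions, lineality, feasible


def _v_to_h(points: Sequence[Vec], rays: Sequence[Vec],
            lineality: Sequence[Vec], dim: int,
            ) -> list[tuple[Vec, Fraction, str]]:
    """Facet enumeration of ``conv(points) + cone(rays) + span(lineality)``.

    The H-representation rows are the extreme rays of the dual cone
    ``{(a, c) : a . p + c >= 0, a . r >= 0, a . l = 0}``; lineality of the
    dual cone yields the affine-hull equalities.
    """
    rows: list[Vec] = [tuple(p) + (Fraction(1),) for p in points]
    rows += [tuple(r) + (_ZERO,) for r in rays]
    for l in lineality:
        rows.append(tuple(l) + (_ZERO,))
        rows.append(tuple(-x for x in l) + (_ZERO,))
    lin, extr = extreme_rays(rows, dim + 1)
    h: list[tuple[Vec, Fraction, str]] = []
    for w in lin:
        a, c = w[:dim], w[dim]
        if any(a):
            h.append((a, -c, "eq"))
    for w in extr:
        a, c = w[:dim], w[dim]
        if any(a):
            h.append((a, -c, "ge"))
    return h


# -- the constraint system ---------------------------------------------------

@dataclass(frozen=True)
class ConstraintSystem:
    """Equalities and inequalities on the independent fluxes.

    ``measured`` supplies the equality block (one row of G per measured
    independent flux, selecting that coordinate, with the measured value in
    b).  ``sign_constraints`` supplies the inequality block: for each
    dependent flux the selection matrix Q picks its kernel row R_dep and
    the sense requires the resulting combination of independent fluxes to
    be nonnegative or nonpositive.
    """

    independent_ids: tuple[str, ...]
    #: (coefficients over independents, rhs, sense) rows, sense eq/ge/le
    rows: tuple[tuple[Vec, Fraction, str], ...]
    n_equalities: int
    n_inequalities: int
    #: provenance of each inequality row: the constrained dependent flux id
    inequality_sources: tuple[str, ...] = ()

    @property
    def f(self) -> int:
        return len(self.independent_ids)


def assemble_system(kernel: KernelResult,
                    measured: Mapping[str, object],
                    sign_constraints: Mapping[str, str],
                    flux_ids: Sequence[str]) -> ConstraintSystem:
    """Build the constraint system from measured values and sign knowledge.

    ``measured`` maps independent flux ids to exact values;
    ``sign_constraints`` maps dependent flux ids to ``"nonnegative"`` or
    ``"nonpositive"`` (e.g. the known net direction of carbon-dioxide
    producing reactions).  Keys on the wrong side of the partition are
    rejected.
    """
    if len(flux_ids) != kernel.partition.n:
        raise ValueError(
            f"{len(flux_ids)} flux ids for {kernel.partition.n} fluxes")
    indep_idx = {flux_ids[c]: j
                 for j, c in enumerate(kernel.partition.independent)}
    dep_rows = {flux_ids[c]: c for c in kernel.partition.dependent}
    f = kernel.partition.f

    rows: list[tuple[Vec, Fraction, str]] = []
    for fid in measured:
        if fid not in indep_idx:
            kind = "a dependent flux" if fid in dep_rows else "unknown"
            raise ValueError(f"measured flux {fid!r} is {kind}; only "
                             f"independent fluxes can be measured directly")
    for fid, sign in sign_constraints.items():
        if fid not in dep_rows:
            kind = "an independent flux" if fid in indep_idx else "unknown"
            raise ValueError(f"sign-constrained flux {fid!r} is {kind}; "
                             f"sign constraints apply to dependent fluxes")
        if sign not in ("nonnegative", "nonpositive"):
            raise ValueError(f"unknown sign {sign!r} for {fid!r}")

    for fid, value in measured.items():
        coeffs = [_ZERO] * f
        coeffs[indep_idx[fid]] = Fraction(1)
        rows.append((tuple(coeffs), _as_fraction(value), "eq"))
    sources = []
    for fid, sign in sign_constraints.items():
        krow = kernel.R.rows.get(dep_rows[fid], {})
        coeffs = [_ZERO] * f
        for j, v in krow.items():
            coeffs[j] = v
        rows.append((tuple(coeffs), _ZERO,
                     "ge" if sign == "nonnegative" else "le"))
        sources.append(fid)
    indep_ids = tuple(flux_ids[c] for c in kernel.partition.independent)
    return ConstraintSystem(independent_ids=indep_ids, rows=tuple(rows),
                            n_equalities=len(measured),
                            n_inequalities=len(sign_constraints),
                            inequality_sources=tuple(sources))


def _empty_polytope(dim: int) -> Polytope:
    return Polytope(dim=dim, vertices=(), rays=(), lineality=(),
                    h_rep=((tuple([_ZERO] * dim), Fraction(1), "ge"),),
                    feasible=False)


def reduce_system(system: ConstraintSystem) -> Polytope:
    """Remove all redundancy from the constraint system.

    Equalities are eliminated by exact substitution (lowering the
    dimension), the remaining inequalities are vertex-enumerated, and the
    generators are facet-enumerated back in the full independent-flux
    space.  The result carries both the minimal H-representation and the
    V-representation.  An infeasible system yields an explicitly empty
    polytope, not an exception.
    """
    f = system.f
    if f < 1:
        raise ValueError("no independent fluxes to constrain")

    eq_rows = [(a, b) for a, b, s in system.rows if s == "eq"]
    ineq_rows = []
    for a, b, s in system.rows:
        if s == "ge":
            ineq_rows.append((a, b))
        elif s == "le":
            ineq_rows.append((tuple(-x for x in a), -b))

    # exact RREF of the equality block: pivot coordinates become affine
    # functions of the free coordinates
    aug = [list(a) + [b] for a, b in eq_rows]
    pivots: list[int] = []
    rank = 0
    for col in range(f):
        piv = next((i for i in range(rank, len(aug)) if aug[i][col]), None)
        if piv is None:
            continue
        aug[rank], aug[piv] = aug[piv], aug[rank]
        prow = aug[rank]
        inv = 1 / prow[col]
        aug[rank] = [x * inv for x in prow]
        prow = aug[rank]
        for i in range(len(aug)):
            if i != rank and aug[i][col]:
                fct = aug[i][col]
                aug[i] = [x - fct * y for x, y in zip(aug[i], prow)]
        pivots.append(col)
        rank += 1
    for i in range(rank, len(aug)):
        if aug[i][f]:  # 0 = nonzero
            return _empty_polytope(f)
    free = [c for c in range(f) if c not in pivots]
    d = len(free)

    # x_pivot = const - sum(coeff * y_free);  lift matrices for later
    # point lift: x = base + L y ; ray lift: x = L y
    base = [_ZERO] * f
    lift = [[_ZERO] * d for _ in range(f)]
    for j, c in enumerate(free):
        lift[c][j] = Fraction(1)
    for k, c in enumerate(pivots):
        base[c] = aug[k][f]
        for j, fc in enumerate(free):
            lift[c][j] = -aug[k][fc]

    # substitute into the inequalities
    red_ineqs: list[tuple[Vec, Fraction]] = []
    for a, b in ineq_rows:
        coeffs = [_dot(a, [lift[i][j] for i in range(f)]) for j in range(d)]
        rhs = b - _dot(a, base)
        if not any(coeffs):
            if rhs > 0:
                return _empty_polytope(f)
            continue
        red_ineqs.append((tuple(coeffs), rhs))

    if d == 0:
        pts, rays, lin, feasible = [tuple()], [], [], True
    else:
        pts, rays, lin, feasible = _h_to_v(red_ineqs, d)
    if not feasible:
        return _empty_polytope(f)

    def lift_point(y: Vec) -> Vec:
        return tuple(base[i] + _dot(lift[i], y) for i in range(f))

    def lift_dir(y: Vec) -> Vec:
        return tuple(_dot(lift[i], y) for i in range(f))

    vertices = tuple(lift_point(p) for p in pts)
    ray_vecs = tuple(v for v in (lift_dir(r) for r in rays) if any(v))
    lin_vecs = tuple(v for v in (lift_dir(l) for l in lin) if any(v))
    h = _v_to_h(vertices, ray_vecs, lin_vecs, f)
    return Polytope(dim=f, vertices=vertices, rays=ray_vecs,
                    lineality=lin_vecs, h_rep=tuple(h), feasible=True)


NEG_INF = float("-inf")
POS_INF = float("inf")


def bounds_per_flux(polytope: Polytope, flux_ids: Sequence[str],
                    ) -> dict[str, tuple]:
    """Per-coordinate extremes read off the V-representation.

    Returns ``{flux id: (lower, upper)}`` with exact rational bounds, or
    ``-inf`` / ``+inf`` where a ray or lineality direction makes the
    coordinate unbounded.  An empty polytope signals infeasibility.
    """
    if not polytope.feasible:
        raise InfeasibleSystemError(
            "the constraint system is infeasible: no steady-state flux "
            "distribution satisfies all measurements and sign constraints")
    if len(flux_ids) != polytope.dim:
        raise ValueError(f"{len(flux_ids)} ids for a {polytope.dim}-D "
                         f"polytope")
    out: dict[str, tuple] = {}
    for j, fid in enumerate(flux_ids):
        lo = min(v[j] for v in polytope.vertices)
        hi = max(v[j] for v in polytope.vertices)
        for r in polytope.rays:
            if r[j] > 0:
                hi = POS_INF
            elif r[j] < 0:
                lo = NEG_INF
        for l in polytope.lineality:
            if l[j]:
                lo, hi = NEG_INF, POS_INF
        out[fid] = (lo, hi)
    return out


def write_bounds_tsv(bounds: Mapping[str, tuple], path) -> None:
    def fmt(x):
        if x == NEG_INF:
            return "-inf"
        if x == POS_INF:
            return "+inf"
        q = _as_fraction(x)
        return f"{q.numerator}/{q.denominator}"

    with open(path, "w") as fh:
        fh.write("flux_id\tlower\tupper\tlower_decimal\tupper_decimal\n")
        for fid, (lo, hi) in bounds.items():
            lod = "-inf" if lo == NEG_INF else f"{float(lo):.12g}"
            hid = "+inf" if hi == POS_INF else f"{float(hi):.12g}"
            fh.write(f"{fid}\t{fmt(lo)}\t{fmt(hi)}\t{lod}\t{hid}\n")


def polytope_to_json(polytope: Polytope) -> str:
    return json.dumps(polytope.to_json(), indent=2, sort_keys=True)
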