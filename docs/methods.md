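# Methods

## Steady-state model and conventions

The package analyzes the linear steady-state condition `N ν = 0` for an
m × n stoichiometric matrix over exact rationals. With `r = rank(N)` and
`f = n − r`, elimination partitions the n reactions into r dependent
(pivot) and f independent (free) fluxes; the kernel `R` (n × f) carries
the identity on the independent rows and `−N₁⁻¹N₂` on the dependent rows,
so one *relation* is emitted per dependent flux and `r + f = n` holds on
every input by construction. Counts reported anywhere (relations,
independent fluxes) follow exactly this convention.

All coefficients are `fractions.Fraction`; no operation in the elimination,
kernel, substitution or polytope path ever rounds. Floating point appears
only in the SVD cross-check, which exists to be compared against the exact
result, and in decimal renderings of reports (always alongside the exact
`p/q`).

## Sparse exact Gauss–Jordan elimination

The working representation is a dict-of-dicts row map plus an incrementally
maintained column index; entries that become zero are deleted immediately,
so sparsity metrics always reflect the true nonzero structure.

Pivot selection, in priority order:

1. **Preferred dependent columns**, scanned in the caller's preference
   order on every round (elimination can re-populate a previously empty
   preferred column). Within the column, the candidate row with the fewest
   nonzeros wins; ties go to the smallest row index.
2. Otherwise a **Markowitz minimum-fill score**
   `(nnz(row) − 1) · (nnz(col) − 1)` over all admissible nonzero entries,
   ties broken by smallest column then smallest row index. This is the
   standard sparsity-preserving heuristic; it minimizes the worst-case
   fill of the step and, as a side effect, keeps rational coefficients
   short (the fixture suite asserts a 64-bit length ceiling as a
   regression guard against coefficient growth; observed values stay
   below 10 bits).
3. **Forbidden columns** (requested independent fluxes) are drawn on only
   when no admissible column has a nonzero left in the unused rows — i.e.
   when the requested independent set cannot remain linearly independent.
   Each such forced pivot is recorded and surfaced to the caller as a
   "moved" independent flux; the move set is minimal because the fallback
   fires one pivot at a time, only after everything admissible is
   exhausted.

Pivots are scaled to exactly 1 and eliminated above and below (full
Gauss–Jordan), and rows are finally swapped into staircase order
(ascending pivot column). Every scale/add/swap is recorded; replaying the
log on the original matrix reproduces the echelon form bit for bit, on an
identity it yields the transformation matrix, and on appended columns it
reduces the augmented system without re-eliminating — useful when adding
transport reactions during constraint work. The routine contains no
randomness: identical input and options give bit-identical output.

Note the reduced row-echelon form is canonical only once the pivot-column
*set* is fixed. The tests therefore check the default (Markowitz) result
for rank, exact conservation and subspace equality, and additionally run
the eliminator with natural column preference, where it must match a naive
dense leftmost-pivot oracle bit for bit, kernel included.

## SBML handling and network preprocessing

Parsing goes through python-libsbml (L2/L3). Stoichiometries are converted
to exact rationals via their shortest round-tripping decimal literal, so
`0.5` → 1/2 and `0.1` → 1/10 rather than the 53-bit binary artifact. A
species with `boundaryCondition="true"` is marked external, but an
explicit external list supplied to the opening step always takes
precedence — external status is never inferred from compartment names,
which are model-dialect-dependent.

Preprocessing, in a fixed documented order:

1. **Orphan removal.** Species appearing in no reaction's reactant or
   product list are dropped. Participation is judged on the raw sides, not
   the net coefficient, so a species cancelling to net zero within one
   reaction survives to step 2.
2. **Polymerization rule.** A species appearing on both sides of one
   reaction is removed from the reactant side — the product coefficient
   stays as written — and one boundary-transport reaction for it is
   appended (`EX_<id>`, coefficient −1, deterministic species order). When
   the two side coefficients differ the rewrite is logged, since it
   changes the net column. The operation is idempotent.

Opening rules: `open_by_degree` appends one `EX_` column per species of
participation degree 1 (after the originals, in species order);
`open_by_externals` deletes the external rows and flags — never drops —
reactions whose stoichiometry becomes empty. On linear chains the two
rules give kernels spanning the same flux values on the shared original
reactions, which the tests verify by exact rank comparison.

## SVD cross-validation

`numpy.linalg.svd` on the dense float image of N; singular values below
`max(m, n) · eps · σ_max` (configurable) delimit the nullspace, whose
dimension must equal the exact `f` or a consistency error is raised. The
orthonormal basis is rebased on the exact partition's independent rows,
`R_svd = V_ker V_indep⁻¹`; the condition number reported is
`σ_max/σ_min` of `V_indep`.

The maximal relative flux error is defined here as

```
ε_SVD = max_ij |R_svd[i,j] − R[i,j]| / max_ij |R[i,j]|
```

with the exact kernel as reference — a scale-invariant reading of
"maximal relative flux error"; this normalization is this package's
definition, stated rather than assumed universal. Principal angles between
the two kernels' column spaces use the sine-based formula for small
angles (the arccos route loses everything below ~1e−8). On the fixture
suite the observed ε_SVD stays below 1e−13 and
`log10 ε_SVD ≤ log10 cond(V_indep) + 2` holds, matching the rule of thumb
that the number of inaccurate digits tracks the condition number's order
of magnitude.

## Constraint reduction

Measured independent fluxes enter as equality rows; a sign constraint on a
dependent flux contributes its kernel row as an inequality (≥ 0 or ≤ 0).
Direction knowledge is always supplied by the user (config/TSV), never
inferred from reaction chemistry.

Equalities are eliminated by exact substitution *before* enumeration —
lower dimension, exactness preserved — rather than being fed in as paired
inequalities. The remaining inequality system is vertex-enumerated via its
homogenization, then the (lifted) generators are facet-enumerated, both by
one exact-rational **double description** routine: the lineality space
starts as the whole space and shrinks per constraint; once a constraint
cuts the pointed part, new rays come from algebraically adjacent
positive/negative pairs (common tight set of rank `dim − dim(lineality)
− 2`), and the output is canonicalized modulo the lineality space with a
final extremality filter (tight-set rank `dim − dim(lineality) − 1`).
Affine-hull equalities re-emerge as lineality of the dual cone, so the
reduced H-representation separates `eq` and `ge` rows and contains no
redundant row; the V-representation (vertices, rays, lineality basis) is
kept because coordinate bounds and volume scans read directly off it.
This backend is written for the low dimensions that remain after
substituting measurements (the tests exercise up to ~6-D); it is not tuned
for high-dimensional cones.

Degenerate cases have defined behavior: an infeasible system returns an
explicitly empty polytope (bounds extraction then raises a dedicated
error); an unconstrained system returns an anchor point plus a full
lineality basis (every bound ±∞); a polyhedron with lineality has no
vertices, so the single generator point kept is an anchor, which is
sufficient and exact for per-coordinate bounds. Per-flux bounds are read
from the V-representation: min/max over points, pushed to ±∞ by any ray or
lineality direction with a nonzero component.

## Synthetic data

The random generator emulates the structural signature of curated
stoichiometric matrices — high sparsity and small-integer entries (pool
{−2, −1, 1, 2}) — with *known* rank: the matrix is `A·B` with full-column-
rank A (m × r) and full-row-rank B (r × n), each an identity block plus
seeded sparse fill, rows and columns shuffled. Rank, and hence nullity,
is thereby guaranteed by construction, giving every fixture an exact
expected kernel dimension. Defaults: sparsity target 0.9 (suite uses
0.85 to keep small shapes non-trivial), integer-only randomness from
`random.Random(seed)` so artifacts are identical across platforms.

The doubling construction replicates a matrix block-diagonally (two
independent copies of the same metabolism) and applies a seeded column
shuffle, reproducing the arbitrary column order of real models; nullity
scales with the number of copies and sparsity follows (1 + s)/2 per
doubling, both asserted exactly.

What the generator does **not** emulate: biological degree distributions,
compartment structure, reaction reversibility patterns, or conserved
moieties of real reconstructions. Passing the suite therefore demonstrates
algorithmic correctness and exactness on realistic sparsity/coefficient
regimes, not biological validity of any particular model.

The shipped toy pathways (linear chain, branch point, two-compartment
shuttle with a futile-cycle degree of freedom) carry hand-derived kernels
and serve as end-to-end oracles down to the CLI.

## Problem sizes and runtime choices

The acceptance suite runs 200 seeded fixtures on a ladder of shapes from
4 × 6 up to 60 × 100 at 85% target sparsity; the doubling law is checked
on the first 40 (the doubled eliminations dominate cost). The same suite
is regenerated from scratch by `scripts/acceptance.py`, seeded entirely
from `--seed`. These sizes keep a full run in the tens of seconds while
covering two orders of magnitude in matrix area; the elimination itself
has been exercised well beyond them.

## Known limitations

- No flux-balance objectives, thermodynamic feasibility beyond signs, or
  elementary flux mode / extreme pathway enumeration.
- SBML kinetic laws, units, annotations and FBC bounds are ignored.
- The polytope backend targets few dimensions; genome-scale inequality
  systems should be pre-reduced by measuring more independent fluxes.
- The exact/SVD sparsity comparison counts exact float zeros in the SVD
  basis; structured matrices whose SVD basis contains representable exact
  zeros could narrow the reported gap.
- The curated yeast central-metabolism SBML model referenced by the
  example-network test is not redistributed; that test requires the file
  to be placed at `data/yeast_example.xml`.
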