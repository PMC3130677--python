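# fluxkernel

Exact steady-state flux analysis for metabolic networks: the kernel of a
stoichiometric matrix by **sparse exact-rational Gauss–Jordan elimination**,
with researcher-selectable independent fluxes, numerical SVD
cross-validation, and reduction of measurements plus irreversibility
knowledge to a minimal set of bounds on the independent fluxes.

## Who this is for

Anyone doing metabolic flux analysis (MFA) on stoichiometric models — from
toy pathways to genome-scale SBML reconstructions — who wants steady-state
flux relations that are *exact* (no floating-point round-off accumulated
over thousands of row operations) and *interpretable* (each basis vector of
the flux space is anchored to one independent flux and touches only the
sub-network that flux controls, instead of the dense eigenvectors an SVD
nullspace gives).

## The model

Mass balance around every metabolite gives, at steady state,

```
N ν = 0
```

where `N` is the m × n stoichiometric matrix (rows = species, columns =
reactions, negative = consumed, positive = produced) and `ν` the flux
vector. With `r = rank(N)`, a viable steady state is fixed by `f = n − r`
*independent* fluxes. Gauss–Jordan elimination over exact rationals brings
`N` to reduced row-echelon form; the pivot columns are the *dependent*
fluxes and the free columns the independent ones, and the kernel

```
ν = R ν_indep,     N R = 0,     R[independent rows] = I_f
```

is read directly off the echelon form. Because the elimination is exact
and sparsity-steered (a Markowitz minimum-fill pivot rule), `R` is sparse:
the nonzero entries of column j mark exactly the dependent fluxes that
independent flux j controls, and columns sharing dependents merge into
connected sub-networks of the metabolism. The researcher can request which
fluxes stay independent; if the request cannot form a coordinate system
the solver moves as few of them as possible and reports the moves.

The same kernel is computed numerically from the SVD `N = u σ vᵀ` (the
right singular vectors of the zero singular values, rebased on the same
independent fluxes as `R_svd = V_ker V_indep⁻¹`), giving a maximal relative
flux error `ε_SVD = max|R_svd − R| / max|R|` and the condition number of
`V_indep` — an independent check that the two routes describe the same
space, and a measurement of what floating point would have cost.

Measured independent fluxes (`G ν_indep = b`) and sign knowledge about
dependent fluxes (`Q R_dep ν_indep ≥ 0`) define a convex polyhedron over
the independent fluxes. Redundancy is removed exactly: vertex enumeration
of the inequality system, then facet enumeration of the generators, both
through one exact-rational double-description routine, leaving a minimal
H-representation plus the vertices and rays.

Closed models are opened either by appending a boundary-transport reaction
for every species of participation degree 1, or by deleting the rows of a
known external-species list; both leave the same steady states on the
shared reactions.

## Worked example

A branched pathway — uptake `v_in` splits at A into two exports:

```python
import fluxkernel as fk
toy = next(t for t in fk.toy_pathways() if t.name == "branch")
fk.write_sbml(toy.network, "branch.xml")
```

Solve with a measured export (`measured.tsv`: `v_outB<TAB>2`):

```
$ fluxkernel solve branch.xml --measured measured.tsv --out sol
$ cat sol/relations.txt
v_v_in = 2 + v_v_outC
v_vAB = 2
v_vAC = v_v_outC
```

The solver picked the two exports as independent fluxes; substituting the
measured `v_outB = 2` fully determines `vAB` (the report lists
`"fully_determined": ["vAB"]`, `"still_free": ["v_outC"]`). Adding
irreversibility of the two branches (`signs.tsv`: `vAB nonnegative`,
`vAC nonnegative`) and reducing:

```
$ fluxkernel constrain sol --measured measured.tsv --signs signs.tsv --out con
$ cat con/bounds.tsv
flux_id  lower  upper  lower_decimal  upper_decimal
v_outB   2/1    2/1    2              2
v_outC   0/1    +inf   0              +inf
```

Three raw constraints reduce to one facet (`v_outC ≥ 0`) and one equality:
the minimal bound set. The SVD cross-check on the same model prints

```
$ fluxkernel check branch.xml
{"condition": 1.414..., "epsilon_svd": 3.3e-16, "f": 2,
 "sparsity_gje": 0.4, "sparsity_svd": 0.0}
```

— the numerical kernel agrees to machine precision, and the exact kernel
is the sparser of the two.

Subcommands: `parse`, `solve`, `check`, `constrain`, `fixtures`, `run`
(full pipeline from a JSON config). `fluxkernel COMMAND --help` for
options.

## Matrix files

Kernels and stoichiometric matrices are written in MatrixMarket coordinate
layout with a `rational` field qualifier: data lines are
`row col p/q` (1-based). Standard MTX readers do not define a rational
field; `fluxkernel.read_mtx` round-trips it losslessly.

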