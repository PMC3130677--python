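"""SBML parsing and preprocessing of metabolic networks.

A metabolic network is a list of species (metabolites, possibly assigned to
compartments, possibly marked external) and a list of reactions whose
stoichiometric coefficients form the m x n matrix N: rows are species,
columns are reactions, negative entries consume, positive entries produce.
All coefficients are exact rationals.

Curated models ship in *closed* form, where every species is balanced
internally and the only steady state is the trivial one.  Two rules convert
a network to *open* form so non-trivial steady states exist:

* :func:`open_by_degree` -- append a boundary-transport (exchange) reaction
  for every species that participates in exactly one reaction;
* :func:`open_by_externals` -- delete the matrix rows of an explicitly
  supplied set of external species.

Both rules describe the same steady-state behaviour on the shared original
reactions.  Preprocessing (:func:`preprocess`) removes orphan species and
rewrites polymerization-style reactions where a species appears on both
sides, adding a boundary transport for it.

SBML reading/writing goes through python-libsbml.  Numeric stoichiometries
are converted to exact rationals via their shortest round-tripping decimal
literal, so "0.5" becomes 1/2 and "0.1" becomes 1/10.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

from .rational_sparse import RationalSparseMatrix, _as_fraction

__all__ = [
    "Species",
    "Reaction",
    "MetabolicNetwork",
    "NetworkError",
    "SBMLParseError",
    "parse_sbml",
    "write_sbml",
    "preprocess",
    "open_by_degree",
    "open_by_externals",
    "network_summary",
]

logger = logging.getLogger("fluxkernel")


class NetworkError(ValueError):
    """Invalid network structure or inconsistent identifiers."""


class SBMLParseError(NetworkError):
    """The SBML document could not be read."""


@dataclass(frozen=True)
class Species:
    id: str
    name: str = ""
    compartment: str = ""
    is_external: bool = False


@dataclass(frozen=True)
class Reaction:
    """One reaction column.

    ``reactants`` and ``products`` keep the two sides separately (needed by
    the polymerization rule); ``stoichiometry`` is the signed net map used
    to build the matrix column: products minus reactants.
    """

    id: str
    reversible: bool = True
    reactants: Mapping[str, Fraction] = field(default_factory=dict)
    products: Mapping[str, Fraction] = field(default_factory=dict)
    is_exchange: bool = False

    @property
    def stoichiometry(self) -> dict[str, Fraction]:
        stoich: dict[str, Fraction] = {}
        for sid, c in self.reactants.items():
            stoich[sid] = stoich.get(sid, Fraction(0)) - c
        for sid, c in self.products.items():
            s = stoich.get(sid, Fraction(0)) + c
            if s:
                stoich[sid] = s
            elif sid in stoich:
                del stoich[sid]
        return stoich


@dataclass(frozen=True)
class MetabolicNetwork:
    """Species, reactions and the implied stoichiometric matrix."""

    species: tuple[Species, ...]
    reactions: tuple[Reaction, ...]
    #: reactions whose stoichiometry became empty when external rows were
    #: removed (never dropped silently)
    empty_reactions: tuple[str, ...] = ()

    def __post_init__(self):
        ids = [s.id for s in self.species]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise NetworkError(f"duplicate species ids: {dupes}")
        known = set(ids)
        for rxn in self.reactions:
            undeclared = set(rxn.stoichiometry) - known
            if undeclared:
                raise NetworkError(
                    f"reaction {rxn.id!r} references undeclared species "
                    f"{sorted(undeclared)}")

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def species_index(self) -> dict[str, int]:
        return {s.id: i for i, s in enumerate(self.species)}

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def matrix(self) -> RationalSparseMatrix:
        idx = self.species_index
        m = RationalSparseMatrix(self.n_species, self.n_reactions)
        for j, rxn in enumerate(self.reactions):
            for sid, coeff in rxn.stoichiometry.items():
                m[idx[sid], j] = coeff
        return m

    def participation_degree(self) -> dict[str, int]:
        """Number of reactions each species appears in (nonzero net)."""
        deg = {s.id: 0 for s in self.species}
        for rxn in self.reactions:
            for sid in rxn.stoichiometry:
                deg[sid] += 1
        return deg


def _stoich_fraction(value: float) -> Fraction:
    return _as_fraction(value)


def parse_sbml(path) -> MetabolicNetwork:
    """Read an SBML (level 2 or 3) model into a :class:`MetabolicNetwork`.

    Species and reaction order follow document order.  A species carrying
    ``boundaryCondition="true"`` is marked external (an explicit external
    list supplied downstream takes precedence over this flag).
    """
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors() > 0:
        for k in range(doc.getNumErrors()):
            err = doc.getError(k)
            if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
                raise SBMLParseError(
                    f"{path}: {err.getCategoryAsString()} at line "
                    f"{err.getLine()}: {err.getMessage().strip()}")
    model = doc.getModel()
    if model is None:
        raise SBMLParseError(f"{path}: document contains no model")

    species = tuple(
        Species(id=sp.getId(), name=sp.getName() or "",
                compartment=sp.getCompartment() or "",
                is_external=bool(sp.getBoundaryCondition()))
        for sp in (model.getSpecies(i) for i in range(model.getNumSpecies()))
    )
    known = {s.id for s in species}

    reactions = []
    for i in range(model.getNumReactions()):
        rxn = model.getReaction(i)
        reactants: dict[str, Fraction] = {}
        products: dict[str, Fraction] = {}
        for side, out in ((rxn.getListOfReactants(), reactants),
                          (rxn.getListOfProducts(), products)):
            for ref in side:
                sid = ref.getSpecies()
                if sid not in known:
                    raise NetworkError(
                        f"reaction {rxn.getId()!r} references undeclared "
                        f"species {sid!r}")
                raw = ref.getStoichiometry()
                if raw != raw:  # NaN: SBML L3 default, means 1
                    raw = 1.0
                coeff = _stoich_fraction(raw)
                if coeff:
                    out[sid] = out.get(sid, Fraction(0)) + coeff
        reactions.append(Reaction(id=rxn.getId(),
                                  reversible=bool(rxn.getReversible()),
                                  reactants=reactants, products=products))
    return MetabolicNetwork(species=species, reactions=tuple(reactions))


def write_sbml(network: MetabolicNetwork, path) -> None:
    """Write the network as SBML L3V1; round-trips through parse_sbml."""
    import libsbml

    doc = libsbml.SBMLDocument(3, 1)
    model = doc.createModel()
    model.setId("fluxkernel_network")
    compartments = {s.compartment or "default" for s in network.species}
    for cid in sorted(compartments):
        comp = model.createCompartment()
        comp.setId(cid)
        comp.setConstant(True)
    for sp in network.species:
        s = model.createSpecies()
        s.setId(sp.id)
        if sp.name:
            s.setName(sp.name)
        s.setCompartment(sp.compartment or "default")
        s.setBoundaryCondition(sp.is_external)
        s.setHasOnlySubstanceUnits(False)
        s.setConstant(False)
    for rxn in network.reactions:
        r = model.createReaction()
        r.setId(rxn.id)
        r.setReversible(rxn.reversible)
        r.setFast(False)
        for sid, coeff in rxn.reactants.items():
            ref = r.createReactant()
            ref.setSpecies(sid)
            ref.setStoichiometry(float(coeff))
            ref.setConstant(True)
        for sid, coeff in rxn.products.items():
            ref = r.createProduct()
            ref.setSpecies(sid)
            ref.setStoichiometry(float(coeff))
            ref.setConstant(True)
    libsbml.writeSBMLToFile(doc, str(path))


def _exchange_reaction(species_id: str) -> Reaction:
    """Boundary transport exporting one unit of the species (column -1)."""
    return Reaction(id=f"EX_{species_id}", reversible=True,
                    reactants={species_id: Fraction(1)}, products={},
                    is_exchange=True)


def preprocess(network: MetabolicNetwork) -> MetabolicNetwork:
    """Orphan removal, then the polymerization rule.  Idempotent.

    1. Species appearing in no reaction's reactant or product list are
       dropped (orphans).
    2. A species appearing as both reactant and product of the same
       reaction (the polymerization pattern) is removed from that
       reaction's reactant side -- the product coefficient stays as
       written -- and one boundary-transport reaction for the species is
       appended.  When the two side coefficients differ the rewrite is
       logged, since it changes the net column entry.
    """
    # orphan removal first; participation is judged on the raw reactant /
    # product lists so a species cancelling to net zero (the polymerization
    # pattern) is kept for step 2
    used: set[str] = set()
    for rxn in network.reactions:
        used |= set(rxn.reactants) | set(rxn.products)
    species = tuple(s for s in network.species if s.id in used)

    # polymerization rewrite
    reactions: list[Reaction] = []
    poly_species: list[str] = []
    seen_poly: set[str] = set()
    for rxn in network.reactions:
        both = sorted(set(rxn.reactants) & set(rxn.products))
        if both:
            for sid in both:
                if rxn.reactants[sid] != rxn.products[sid]:
                    logger.warning(
                        "reaction %s: species %s has reactant coefficient %s "
                        "and product coefficient %s; reactant entry removed",
                        rxn.id, sid, rxn.reactants[sid], rxn.products[sid])
                if sid not in seen_poly:
                    seen_poly.add(sid)
                    poly_species.append(sid)
            reactants = {s: c for s, c in rxn.reactants.items()
                         if s not in rxn.products}
            rxn = replace(rxn, reactants=reactants)
        reactions.append(rxn)
    existing = {r.id for r in reactions}
    for sid in poly_species:
        ex = _exchange_reaction(sid)
        if ex.id not in existing:
            reactions.append(ex)
    return MetabolicNetwork(species=species, reactions=tuple(reactions),
                            empty_reactions=network.empty_reactions)


def open_by_degree(network: MetabolicNetwork) -> MetabolicNetwork:
    """Append one exchange reaction per species of participation degree 1.

    Exchange columns are appended after all original reactions, in species
    order, leaving the original columns untouched.
    """
    deg = network.participation_degree()
    existing = {r.id for r in network.reactions}
    new = [
        _exchange_reaction(s.id) for s in network.species
        if deg[s.id] == 1 and f"EX_{s.id}" not in existing
    ]
    return MetabolicNetwork(species=network.species,
                            reactions=network.reactions + tuple(new),
                            empty_reactions=network.empty_reactions)


def open_by_externals(network: MetabolicNetwork,
                      external_ids: Iterable[str]) -> MetabolicNetwork:
    """Delete the rows of the given external species; columns unchanged.

    Reactions whose stoichiometry becomes empty are recorded in
    ``empty_reactions`` rather than silently dropped.
    """
    ext = set(external_ids)
    known = {s.id for s in network.species}
    unknown = sorted(ext - known)
    if unknown:
        raise NetworkError(f"unknown external species ids: {unknown}")
    species = tuple(s for s in network.species if s.id not in ext)
    reactions = []
    emptied = list(network.empty_reactions)
    for rxn in network.reactions:
        reactants = {s: c for s, c in rxn.reactants.items() if s not in ext}
        products = {s: c for s, c in rxn.products.items() if s not in ext}
        new = replace(rxn, reactants=reactants, products=products)
        if not new.stoichiometry and rxn.stoichiometry:
            emptied.append(rxn.id)
        reactions.append(new)
    return MetabolicNetwork(species=species, reactions=tuple(reactions),
                            empty_reactions=tuple(emptied))


def network_summary(network: MetabolicNetwork) -> dict:
    """Counts and sparsity, serializable as JSON."""
    from .rational_sparse import sparsity

    matrix = network.matrix
    by_comp: dict[str, int] = {}
    for s in network.species:
        by_comp[s.compartment or "default"] = \
            by_comp.get(s.compartment or "default", 0) + 1
    return {
        "n_species": network.n_species,
        "n_reactions": network.n_reactions,
        "n_external": sum(s.is_external for s in network.species),
        "n_exchange_reactions": sum(r.is_exchange for r in network.reactions),
        "species_per_compartment": by_comp,
        "nnz": matrix.nnz,
        "sparsity": float(sparsity(matrix)) if matrix.n_rows and
        matrix.n_cols else None,
        "empty_reactions": list(network.empty_reactions),
    }


def write_tables(network: MetabolicNetwork, species_path, reactions_path) -> None:
    """Species and reaction tables as TSV."""
    with open(species_path, "w") as fh:
        fh.write("species_id\tname\tcompartment\tis_external\n")
        for s in network.species:
            fh.write(f"{s.id}\t{s.name}\t{s.compartment}\t"
                     f"{int(s.is_external)}\n")
    with open(reactions_path, "w") as fh:
        fh.write("reaction_id\treversible\tis_exchange\tstoichiometry\n")
        for r in network.reactions:
            stoich = ";".join(f"{sid}:{coeff}" for sid, coeff in
                              sorted(r.stoichiometry.items()))
            fh.write(f"{r.id}\t{int(r.reversible)}\t{int(r.is_exchange)}\t"
                     f"{stoich}\n")
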