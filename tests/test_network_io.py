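"""SBML parsing, preprocessing, and network opening rules."""

from fractions import Fraction

import pytest

from fluxkernel import (MetabolicNetwork, NetworkError, Reaction,
                        SBMLParseError, Species, open_by_degree,
                        open_by_externals, parse_sbml, preprocess,
                        solve_network, write_sbml)
from conftest import same_span

F = Fraction


SBML_TEMPLATE = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core" level="3" version="1">
  <model id="toy">
    <listOfCompartments>
      <compartment id="c" constant="true"/>
    </listOfCompartments>
    <listOfSpecies>
      {species}
    </listOfSpecies>
    <listOfReactions>
      {reactions}
    </listOfReactions>
  </model>
</sbml>
"""


def sbml_doc(species: str, reactions: str) -> str:
    return SBML_TEMPLATE.format(species=species, reactions=reactions)


def species_xml(sid: str, boundary: bool = False) -> str:
    return (f'<species id="{sid}" compartment="c" constant="false" '
            f'hasOnlySubstanceUnits="false" '
            f'boundaryCondition="{"true" if boundary else "false"}"/>')


def reaction_xml(rid: str, reactants: dict, products: dict,
                 reversible: bool = True) -> str:
    def refs(side):
        return "".join(
            f'<speciesReference species="{s}" stoichiometry="{c}" '
            f'constant="true"/>' for s, c in side.items())

    parts = [f'<reaction id="{rid}" reversible='
             f'"{"true" if reversible else "false"}" fast="false">']
    if reactants:
        parts.append(f"<listOfReactants>{refs(reactants)}</listOfReactants>")
    if products:
        parts.append(f"<listOfProducts>{refs(products)}</listOfProducts>")
    parts.append("</reaction>")
    return "".join(parts)


@pytest.fixture
def write_doc(tmp_path):
    def _write(text, name="model.xml"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write


class TestParse:
    def test_sign_convention_2a_to_b(self, write_doc):
        doc = sbml_doc(species_xml("A") + species_xml("B"),
                       reaction_xml("r1", {"A": 2}, {"B": 1}))
        net = parse_sbml(write_doc(doc))
        m = net.matrix
        assert m[0, 0] == F(-2) and m[1, 0] == F(1)

    def test_decimal_literal_becomes_exact_fraction(self, write_doc):
        doc = sbml_doc(species_xml("A") + species_xml("B"),
                       reaction_xml("r1", {"A": "0.5"}, {"B": "0.1"}))
        net = parse_sbml(write_doc(doc))
        assert net.reactions[0].reactants["A"] == F(1, 2)
        assert net.reactions[0].products["B"] == F(1, 10)

    def test_document_order_preserved(self, write_doc):
        doc = sbml_doc(
            species_xml("Z") + species_xml("A") + species_xml("M"),
            reaction_xml("r2", {"Z": 1}, {"A": 1})
            + reaction_xml("r1", {"A": 1}, {"M": 1}))
        net = parse_sbml(write_doc(doc))
        assert [s.id for s in net.species] == ["Z", "A", "M"]
        assert net.reaction_ids == ["r2", "r1"]

    def test_boundary_condition_marks_external(self, write_doc):
        doc = sbml_doc(species_xml("A", boundary=True) + species_xml("B"),
                       reaction_xml("r1", {"A": 1}, {"B": 1}))
        net = parse_sbml(write_doc(doc))
        assert net.species[0].is_external and not net.species[1].is_external

    def test_malformed_xml_raises_parse_error(self, write_doc):
        with pytest.raises(SBMLParseError):
            parse_sbml(write_doc("<sbml><model></sbml>"))

    def test_undeclared_species_rejected(self, write_doc):
        doc = sbml_doc(species_xml("A"),
                       reaction_xml("r1", {"A": 1}, {"GHOST": 1}))
        with pytest.raises(NetworkError, match="GHOST"):
            parse_sbml(write_doc(doc))


def _net(species, reactions):
    return MetabolicNetwork(
        species=tuple(Species(id=s) for s in species),
        reactions=tuple(
            Reaction(id=rid,
                     reactants={k: F(v) for k, v in rea.items()},
                     products={k: F(v) for k, v in pro.items()})
            for rid, rea, pro in reactions))


class TestPreprocess:
    def test_orphan_species_removed(self):
        net = _net(["A", "B", "LONELY"], [("r1", {"A": 1}, {"B": 1})])
        out = preprocess(net)
        assert [s.id for s in out.species] == ["A", "B"]

    def test_polymerization_species_moved_to_boundary(self):
        # A + X -> A + B: A leaves the reactant side, EX_A is appended
        net = _net(["A", "X", "B"],
                   [("r1", {"A": 1, "X": 1}, {"A": 1, "B": 1})])
        out = preprocess(net)
        assert out.n_reactions == 2
        assert "A" not in out.reactions[0].reactants
        assert out.reactions[0].products["A"] == 1
        ex = out.reactions[1]
        assert ex.id == "EX_A" and ex.is_exchange
        assert ex.stoichiometry == {"A": F(-1)}

    def test_idempotent(self):
        net = _net(["A", "X", "B", "LONELY"],
                   [("r1", {"A": 1, "X": 1}, {"A": 1, "B": 1})])
        once = preprocess(net)
        twice = preprocess(once)
        assert twice.matrix == once.matrix
        assert twice.reaction_ids == once.reaction_ids


class TestOpening:
    def test_degree_rule_on_single_reaction(self):
        net = _net(["A", "B"], [("r1", {"A": 1}, {"B": 1})])
        out = open_by_degree(net)
        assert out.n_reactions == 3
        assert out.reaction_ids == ["r1", "EX_A", "EX_B"]
        assert out.matrix[0, 1] == F(-1) and out.matrix[1, 2] == F(-1)

    def test_degree_rule_noop_when_all_species_shared(self):
        net = _net(["A", "B"], [("r1", {"A": 1}, {"B": 1}),
                                ("r2", {"B": 1}, {"A": 1})])
        assert open_by_degree(net).n_reactions == 2

    def test_externals_rule_removes_rows_only(self):
        net = _net(["A", "B", "E"], [("r1", {"A": 1}, {"B": 1}),
                                     ("r2", {"B": 1}, {"E": 1})])
        out = open_by_externals(net, {"E"})
        assert [s.id for s in out.species] == ["A", "B"]
        assert out.n_reactions == 2
        assert out.matrix.n_rows == 2

    def test_externals_rule_empty_set_is_noop(self):
        net = _net(["A", "B"], [("r1", {"A": 1}, {"B": 1})])
        out = open_by_externals(net, set())
        assert out.matrix == net.matrix

    def test_all_species_external_flags_every_reaction(self):
        net = _net(["A", "B"], [("r1", {"A": 1}, {"B": 1})])
        out = open_by_externals(net, {"A", "B"})
        assert out.matrix.n_rows == 0
        assert out.empty_reactions == ("r1",)

    def test_unknown_external_ids_listed(self):
        net = _net(["A"], [("r1", {"A": 1}, {})])
        with pytest.raises(NetworkError, match="GHOST"):
            open_by_externals(net, {"GHOST"})

    @pytest.mark.parametrize("length", [3, 4, 6])
    def test_opening_rules_agree_on_linear_chains(self, length):
        """Both rules leave the same steady states on the original fluxes.

        A chain E0 -> M1 -> ... -> E_end with external endpoints: opening by
        degree appends transports, opening by externals deletes endpoint
        rows.  The reachable flux values on the shared original reactions
        must span the same space.
        """
        species = [f"M{i}" for i in range(length + 1)]
        reactions = [(f"v{i}", {species[i]: 1}, {species[i + 1]: 1})
                     for i in range(length)]
        net = _net(species, reactions)
        n_orig = net.n_reactions

        by_degree = open_by_degree(net)
        k_deg = solve_network(by_degree.matrix)
        by_ext = open_by_externals(net, {species[0], species[-1]})
        k_ext = solve_network(by_ext.matrix)

        def original_span(kernel):
            cols = []
            for j in range(kernel.R.n_cols):
                cols.append([kernel.R[i, j] for i in range(n_orig)])
            return cols

        assert same_span(original_span(k_deg), original_span(k_ext))


class TestRoundTrip:
    def test_write_then_parse_preserves_everything(self, tmp_path):
        net = _net(["A", "B", "C"],
                   [("r1", {"A": 2}, {"B": 1}),
                    ("r2", {"B": 1}, {"C": 1, "A": 0})])
        net = MetabolicNetwork(
            species=(Species(id="A", compartment="c"),
                     Species(id="B", compartment="c"),
                     Species(id="C", compartment="m", is_external=True)),
            reactions=net.reactions)
        path = tmp_path / "net.xml"
        write_sbml(net, path)
        back = parse_sbml(path)
        assert [s.id for s in back.species] == [s.id for s in net.species]
        assert [s.compartment for s in back.species] == ["c", "c", "m"]
        assert [s.is_external for s in back.species] == [False, False, True]
        assert back.reaction_ids == net.reaction_ids
        assert back.matrix == net.matrix
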