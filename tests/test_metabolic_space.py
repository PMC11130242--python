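"""Reaction-table parsing, structure resolution and simplification."""

import pytest

from promiskit import (
    EngineConfig,
    MetabolicSpace,
    Reaction,
    filter_unstructured,
    load_reaction_table,
    parse_equation,
    remove_cofactors,
    resolve_structures,
)

from conftest import met


@pytest.fixture()
def toy_table(tmp_path):
    path = tmp_path / "reactions.tsv"
    path.write_text(
        "id\tec\tequation\n"
        "R01296\t1.14.13.2\t4-Hydroxybenzoate + O2 + NADH + H(+) -> 3,4-Dihydroxybenzoate + H2O + NAD(+)\n"
        "RX1\t\tA + B -> C\n"
        "RX2\t1.1.1.1;2.2.2.2\tC <=> D\n"
        "RBAD\t\t->\n"
    )
    return path


def test_reaction_table_round_trip(toy_table):
    reactions, errors = load_reaction_table(toy_table)
    assert [r.id for r in reactions] == ["R01296", "RX1", "RX2"]
    r = reactions[0]
    assert len(r.substrates) == 4 and len(r.products) == 3
    assert r.substrates[0] == "4-Hydroxybenzoate"
    assert reactions[2].ec == ("1.1.1.1", "2.2.2.2")
    # the empty-equation row becomes an error record, not a silent drop
    assert len(errors) == 1 and errors[0].reaction_id == "RBAD"


@pytest.mark.parametrize(
    "equation, subs, prods",
    [
        ("A + B -> C + D", ["A", "B"], ["C", "D"]),
        ("A <=> B", ["A"], ["B"]),
        ("2 H2O + A -> B", ["H2O", "A"], ["B"]),  # coefficients ignored
    ],
)
def test_parse_equation(equation, subs, prods):
    assert parse_equation(equation) == (subs, prods)


def test_resolve_structures_precedence_and_unresolved():
    first = {"M1": "c1ccccc1O", "M2": "CCO"}
    second = {"M1": "CC(=O)O", "M3": "not a smiles"}
    resolved, unresolved = resolve_structures(["M1", "M2", "M3", "M4"], [first, second])
    # first source wins for M1: phenol, 7 heavy atoms, 6 in the ring
    m1 = resolved["M1"]
    assert m1.mol.GetNumAtoms() == 7
    assert sum(a.IsInRing() for a in m1.mol.GetAtoms()) == 6
    assert resolved["M2"].smiles == "CCO"
    assert "unparsable" in unresolved["M3"]
    assert "no structure" in unresolved["M4"]


def test_remove_cofactors_examples():
    cof = {"O2", "NADH", "H(+)", "H2O", "NAD(+)", "ATP", "ADP", "Pi"}
    r = Reaction(
        "R01296",
        (),
        ("4-Hydroxybenzoate", "O2", "NADH", "H(+)"),
        ("3,4-Dihydroxybenzoate", "H2O", "NAD(+)"),
    )
    kept, drop = remove_cofactors(r, cof)
    assert drop is None
    assert kept.substrates == ("4-Hydroxybenzoate",)
    assert kept.products == ("3,4-Dihydroxybenzoate",)

    only_cof = Reaction("R0", (), ("ATP",), ("ADP", "Pi"))
    kept, drop = remove_cofactors(only_cof, cof)
    assert kept is None and drop.stage == "cofactor_removal"

    untouched = Reaction("R1", (), ("A",), ("B",))
    assert remove_cofactors(untouched, cof)[0] == untouched


def test_filter_unstructured_rules():
    resolved = {"A": met("A", "CCO"), "B": met("B", "CC=O")}
    rxns = [
        Reaction("R1", (), ("A", "X"), ("B",)),
        Reaction("R2", (), ("X",), ("Y",)),
        Reaction("R3", (), ("A",), ("B",)),
    ]
    kept, dropped = filter_unstructured(rxns, resolved)
    assert [r.id for r in kept] == ["R1", "R3"]
    assert kept[0].substrates == ("A",)  # X removed
    assert [d.reaction_id for d in dropped] == ["R2"]


def test_simplification_idempotent_and_count_conserving(cfg):
    structures = {
        "A": "CCO",
        "B": "CC=O",
        "C": "c1ccccc1",
    }
    reactions = [
        Reaction("R1", (), ("A", "H2O"), ("B",), "A + H2O -> B"),
        Reaction("R2", (), ("H2O",), ("O2",), "H2O -> O2"),  # cofactors only
        Reaction("R3", (), ("C",), ("UNKNOWN",), "C -> UNKNOWN"),  # no structure
    ]
    space = MetabolicSpace.build(reactions, [structures], cfg)
    assert space.n_input_reactions == len(space.reactions) + len(space.dropped)
    assert {d.reaction_id for d in space.dropped} == {"R2", "R3"}
    assert all(d.reason for d in space.dropped)
    # idempotence: simplifying the simplified space changes nothing
    again = MetabolicSpace.build(space.reactions, [structures], cfg)
    assert [(r.id, r.substrates, r.products) for r in again.reactions] == [
        (r.id, r.substrates, r.products) for r in space.reactions
    ]
    assert not again.dropped


def test_metabolite_graph_and_invariants():
    m = met("phenol", "Oc1ccccc1")
    g = m.graph
    assert g.number_of_nodes() == 7
    assert sum(1 for _, d in g.nodes(data=True) if d["in_ring"]) == 6
    assert all(isinstance(d["charge"], int) for _, d in g.nodes(data=True))
    # canonical round trip
    assert met("again", m.smiles).smiles == m.smiles
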