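"""Reaction-centre detection, bond rearrangements and rule construction."""

import pytest
from rdkit import Chem

from promiskit import (
    EngineConfig,
    ReactantPair,
    RuleBuildError,
    build_rule,
    compute_mcs_alignment,
    detect_bond_rearrangements,
    find_reaction_centres,
    induce_rules,
    load_rules,
    predict_all,
    rule_for_pair,
    save_rules,
    type_codes,
)
from promiskit.fixtures import generate_synthetic_space

from conftest import met


def _aligned(cfg, s_smiles, p_smiles, **cfg_kwargs):
    config = cfg.replace(**cfg_kwargs) if cfg_kwargs else cfg
    s, p = met("S", s_smiles), met("P", p_smiles)
    al = compute_mcs_alignment(s.mol, p.mol, config)
    return s, p, al, config


def test_single_centre_hydroxylation(cfg):
    s, p, al, _ = _aligned(cfg, "OC(=O)c1ccc(O)cc1", "OC(=O)c1ccc(O)c(O)c1")
    centres = find_reaction_centres(al, type_codes(s.mol), type_codes(p.mol))
    assert len(centres) == 1
    (c,) = centres
    assert (c.substrate_type, c.product_type) == ("C8x", "C8y")
    assert c.substrate_atom == 8  # the ring CH ortho to the hydroxyl


def test_two_centres_for_amino_mutase_pair(cfg):
    s, p, al, _ = _aligned(cfg, "CC(C)CC(N)C(O)=O", "CC(C)C(N)CC(O)=O")
    centres = find_reaction_centres(al, type_codes(s.mol), type_codes(p.mol))
    assert len(centres) == 2
    assert {(c.substrate_type, c.product_type) for c in centres} == {("C1b", "C1c"), ("C1c", "C1b")}


def test_identity_has_no_centres_and_no_edits(cfg):
    s, p, al, _ = _aligned(cfg, "Oc1ccccc1", "Oc1ccccc1")
    assert find_reaction_centres(al, type_codes(s.mol), type_codes(p.mol)) == []
    assert detect_bond_rearrangements(al, s.mol, p.mol) == []
    with pytest.raises(RuleBuildError) as err:
        build_rule(ReactantPair("R", "S", "P", 1.0), s, p, al, cfg)
    assert err.value.reason == "no_transformation"


def test_bond_order_change_detected_as_edit(cfg):
    """Vinyl to ethyl: the double bond inside the MCS becomes single."""
    s, p, al, _ = _aligned(cfg, "C=Cc1ccccc1", "CCc1ccccc1")
    edits = detect_bond_rearrangements(al, s.mol, p.mol)
    assert len(edits) == 1
    (e,) = edits
    assert (e.action, e.old_order, e.new_order) == ("change", 2.0, 1.0)


def test_bond_edit_set_equals_symmetric_difference_oracle(cfg):
    """Enol/keto-like pair: edits must equal the symmetric difference of the
    mapped bond sets computed independently from the alignment."""
    s, p, al, _ = _aligned(cfg, "C=C(O)CC", "CC(=O)CC")
    edits = detect_bond_rearrangements(al, s.mol, p.mol)
    s2p = al.sub_to_prod
    sub_bonds = {
        tuple(sorted((b.GetBeginAtomIdx(), b.GetEndAtomIdx()))): b.GetBondTypeAsDouble()
        for b in s.mol.GetBonds()
        if b.GetBeginAtomIdx() in s2p and b.GetEndAtomIdx() in s2p
    }
    prod_bonds = {}
    p2s = al.prod_to_sub
    for b in p.mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i in p2s and j in p2s:
            prod_bonds[tuple(sorted((p2s[i], p2s[j])))] = b.GetBondTypeAsDouble()
    expected = {
        k for k in set(sub_bonds) | set(prod_bonds) if sub_bonds.get(k) != prod_bonds.get(k)
    }
    assert {e.sub_atoms for e in edits} == expected


def test_rule_units_and_fragments_for_worked_examples(builtin_rules):
    (r1,) = builtin_rules["R01296"]
    assert len(r1.units) == 1 and not r1.multi_centre
    (unit,) = r1.units
    assert unit.key.centre_type == "C8x" and unit.value.centre_type_product == "C8y"
    (frag,) = r1.fragments_added
    assert frag.elements == ("O",) and not r1.fragments_removed

    (r2,) = builtin_rules["R01091"]
    assert len(r2.units) == 2 and r2.multi_centre
    assert [u.label for u in r2.units] == ["R1", "R2"]
    assert len(r2.fragments_added) == len(r2.fragments_removed) == 1


def test_charge_only_difference_yields_charge_edit(cfg):
    """A pair differing only in a formal charge on a mapped oxygen produces
    an empty-fragment rule with a single charge edit (charge matching off in
    the MCS so the atom maps; charge tracking on)."""
    s, p, al, config = _aligned(
        cfg, "CC(=O)O", "CC(=O)[O-]", match_formal_charge=False
    )
    rule = build_rule(ReactantPair("R", "S", "P", 1.0), s, p, al, config)
    assert not rule.fragments_added and not rule.fragments_removed
    edits = [e for u in rule.units for e in u.value.charge_edits]
    assert len(edits) == 1 and edits[0].delta == -1
    # and the rule round-trips through prediction
    preds = predict_all(s, [rule], config)
    assert p.smiles in [x.product_smiles for x in preds]


def test_disconnected_fragment_is_ambiguous(cfg):
    """A substrate whose second component disappears entirely has no anchor
    for the removed fragment."""
    s, p, al, _ = _aligned(cfg, "CCO.[Na+]", "CCO", match_formal_charge=True)
    with pytest.raises(RuleBuildError) as err:
        build_rule(ReactantPair("R", "S", "P", 1.0), s, p, al, cfg)
    assert err.value.reason == "ambiguous_fragment"


def test_rule_serialization_bit_stable(tmp_path, builtin_space, cfg):
    rules, failures = induce_rules(builtin_space, cfg)
    assert not failures
    p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
    save_rules(rules, p1, cfg)
    loaded, config = load_rules(p1)
    save_rules(loaded, p2, config)
    assert p1.read_bytes() == p2.read_bytes()
    assert [r.rule_id for r in loaded] == [r.rule_id for r in rules]


def test_rule_building_deterministic(cfg):
    pair = ReactantPair("R01296", "S", "P", 1.0)
    mets = {"S": met("S", "OC(=O)c1ccc(O)cc1"), "P": met("P", "OC(=O)c1ccc(O)c(O)c1")}
    r1 = rule_for_pair(pair, mets, cfg)
    r2 = rule_for_pair(pair, mets, cfg)
    from promiskit.rule_builder import _rule_to_dict

    assert _rule_to_dict(r1) == _rule_to_dict(r2)


def test_self_recovery_round_trip_on_synthetic_rules(cfg):
    """The defining invariant: every successfully built rule regenerates its
    template product from its template substrate."""
    fs = generate_synthetic_space(12, seed=5)
    space = fs.build_space(cfg)
    rules, failures = induce_rules(space, cfg)
    assert not failures
    for rule in rules:
        sub = space.metabolites[rule.template_substrate_id]
        prod = space.metabolites[rule.template_product_id]
        preds = predict_all(sub, [rule], cfg)
        assert prod.smiles in [p.product_smiles for p in preds], rule.rule_id
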