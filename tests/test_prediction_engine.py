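"""Key matching, rule application and the prediction batch driver."""

import json

import pytest
from rdkit import Chem

from promiskit import (
    EngineConfig,
    ReactantPair,
    apply_rule,
    canonicalize_smiles,
    enumerate_query_sites,
    load_predictions_json,
    match_rule,
    predict_all,
    rule_for_pair,
    similarity_prefilter,
    write_predictions_json,
)

from conftest import met


@pytest.fixture(scope="module")
def fig3_rule(builtin_rules):
    (rule,) = builtin_rules["R01296"]
    return rule


def test_enumerate_query_sites_single_atom():
    (desc,) = enumerate_query_sites(met("W", "O").mol)
    assert desc.adjacent == ()


def test_enumerate_query_sites_ethanol_manual_oracle():
    """Ethanol descriptors must equal a hand-enumerated adjacency table."""
    sites = enumerate_query_sites(met("E", "CCO").mol)  # C0 C1 O2
    by_centre = {d.centre_type: d for d in sites}
    c1a = by_centre["C1a"]
    assert [(a.code, a.order) for a in c1a.adjacent] == [("C1b", 1.0)]
    assert c1a.adjacent[0].distant == (("O1a", 1.0, 0),)
    c1b = by_centre["C1b"]
    assert sorted((a.code, a.order) for a in c1b.adjacent) == [("C1a", 1.0), ("O1a", 1.0)]
    assert all(a.distant == () for a in c1b.adjacent)
    o1a = by_centre["O1a"]
    assert [(a.code, a.order) for a in o1a.adjacent] == [("C1b", 1.0)]
    assert o1a.adjacent[0].distant == (("C1a", 1.0, 0),)


def test_tyrosine_site_matches_fig3_key(fig3_rule):
    tyr = met("Tyr", "NC(Cc1ccc(O)cc1)C(O)=O")
    sites = enumerate_query_sites(tyr.mol)
    (unit,) = fig3_rule.units
    assert any(d == unit.key for d in sites)


def test_prefilter_thresholds(fig3_rule, cfg):
    sub = met("S", fig3_rule.substrate_smiles)
    assert similarity_prefilter(sub, fig3_rule, threshold=1.0, config=cfg)
    assert similarity_prefilter(met("W", "O"), fig3_rule, threshold=0.0, config=cfg)
    tyr = met("Tyr", "NC(Cc1ccc(O)cc1)C(O)=O")
    from promiskit import molecule_similarity

    expected = molecule_similarity(tyr.mol, Chem.MolFromSmiles(fig3_rule.substrate_smiles), cfg)
    assert similarity_prefilter(tyr, fig3_rule, 0.6, cfg) == (expected >= 0.6)


def test_self_match_covers_original_centre(fig3_rule, cfg):
    sub = met("S", fig3_rule.substrate_smiles)
    matches = match_rule(sub, fig3_rule, cfg)
    assert matches
    anchors = {u.anchor for u in fig3_rule.units}
    assert any(set(m.combined_map) >= anchors for m in matches)


def test_multi_centre_requires_all_keys(builtin_rules, cfg):
    (rule,) = builtin_rules["R01091"]  # 2 units
    assert len(rule.units) == 2
    # leucine matches both units; propane matches at most one
    assert match_rule(met("L", "CC(C)CC(N)C(O)=O"), rule, cfg)
    assert match_rule(met("X", "CCC"), rule, cfg) == []


def test_match_count_matches_embedding_oracle(fig3_rule, cfg):
    """p-cresol: match centres must equal brute-force embedding
    enumeration of the key ball."""
    from oracles import enumerate_key_embeddings
    from promiskit import type_codes

    query = met("pC", "Cc1ccc(O)cc1")
    matches = match_rule(query, fig3_rule, cfg)
    tmol = fig3_rule.substrate_mol()
    expected = enumerate_key_embeddings(
        tmol,
        list(fig3_rule.sub_codes),
        fig3_rule.units[0].anchor,
        query.mol,
        type_codes(query.mol),
    )
    assert {m.centre_atoms[0] for m in matches} == expected
    assert len(expected) == 2  # the two CH positions ortho to the hydroxyl


def test_apply_rule_tyrosine_gives_dopa(fig3_rule, cfg):
    tyr = met("Tyr", "NC(Cc1ccc(O)cc1)C(O)=O", name="L-Tyrosine")
    preds = predict_all(tyr, [fig3_rule], cfg)
    assert canonicalize_smiles("NC(Cc1ccc(O)c(O)c1)C(O)=O") in {p.product_smiles for p in preds}


def test_glucuronide_cleavage_two_product_outcome(builtin_space, builtin_rules, cfg):
    """The glucuronidase template predicts both the aglycone and glucuronic
    acid from the conjugate, with the split-off moiety as co-product."""
    rules = builtin_rules["GLCRD1"]
    query = builtin_space.metabolites["Phloretin-2'-O-glucuronide"]
    preds = predict_all(query, rules, cfg)
    products = {p.product_smiles for p in preds}
    assert builtin_space.metabolites["Phloretin"].smiles in products
    assert builtin_space.metabolites["Glucuronate"].smiles in products
    assert any(p.co_products for p in preds)


def test_amide_hydrolysis_products(builtin_space, builtin_rules, cfg):
    rules = builtin_rules["AMHYD1"]
    query = builtin_space.metabolites["4-Hydroxyhippurate"]
    products = {p.product_smiles for p in predict_all(query, rules, cfg)}
    assert builtin_space.metabolites["Glycine"].smiles in products
    assert builtin_space.metabolites["4-Hydroxybenzoate"].smiles in products


def test_duplicate_addition_guard_shared_fragment(cfg):
    """A two-centre ring-fusion rule (benzene -> naphthalene) shares one
    four-carbon fragment between its centres; the fragment must be added
    exactly once."""
    s = met("S", "c1ccccc1")
    p = met("P", "c1ccc2ccccc2c1")
    rule = rule_for_pair(ReactantPair("FUSE", "S", "P", 0.5), {"S": s, "P": p}, cfg)
    assert len(rule.units) == 2
    (frag,) = rule.fragments_added
    assert len(frag.atoms) == 4
    assert len(frag.attachments) == 2
    assert {a.unit_label for a in frag.attachments} == {"R1", "R2"}
    preds = predict_all(s, [rule], cfg)
    assert p.smiles in {x.product_smiles for x in preds}
    for x in preds:
        assert Chem.MolFromSmiles(x.product_smiles).GetNumAtoms() == 10


def test_prefilter_monotonicity(builtin_space, builtin_rules, cfg):
    """Raising the threshold never enlarges the prediction set."""
    rules = [r for rs in builtin_rules.values() for r in rs]
    query = met("pC", "Cc1ccc(O)cc1")
    previous = None
    for thr in (0.0, 0.3, 0.6, 0.9):
        preds = {
            (p.product_smiles, p.reaction_id)
            for p in predict_all(query, rules, cfg.replace(similarity_threshold=thr))
        }
        if previous is not None:
            assert preds <= previous
        previous = preds


def test_predict_all_empty_rules_and_dedup_order(fig3_rule, cfg):
    tyr = met("Tyr", "NC(Cc1ccc(O)cc1)C(O)=O")
    assert predict_all(tyr, [], cfg) == []
    preds = predict_all(tyr, [fig3_rule, fig3_rule], cfg)
    keys = [(p.product_smiles, p.reaction_id) for p in preds]
    assert len(keys) == len(set(keys))
    assert keys == sorted(keys)


def test_predictions_json_round_trip(tmp_path, fig3_rule, cfg):
    tyr = met("Tyr", "NC(Cc1ccc(O)cc1)C(O)=O", name="L-Tyrosine")
    preds = predict_all(tyr, [fig3_rule], cfg)
    path = tmp_path / "preds.json"
    write_predictions_json(preds, path)
    payload = load_predictions_json(path)
    assert len(payload["predictions"]) == len(preds)
    for rec, pred in zip(payload["predictions"], preds):
        assert rec["product"]["smiles"] == pred.product_smiles
        assert rec["template"]["reaction_id"] == pred.reaction_id
        assert rec["query"]["id"] == pred.query_id
        assert Chem.MolFromMolBlock(rec["product"]["molblock"]) is not None
    # empty list is valid too
    write_predictions_json([], tmp_path / "empty.json")
    assert load_predictions_json(tmp_path / "empty.json")["predictions"] == []


def test_exhaustive_driver_equivalence(builtin_space, builtin_rules, cfg):
    """predict_all must equal running apply_rule over every match of every
    prefilter-passing rule, up to dedup and ordering."""
    from promiskit.prediction_engine import PredictionError

    rules = [r for rs in builtin_rules.values() for r in rs]
    queries = [
        met("Tyr", "NC(Cc1ccc(O)cc1)C(O)=O"),
        met("pC", "Cc1ccc(O)cc1"),
        builtin_space.metabolites["4-Hydroxyhippurate"],
        builtin_space.metabolites["Phloretin-2'-O-glucuronide"],
        builtin_space.metabolites["L-Leucine"],
    ]
    for query in queries:
        expected = set()
        for rule in rules:
            if not similarity_prefilter(query, rule, config=cfg):
                continue
            for m in match_rule(query, rule, cfg):
                try:
                    pred = apply_rule(query, rule, m, cfg)
                except PredictionError:
                    continue
                expected.add((pred.product_smiles, pred.reaction_id))
        got = {(p.product_smiles, p.reaction_id) for p in predict_all(query, rules, cfg)}
        assert got == expected
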