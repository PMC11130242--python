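"""Induce a look-up rule from one substrate-product pair.

The aromatic hydroxylation 4-hydroxybenzoate -> 3,4-dihydroxybenzoate is
simplified (cofactors stripped), the two structures are aligned over their
maximum common substructure, and the atom whose KEGG atom type changes
becomes the reaction centre of the induced rule.
"""

from promiskit import EngineConfig, Metabolite, ReactantPair, rule_for_pair

cfg = EngineConfig()
substrate = Metabolite.from_smiles("4HB", "OC(=O)c1ccc(O)cc1", name="4-Hydroxybenzoate")
product = Metabolite.from_smiles("34DHB", "OC(=O)c1ccc(O)c(O)c1", name="3,4-Dihydroxybenzoate")

rule = rule_for_pair(
    ReactantPair("R01296", "4HB", "34DHB", similarity=0.77),
    {"4HB": substrate, "34DHB": product},
    cfg,
)

print(f"rule {rule.rule_id}: {len(rule.units)} unit(s), multi-centre={rule.multi_centre}")
for centre in rule.centres:
    print(
        f"  centre {centre.label}: substrate atom {centre.substrate_atom} "
        f"{centre.substrate_type} -> {centre.product_type}"
    )
unit = rule.units[0]
print(f"  key: centre {unit.key.centre_type}, adjacent {[(a.code, a.order) for a in unit.key.adjacent]}")
for frag in rule.fragments_added:
    print(f"  value: adds fragment {list(frag.elements)} at the centre")

# The single centre is an unsubstituted aromatic CH (C8x) that becomes a
# substituted aromatic carbon (C8y) by gaining one hydroxyl oxygen: the rule
# is "hydroxylate an aromatic CH whose radius-2 neighbourhood looks like the
# template's".
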