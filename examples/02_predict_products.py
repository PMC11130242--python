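"""Apply an induced rule to new query compounds.

The hydroxylation rule from example 01 transfers to any molecule presenting
the same radius-2 neighbourhood around an aromatic CH — the essence of
enzyme promiscuity prediction.  L-tyrosine passes the 0.6 Dice prefilter
against the template substrate and is hydroxylated ortho to its phenol
hydroxyl, giving 3,4-dihydroxy-L-phenylalanine (L-DOPA).
"""

from promiskit import EngineConfig, Metabolite, ReactantPair, predict_all, rule_for_pair

cfg = EngineConfig()
mets = {
    "4HB": Metabolite.from_smiles("4HB", "OC(=O)c1ccc(O)cc1"),
    "34DHB": Metabolite.from_smiles("34DHB", "OC(=O)c1ccc(O)c(O)c1"),
}
rule = rule_for_pair(ReactantPair("R01296", "4HB", "34DHB", 0.77), mets, cfg)

for qid, smiles in [
    ("L-Tyrosine", "NC(Cc1ccc(O)cc1)C(O)=O"),
    ("p-Cresol", "Cc1ccc(O)cc1"),
]:
    query = Metabolite.from_smiles(qid, smiles, name=qid)
    predictions = predict_all(query, [rule], cfg)
    print(f"{qid}:")
    for p in predictions:
        print(f"  -> {p.product_smiles}   (template {p.reaction_id}, centre atoms {p.centre_atoms})")
    if not predictions:
        print("  (no prediction: no key match or prefilter below threshold)")

# Each line is one putative metabolic product: the query's graph rewritten
# at the matched reaction centre exactly as the template reaction rewrote
# its substrate.
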