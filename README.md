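# promiskit

Rule-based prediction of enzyme-promiscuity products. `promiskit` induces
chemical-transformation rules ("look-up tables") automatically from the
substrate–product pairs of any reaction database and applies them to query
molecules to propose putative metabolic products — the kind of evidence used
to fill gaps in metabolic networks, annotate underground metabolism, or
propose degradation routes for compounds (such as dietary phenolics) that
curated databases do not yet cover.

## The method

Enzymes frequently accept substrates beyond their annotated ones. If a known
reaction rewrites a particular molecular substructure, a promiscuous enzyme
may apply the same rewrite wherever that substructure occurs. `promiskit`
operationalises this in six steps:

1. **Metabolic space.** Reaction equations are parsed, common cofactors
   (H₂O, NAD(H), ATP, …; an editable list) are stripped, metabolites without
   a resolvable structure are filtered, and reactions that lose a whole side
   are dropped with a machine-readable reason.
2. **Pairing.** Each simplified reaction's substrates and products are
   paired by chemical similarity (Morgan count fingerprints, radius 2,
   Dice coefficient), greedily on descending similarity; a lone substrate is
   paired with every product and vice versa.
3. **Alignment.** Each pair is aligned atom-to-atom over its maximum common
   substructure (MCS), under two constraints: ring atoms only match ring
   atoms, and matched atoms must carry equal formal charge. Bond orders are
   *not* compared, so order changes inside the conserved core remain visible.
4. **Atom typing and rule construction.** Every heavy atom is classified
   into a KEGG atom-type code (`C8x` = aromatic CH, `C8y` = substituted
   aromatic C, `O1a` = hydroxyl O, …). A **reaction centre** is a mapped
   atom whose code changes, e.g. `C8x → C8y` for an aromatic hydroxylation.
   Each centre yields one (key, value) unit: the **key** stores the centre
   plus its distance-1 ("adjacent") and distance-2 ("distant") neighbours;
   the **value** stores the product-side centre type, fragments added or
   removed through the centre, bond edits (introduce / delete / change
   order), and formal-charge edits. Multi-step reactions produce several
   units (R1, R2, …) in one rule.
5. **Key matching.** For a query compound, every atom's radius-2
   neighbourhood is compared against the rule keys; multi-centre rules must
   match *all* their keys with mutually consistent atom assignments. A
   Dice-similarity prefilter (default ≥ 0.6 against the template substrate)
   discards far-fetched transfers.
6. **Product generation.** The query graph is rewritten according to the
   value tables — fragments grafted or excised, bonds edited, charges
   introduced, preserved or removed — with a tracking system that adds
   fragments shared between centres exactly once. The edited graph is
   re-sanitised and canonicalised; removed moieties are reported as
   co-products.

Two validation harnesses ship with the engine. **Self-recovery** applies
each rule to its own template substrate and requires the annotated product
among the predictions — rules that pass have captured their reaction's
chemistry. **Leave-one-out** asks whether a pair's product is recovered by
rules from *other* reactions, measuring how well the rule space generalises.

## Worked example

Induce the hydroxylation rule from 4-hydroxybenzoate → 3,4-dihydroxybenzoate
and apply it to L-tyrosine and p-cresol (`examples/02_predict_products.py`):

```text
L-Tyrosine:
  -> NC(Cc1ccc(O)c(O)c1)C(=O)O   (template R01296, centre atoms (5,))
p-Cresol:
  -> Cc1ccc(O)c(O)c1   (template R01296, centre atoms (3,))
```

The rule's key — an aromatic CH (`C8x`) whose two ring neighbours lead to a
phenolic oxygen on one side — matches L-tyrosine at the ring position ortho
to its hydroxyl; rewriting there attaches one oxygen and yields
3,4-dihydroxy-L-phenylalanine (L-DOPA). p-Cresol is hydroxylated to
4-methylcatechol the same way. Each prediction records its product SMILES
and MOL block, the template reaction (id, EC, equation) and the query, and
batches serialise to a schema-validated JSON file.

The other examples cover rule anatomy (`01`), a two-centre aminomutase rule
(`03`), self-recovery across the three engine configurations (`04`), and
leave-one-out generalisation (`05`). A thin CLI wraps the same library
calls:

```bash
promiskit induce --reactions reactions.tsv --structures structures.tsv --out rules.json
promiskit predict --rules rules.json --query queries.smi --threshold 0.6 --out preds.json
promiskit validate self-recovery --reactions reactions.tsv --structures structures.tsv --case 3
```

## Layout

- `src/promiskit/` — the library (`metabolic_space`, `pairing`, `alignment`,
  `atom_typing`, `rule_builder`, `prediction_engine`, `validation`,
  `fixtures`, `cli`).
- `examples/` — one short narrative script per capability.
- `docs/methods.md` — model, parameters, numerical choices, limitations.
- `tests/` — pytest suite, including brute-force oracles for the MCS
  alignment and key matching.
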