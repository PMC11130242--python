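# Methods

This note documents the model behind `promiskit`, the parameters that
matter, the numerical and design choices made where the design was open,
what the synthetic fixtures do and do not establish, and known limitations.

## The rule model

A reaction rule is induced from a single substrate–product pair and stored
as one or more (key, value) units.

**Alignment.** The pair is aligned over its maximum common substructure,
computed with RDKit's FMCS. Two constraints are fixed on: ring atoms match
only ring atoms, and matched atoms must carry equal formal charge. Bond
orders are deliberately not compared — a double bond becoming single within
the conserved core must stay inside the alignment to be detected as a bond
rearrangement rather than splitting the MCS. The search maximises atom
count (not bond count), which makes the implementation directly comparable
with the exhaustive maximum-common-connected-subgraph oracle used in the
tests. Among equally sized embeddings of the MCS pattern, the one
minimising the lexicographic sequence of (substrate index, product index)
pairs is selected; this tie-break is arbitrary but deterministic, which is
what reproducible rule files require. Per-pair MCS time budget: 60 s;
alignment failures (timeout, empty MCS) are recorded per pair, never fatal.

**Atom typing.** Heavy atoms are classified into KEGG atom-type codes by a
data-driven rule table (`data/kegg_atom_types.tsv`: code, element, SMARTS
environment pattern, priority; first match per atom wins). The table
implements the published KEGG nomenclature for C/N/O/S/P and halogens at
the granularity the rule machinery needs; environments outside the table
receive a deterministic hashed fallback code so typing never fails. Two
properties are load-bearing and tested: atoms with identical radius-2
environments always receive identical codes, and codes never depend on
context beyond two bonds. Formal charge is *not* part of the code — a
charged atom keeps the code of its neutral environment and charge is
tracked separately, so that charge handling can be switched off (the
engine's charge-blind mode) without changing centre detection.

**Centres and units.** A reaction centre is a mapped atom whose code
differs between substrate and product. Each centre anchors one unit: the
key is the centre's code plus its distance-1 neighbours (code, bond order,
charge) and, grouped per distance-1 branch, its distance-2 neighbours; the
value holds the product-side centre code, fragment edits, bond edits and
charge edits. Additional anchoring rules complete the picture where the
centre definition alone is silent:

- a bond edit whose endpoints both changed type is folded into the existing
  centre unit (not double-counted); an edit with an unchanged endpoint
  anchors a unit of its own at the lower-indexed endpoint;
- a fragment whose attachment atom is not a centre anchors a unit at the
  attachment atom (this happens when only a charged terminal atom is
  exchanged, e.g. a carboxyl carbon keeps `C6a` while −OH is swapped for
  −O⁻);
- fragments reachable from several centres are stored once with multiple
  attachments. This is what makes the duplicate-addition guard at
  application time well defined: application iterates fragments, not
  units, so a shared fragment is grafted exactly once.

A fragment with no bond to any mapped atom (a disappearing disconnected
component, e.g. a counter-ion) has no anchor; rule construction fails with
`ambiguous_fragment`. A pair with no centres, edits or fragments fails with
`no_transformation`.

**Matching.** A rule fires on a query when every unit's key embeds into the
query with mutually consistent, injective atom assignments. The embedding
is branch-exact at the centre and its distance-1 atoms (equal neighbour
counts, equal codes, charges and bond orders) and permissive at distance 2
(codes and charges only) — the distance-2 shell is the promiscuity
boundary. The alternative flat-multiset reading of the distant shell is
available as `key_match_mode="flat"`. Removed fragments are located in the
query by an anchored subgraph match that must be *terminal*: deleting the
image severs only the attachment bonds. Fragment atoms within two bonds of
a centre already have images under the key embedding; those are pinned, not
re-searched.

**Application.** Charge edits, bond edits, fragment additions and removals
are applied to an editable copy of the query graph. Added fragments carry
kekulized bond orders (they must survive sanitisation when grafted);
removed fragments are matched with perceived aromatic orders (they are
compared against the aromatic-perceived query). The edited graph is
re-sanitised — aromaticity re-perceived — before canonicalisation;
predictions failing sanitisation are rejected with a reason, never emitted.
Removed components are returned as co-products (H-capped at the severed
bond), behind `emit_co_products` (default on) since two-product outcomes
(e.g. glucuronide cleavage) are chemically meaningful. Note that for a
cleavage template the leaving group's own product (e.g. glucuronic acid
with its anomeric hydroxyl) is produced exactly by the *other*
substrate–product pair of the same reaction; the co-product of the aglycone
rule is the H-capped moiety, which may differ from the biological
co-product by the atoms contributed by water.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `fingerprint_radius` / `fingerprint_bits` | 2 / 2048 | Morgan fingerprint for pairing and prefilter |
| `fingerprint_counts` | on | count (frequency) fingerprints rather than bits |
| `similarity_threshold` | 0.6 | Dice prefilter query vs template substrate |
| `ring_matches_ring`, `match_formal_charge` | on | MCS constraints |
| `use_charges` | on | track charges in rules and application |
| `single_centre_only` | off | restrict induction to one-centre, no-bond-edit reactions |
| `mcs_timeout` | 60 s | per-pair MCS budget |
| `key_match_mode` | branch | distance-2 matching per branch or flat |
| `bidirectional` | off | also induce reversed pairs |
| `cofactors` | packaged list | editable YAML; logged on every run |

The count-fingerprint default deserves a note: with plain 2048-bit vectors,
Dice(L-tyrosine, 4-hydroxybenzoate) = 0.55, below the 0.6 prefilter, and
the canonical hydroxylation transfer would never fire; with count
fingerprints (the classic Morgan + Dice combination) the same pair scores
0.68 and the transfer behaves as expected. Dice similarity is used
throughout — one coefficient for pairing, prefiltering and product
comparison.

Pairing uses greedy descending-similarity assignment with lexicographic
tie-breaks, then attaches leftovers on the larger side to their most
similar counterpart (many-to-one), guaranteeing every structured species
appears in at least one pair. Greedy was chosen over optimal matching as
the simplest defensible scheme; the choice only matters for reactions with
several near-tied cross-similarities, and it is logged.

Validation configurations: Case 1 = single-centre reactions, charges off;
Case 2 = single-centre, charges on; Case 3 = everything. "Single centre" is
classified from the engine's own detection (every pair ≤ 1 centre, no bond
edits), so the subset is auditable. Recovery reports state both
denominators: all reactions, and reactions with complete look-up tables.

## Synthetic fixtures: what they show

`generate_synthetic_space` builds reactions whose products are constructed
by direct graph editing of random decorated benzene / aliphatic scaffolds —
the ground truth is therefore correct by construction and independent of
the engine. The edit vocabulary (hydroxylation, O-methylation,
deglucuronidation, amide hydrolysis with two products, bond-order change,
charge toggle) exercises every rule-unit variety: single- and multi-centre
rules, fragment addition and removal, bond edits and charge edits. On these
spaces self-recovery must be, and is, 100% — that establishes the engine's
internal consistency (induction and application are exact inverses on the
template), not real-database accuracy. Real reaction sets add challenges
the generator deliberately omits: stereochemistry, tautomers,
resonance-delocalised charges, unbalanced or lumped multi-step equations,
and structure-resolution noise; accuracy there is an empirical question for
the user's own database. Leave-one-out on synthetic spaces measures only
the chemistry overlap that was generated into them (problem sizes used in
the shipped scripts: 50 reactions for self-recovery, ~20 for the
charge-ledger and leave-one-out checks).

## Numerical and degenerate-input choices

- Stereochemistry is stripped on input and ignored throughout; product
  identity is canonical SMILES equality after stereo removal.
- Formal-charge bookkeeping is closed: for every prediction, charge of
  product plus co-products minus query equals the rule's charge edits plus
  added-fragment charges (a tested ledger invariant).
- Embedding and match enumeration are capped (256 options per unit, 1024
  combined matches, 200k MCS embedding combinations) with deterministic
  enumeration order, so caps never introduce nondeterminism.
- Degenerate inputs: empty equations, unresolved structures, cofactor-only
  reactions and unparsable SMILES all become typed error/drop records;
  counts reconcile exactly (inputs = simplified + dropped).
- Rule files are versioned JSON; save → load → save is byte-identical.

## Limitations

- No stereochemistry: rules cannot distinguish epimers, and
  stereo-specific template reactions induce stereo-blind rules.
- Connected MCS only; reactions whose conserved core is split across
  disconnected pieces fail alignment.
- The co-product of a cleavage rule is H-capped rather than
  hydrolysis-balanced (see above).
- Key matching is neighbourhood-exact at radius 1; promiscuity across
  substituent variation directly adjacent to the centre is out of reach by
  design (that specificity is the point of the radius-2 key), which bounds
  leave-one-out recovery.
- The KEGG atom-type table is a faithful but package-local implementation;
  exotic environments fall back to hashed codes that are stable but not
  part of the published nomenclature.
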