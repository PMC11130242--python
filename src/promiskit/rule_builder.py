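"""Reaction-centre detection and look-up-table (rule) construction.

A *reaction centre* is a mapped substrate atom whose KEGG atom-type code
differs from its aligned product atom.  Each rule is one or more
(key table, value table) units:

* the **key** stores the centre's code plus its distance-1 ("adjacent") and
  distance-2 ("distant") neighbourhood, the substructure a query compound
  must present;
* the **value** stores the resulting change: the centre's product-side code,
  fragments added or removed through the centre, bond edits (introduce /
  delete / change order) between mapped atoms, and formal-charge edits.

Multi-step transformations produce several centres and therefore several
units (labelled R1, R2, ...), which must all match a query simultaneously.
Bond rearrangements whose endpoints both change type are folded into the
existing centre units; otherwise they anchor a unit of their own.  Fragments
connected through a mapped atom that is not a centre (possible when only a
charged terminal atom is exchanged) likewise anchor a unit at the attachment
atom.  Fragments reachable from several centres are stored once with
multiple attachments, which is what makes the duplicate-addition guard at
application time well defined.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
from rdkit import Chem

from .alignment import AlignmentError, AtomAlignment, compute_mcs_alignment
from .atom_typing import assign_kegg_atom_types
from .chem import bond_order, canonical_smiles
from .config import EngineConfig
from .metabolic_space import MetabolicSpace, Metabolite, Reaction
from .pairing import ReactantPair, pair_reactants

RULES_SCHEMA_VERSION = 1


class RuleBuildError(RuntimeError):
    """Rule construction failed; ``reason`` is machine-readable."""

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}{': ' + detail if detail else ''}")


@dataclass(frozen=True)
class ReactionCentre:
    substrate_atom: int
    product_atom: int
    substrate_type: str
    product_type: str
    label: str = ""


@dataclass(frozen=True)
class BondEdit:
    """A bond between two mapped atoms present on one side only or with a
    different order; endpoints are substrate-side indices."""

    sub_atoms: tuple[int, int]
    old_order: float | None
    new_order: float | None
    action: str  # "introduce" | "delete" | "change"


@dataclass(frozen=True)
class ChargeEdit:
    sub_atom: int
    delta: int


@dataclass(frozen=True)
class Attachment:
    unit_label: str
    sub_atom: int  # mapped atom (substrate indexing) the fragment bonds to
    frag_atom: int  # fragment atom (owning molecule's indexing)
    order: float


@dataclass(frozen=True)
class Fragment:
    """A connected set of unmapped atoms (indices of the owning molecule:
    substrate for removed fragments, product for added ones)."""

    atoms: tuple[int, ...]
    elements: tuple[str, ...]
    charges: tuple[int, ...]
    bonds: tuple[tuple[int, int, float], ...]
    attachments: tuple[Attachment, ...] = ()

    def with_attachments(self, att: tuple[Attachment, ...]) -> "Fragment":
        return Fragment(self.atoms, self.elements, self.charges, self.bonds, att)

    @property
    def total_charge(self) -> int:
        return sum(self.charges)


@dataclass(frozen=True)
class AdjacentEntry:
    code: str
    order: float
    charge: int
    distant: tuple[tuple[str, float, int], ...]  # sorted (code, order, charge)


@dataclass(frozen=True)
class KeyTable:
    centre_type: str
    centre_charge: int
    adjacent: tuple[AdjacentEntry, ...]

    @property
    def flat_distant(self) -> tuple[tuple[str, float, int], ...]:
        return tuple(sorted(d for a in self.adjacent for d in a.distant))


@dataclass(frozen=True)
class ValueTable:
    centre_type_product: str
    adjacent_product: tuple[tuple[str, float], ...]
    fragment_added_idx: tuple[int, ...]
    fragment_removed_idx: tuple[int, ...]
    bond_edits: tuple[BondEdit, ...]
    charge_edits: tuple[ChargeEdit, ...]

    @property
    def is_empty(self) -> bool:
        return not (
            self.fragment_added_idx
            or self.fragment_removed_idx
            or self.bond_edits
            or self.charge_edits
        )


@dataclass(frozen=True)
class RuleUnit:
    label: str
    anchor: int  # substrate atom index of the centre / anchor atom
    is_centre: bool
    key: KeyTable
    value: ValueTable


@dataclass(frozen=True)
class LookupRule:
    rule_id: str
    reaction_id: str
    ec: tuple[str, ...]
    equation: str
    template_substrate_id: str
    template_product_id: str
    substrate_molblock: str
    product_molblock: str
    substrate_smiles: str
    product_smiles: str
    alignment: AtomAlignment
    sub_codes: tuple[str, ...]
    prod_codes: tuple[str, ...]
    units: tuple[RuleUnit, ...]
    centres: tuple[ReactionCentre, ...]
    fragments_added: tuple[Fragment, ...]
    fragments_removed: tuple[Fragment, ...]
    use_charges: bool

    @property
    def multi_centre(self) -> bool:
        return len(self.units) > 1

    def substrate_mol(self) -> Chem.Mol:
        return Chem.MolFromMolBlock(self.substrate_molblock)

    def product_mol(self) -> Chem.Mol:
        return Chem.MolFromMolBlock(self.product_molblock)

    @property
    def has_bond_edits(self) -> bool:
        return any(u.value.bond_edits for u in self.units)

    @property
    def charge_balance(self) -> int:
        """Signed charge the rule adds: fragment charges in minus out, plus
        explicit charge edits."""
        delta = sum(f.total_charge for f in self.fragments_added)
        delta -= sum(f.total_charge for f in self.fragments_removed)
        delta += sum(e.delta for u in self.units for e in u.value.charge_edits)
        return delta


def neighbourhood_key(
    mol: Chem.Mol, codes: list[str], centre: int, use_charges: bool
) -> KeyTable:
    """Radius-2 neighbourhood descriptor of ``centre``: the key-table shape.

    Adjacent entries are the atoms at topological distance exactly 1;
    distant entries, grouped per adjacent branch, those at distance exactly
    2 (a neighbour's neighbour that is itself bonded to the centre is
    distance 1 and excluded from the branch).
    """
    charges = [a.GetFormalCharge() for a in mol.GetAtoms()]
    catom = mol.GetAtomWithIdx(centre)
    entries = []
    for nb in catom.GetNeighbors():
        border = bond_order(mol.GetBondBetweenAtoms(centre, nb.GetIdx()))
        distant = []
        for nb2 in nb.GetNeighbors():
            if nb2.GetIdx() == centre:
                continue
            if mol.GetBondBetweenAtoms(centre, nb2.GetIdx()) is not None:
                continue  # distance 1, not 2
            o2 = bond_order(mol.GetBondBetweenAtoms(nb.GetIdx(), nb2.GetIdx()))
            distant.append((codes[nb2.GetIdx()], o2, charges[nb2.GetIdx()] if use_charges else 0))
        entries.append(
            AdjacentEntry(
                codes[nb.GetIdx()],
                border,
                charges[nb.GetIdx()] if use_charges else 0,
                tuple(sorted(distant)),
            )
        )
    entries.sort(key=lambda e: (e.code, e.order, e.charge, e.distant))
    return KeyTable(codes[centre], charges[centre] if use_charges else 0, tuple(entries))


def find_reaction_centres(
    alignment: AtomAlignment, sub_codes: list[str], prod_codes: list[str]
) -> list[ReactionCentre]:
    """Mapped atoms whose KEGG atom-type codes differ, by substrate index."""
    centres = []
    for s, p in alignment.mapping:
        if sub_codes[s] != prod_codes[p]:
            centres.append(ReactionCentre(s, p, sub_codes[s], prod_codes[p]))
    return sorted(centres, key=lambda c: c.substrate_atom)


def detect_bond_rearrangements(
    alignment: AtomAlignment, sub: Chem.Mol, prod: Chem.Mol
) -> list[BondEdit]:
    """Bonds between mapped atoms present on one side only or with a
    different order."""
    s2p = alignment.sub_to_prod
    p2s = alignment.prod_to_sub
    edits: list[BondEdit] = []
    for bond in sub.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if i not in s2p or j not in s2p:
            continue
        pb = prod.GetBondBetweenAtoms(s2p[i], s2p[j])
        key = tuple(sorted((i, j)))
        if pb is None:
            edits.append(BondEdit(key, bond_order(bond), None, "delete"))
        elif bond_order(pb) != bond_order(bond):
            edits.append(BondEdit(key, bond_order(bond), bond_order(pb), "change"))
    for bond in prod.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if i not in p2s or j not in p2s:
            continue
        if sub.GetBondBetweenAtoms(p2s[i], p2s[j]) is None:
            edits.append(BondEdit(tuple(sorted((p2s[i], p2s[j]))), None, bond_order(bond), "introduce"))
    return sorted(edits, key=lambda e: e.sub_atoms)


def _fragments(mol: Chem.Mol, unmapped: tuple[int, ...], mapped: set[int]) -> list[Fragment]:
    """Connected components of unmapped atoms, with their bonds to mapped
    atoms recorded (attachments are filled in by the unit assembly)."""
    g = nx.Graph()
    g.add_nodes_from(unmapped)
    unmapped_set = set(unmapped)
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if i in unmapped_set and j in unmapped_set:
            g.add_edge(i, j)
    frags = []
    for comp in sorted(nx.connected_components(g), key=min):
        atoms = tuple(sorted(comp))
        bonds = []
        raw_att = []
        for a in atoms:
            for nb in mol.GetAtomWithIdx(a).GetNeighbors():
                b = nb.GetIdx()
                order = bond_order(mol.GetBondBetweenAtoms(a, b))
                if b in comp:
                    if a < b:
                        bonds.append((a, b, order))
                elif b in mapped:
                    raw_att.append((b, a, order))
        frag = Fragment(
            atoms=atoms,
            elements=tuple(mol.GetAtomWithIdx(a).GetSymbol() for a in atoms),
            charges=tuple(mol.GetAtomWithIdx(a).GetFormalCharge() for a in atoms),
            bonds=tuple(sorted(bonds)),
        )
        frags.append((frag, sorted(raw_att)))
    return frags


def build_rule(
    pair: ReactantPair,
    substrate: Metabolite,
    product: Metabolite,
    alignment: AtomAlignment,
    config: EngineConfig | None = None,
    ec: tuple[str, ...] = (),
    equation: str = "",
) -> LookupRule:
    """Build the look-up rule for one aligned substrate-product pair.

    Raises
    ------
    RuleBuildError
        ``"no_transformation"`` when substrate and product are structurally
        identical under the alignment; ``"ambiguous_fragment"`` when an
        added/removed fragment has no bond to any mapped atom and therefore
        no anchor.
    """
    config = config or EngineConfig()
    sub, prod = substrate.mol, product.mol
    sub_codes = [t.type_code for t in assign_kegg_atom_types(sub)]
    prod_codes = [t.type_code for t in assign_kegg_atom_types(prod)]
    s2p = alignment.sub_to_prod

    centres = find_reaction_centres(alignment, sub_codes, prod_codes)
    bond_edits = detect_bond_rearrangements(alignment, sub, prod)
    charge_edits: list[ChargeEdit] = []
    if config.use_charges:
        for s, p in alignment.mapping:
            ds = prod.GetAtomWithIdx(p).GetFormalCharge() - sub.GetAtomWithIdx(s).GetFormalCharge()
            if ds:
                charge_edits.append(ChargeEdit(s, ds))

    mapped_sub = set(s2p)
    mapped_prod = set(alignment.prod_to_sub)
    removed_raw = _fragments(sub, alignment.unmapped_substrate, mapped_sub)
    # Added fragments are stored with kekulized bond orders: they must later
    # be grafted onto a query graph and survive sanitisation.  Removed
    # fragments keep perceived (aromatic) orders: they are matched against
    # the aromatic-perceived query.
    kek_prod = Chem.Mol(prod)
    try:
        Chem.Kekulize(kek_prod, clearAromaticFlags=True)
    except Exception:
        kek_prod = prod
    added_raw = _fragments(kek_prod, alignment.unmapped_product, mapped_prod)
    for frag, att in (*removed_raw, *added_raw):
        if not att:
            raise RuleBuildError("ambiguous_fragment", "fragment has no bond to a mapped atom")

    if not (centres or bond_edits or charge_edits or removed_raw or added_raw):
        raise RuleBuildError("no_transformation")

    # ---- unit assembly ----------------------------------------------------
    dist = Chem.GetDistanceMatrix(sub)
    anchors: list[int] = [c.substrate_atom for c in centres]
    centre_by_anchor = {c.substrate_atom: c for c in centres}

    def owner(atom: int, max_dist: int = 2) -> int:
        """Anchor owning ``atom``: itself if anchored, else the nearest
        anchor within ``max_dist`` bonds, else a fresh anchor at ``atom``."""
        if atom in anchors:
            return atom
        near = [(dist[atom][a], a) for a in anchors if dist[atom][a] <= max_dist]
        if near:
            return min(near)[1]
        anchors.append(atom)
        return atom

    unit_bond_edits: dict[int, list[BondEdit]] = {}
    for edit in bond_edits:
        e1, e2 = edit.sub_atoms
        target = e1 if e1 in anchors else (e2 if e2 in anchors else e1)
        if target not in anchors:
            anchors.append(target)
        unit_bond_edits.setdefault(target, []).append(edit)

    unit_charge_edits: dict[int, list[ChargeEdit]] = {}
    for ce in charge_edits:
        unit_charge_edits.setdefault(owner(ce.sub_atom), []).append(ce)

    # Attachments: product-side attachment atoms are translated to substrate
    # indexing so application can resolve them through the key embedding.
    p2s = alignment.prod_to_sub
    frag_owner_removed: list[list[tuple[int, int, int, float]]] = []
    for frag, att in removed_raw:
        frag_owner_removed.append([(owner(b), b, a, o) for (b, a, o) in att])
    frag_owner_added: list[list[tuple[int, int, int, float]]] = []
    for frag, att in added_raw:
        frag_owner_added.append([(owner(p2s[b]), p2s[b], a, o) for (b, a, o) in att])

    anchors_sorted = sorted(anchors)
    labels = {a: f"R{i + 1}" for i, a in enumerate(anchors_sorted)}

    def finalize_frags(raw, owners) -> tuple[Fragment, ...]:
        out = []
        for (frag, _), own in zip(raw, owners):
            atts = tuple(
                Attachment(labels[anchor], sub_atom, frag_atom, order)
                for anchor, sub_atom, frag_atom, order in sorted(own)
            )
            out.append(frag.with_attachments(atts))
        return tuple(out)

    fragments_removed = finalize_frags(removed_raw, frag_owner_removed)
    fragments_added = finalize_frags(added_raw, frag_owner_added)

    units = []
    relabelled_centres = []
    for anchor in anchors_sorted:
        label = labels[anchor]
        centre = centre_by_anchor.get(anchor)
        if centre is not None:
            centre = ReactionCentre(
                centre.substrate_atom, centre.product_atom, centre.substrate_type, centre.product_type, label
            )
            relabelled_centres.append(centre)
        key = neighbourhood_key(sub, sub_codes, anchor, config.use_charges)
        p_anchor = s2p[anchor]
        adjacent_product = tuple(
            sorted(
                (prod_codes[nb.GetIdx()], bond_order(prod.GetBondBetweenAtoms(p_anchor, nb.GetIdx())))
                for nb in prod.GetAtomWithIdx(p_anchor).GetNeighbors()
            )
        )
        value = ValueTable(
            centre_type_product=prod_codes[p_anchor],
            adjacent_product=adjacent_product,
            fragment_added_idx=tuple(
                i for i, f in enumerate(fragments_added) if any(a.unit_label == label for a in f.attachments)
            ),
            fragment_removed_idx=tuple(
                i for i, f in enumerate(fragments_removed) if any(a.unit_label == label for a in f.attachments)
            ),
            bond_edits=tuple(unit_bond_edits.get(anchor, ())),
            charge_edits=tuple(unit_charge_edits.get(anchor, ())),
        )
        units.append(RuleUnit(label, anchor, centre is not None, key, value))

    return LookupRule(
        rule_id=f"{pair.reaction_id}:{pair.substrate_id}>{pair.product_id}",
        reaction_id=pair.reaction_id,
        ec=ec,
        equation=equation,
        template_substrate_id=pair.substrate_id,
        template_product_id=pair.product_id,
        substrate_molblock=Chem.MolToMolBlock(sub, kekulize=True),
        product_molblock=Chem.MolToMolBlock(prod, kekulize=True),
        substrate_smiles=canonical_smiles(sub),
        product_smiles=canonical_smiles(prod),
        alignment=alignment,
        sub_codes=tuple(sub_codes),
        prod_codes=tuple(prod_codes),
        units=tuple(units),
        centres=tuple(relabelled_centres),
        fragments_added=fragments_added,
        fragments_removed=fragments_removed,
        use_charges=config.use_charges,
    )


@dataclass(frozen=True)
class RuleFailure:
    reaction_id: str
    substrate_id: str
    product_id: str
    reason: str


def rule_for_pair(
    pair: ReactantPair,
    space: MetabolicSpace | dict[str, Metabolite],
    config: EngineConfig | None = None,
    ec: tuple[str, ...] = (),
    equation: str = "",
) -> LookupRule:
    """Convenience: align a pair and build its rule in one call."""
    config = config or EngineConfig()
    mets = space.metabolites if isinstance(space, MetabolicSpace) else space
    substrate = mets[pair.substrate_id]
    product = mets[pair.product_id]
    alignment = compute_mcs_alignment(substrate.mol, product.mol, config)
    return build_rule(pair, substrate, product, alignment, config, ec=ec, equation=equation)


def induce_rules(
    space: MetabolicSpace, config: EngineConfig | None = None
) -> tuple[list[LookupRule], list[RuleFailure]]:
    """Induce look-up rules for every substrate-product pair of the space.

    Rules are induced in the written left-to-right direction;
    ``config.bidirectional`` additionally induces the reversed pairs.  With
    ``config.single_centre_only`` every reaction whose pairs produce more
    than one rule unit or any bond rearrangement is excluded (recorded as a
    failure), which restricts the rule space to simple one-centre chemistry.
    """
    config = config or EngineConfig()
    rules: list[LookupRule] = []
    failures: list[RuleFailure] = []
    for reaction in space.reactions:
        pairs = pair_reactants(reaction, space.metabolites, config)
        if config.bidirectional:
            pairs = pairs + [
                ReactantPair(p.reaction_id, p.product_id, p.substrate_id, p.similarity) for p in pairs
            ]
        reaction_rules: list[LookupRule] = []
        reaction_failures: list[RuleFailure] = []
        for pair in pairs:
            try:
                rule = rule_for_pair(pair, space, config, ec=reaction.ec, equation=reaction.equation_text)
                reaction_rules.append(rule)
            except (AlignmentError, RuleBuildError) as exc:
                reaction_failures.append(
                    RuleFailure(reaction.id, pair.substrate_id, pair.product_id, exc.reason)
                )
        if config.single_centre_only and any(
            len(r.units) > 1 or r.has_bond_edits for r in reaction_rules
        ):
            failures.extend(
                RuleFailure(reaction.id, r.template_substrate_id, r.template_product_id, "multi_centre_excluded")
                for r in reaction_rules
            )
            failures.extend(reaction_failures)
            continue
        rules.extend(reaction_rules)
        failures.extend(reaction_failures)
    return rules, failures


# ---------------------------------------------------------------------------
# serialization (versioned JSON rule file; load/save round-trip is bit-stable)
# ---------------------------------------------------------------------------


def _rule_to_dict(rule: LookupRule) -> dict:
    return {
        "rule_id": rule.rule_id,
        "reaction_id": rule.reaction_id,
        "ec": list(rule.ec),
        "equation": rule.equation,
        "template_substrate_id": rule.template_substrate_id,
        "template_product_id": rule.template_product_id,
        "substrate_molblock": rule.substrate_molblock,
        "product_molblock": rule.product_molblock,
        "substrate_smiles": rule.substrate_smiles,
        "product_smiles": rule.product_smiles,
        "alignment": rule.alignment.to_json_dict(),
        "sub_codes": list(rule.sub_codes),
        "prod_codes": list(rule.prod_codes),
        "use_charges": rule.use_charges,
        "centres": [
            {
                "substrate_atom": c.substrate_atom,
                "product_atom": c.product_atom,
                "substrate_type": c.substrate_type,
                "product_type": c.product_type,
                "label": c.label,
            }
            for c in rule.centres
        ],
        "fragments_added": [_frag_to_dict(f) for f in rule.fragments_added],
        "fragments_removed": [_frag_to_dict(f) for f in rule.fragments_removed],
        "units": [
            {
                "label": u.label,
                "anchor": u.anchor,
                "is_centre": u.is_centre,
                "key": {
                    "centre_type": u.key.centre_type,
                    "centre_charge": u.key.centre_charge,
                    "adjacent": [
                        {
                            "code": a.code,
                            "order": a.order,
                            "charge": a.charge,
                            "distant": [list(d) for d in a.distant],
                        }
                        for a in u.key.adjacent
                    ],
                },
                "value": {
                    "centre_type_product": u.value.centre_type_product,
                    "adjacent_product": [list(t) for t in u.value.adjacent_product],
                    "fragment_added_idx": list(u.value.fragment_added_idx),
                    "fragment_removed_idx": list(u.value.fragment_removed_idx),
                    "bond_edits": [
                        {
                            "sub_atoms": list(e.sub_atoms),
                            "old_order": e.old_order,
                            "new_order": e.new_order,
                            "action": e.action,
                        }
                        for e in u.value.bond_edits
                    ],
                    "charge_edits": [
                        {"sub_atom": e.sub_atom, "delta": e.delta} for e in u.value.charge_edits
                    ],
                },
            }
            for u in rule.units
        ],
    }


def _frag_to_dict(f: Fragment) -> dict:
    return {
        "atoms": list(f.atoms),
        "elements": list(f.elements),
        "charges": list(f.charges),
        "bonds": [list(b) for b in f.bonds],
        "attachments": [
            {"unit_label": a.unit_label, "sub_atom": a.sub_atom, "frag_atom": a.frag_atom, "order": a.order}
            for a in f.attachments
        ],
    }


def _frag_from_dict(d: dict) -> Fragment:
    return Fragment(
        atoms=tuple(d["atoms"]),
        elements=tuple(d["elements"]),
        charges=tuple(d["charges"]),
        bonds=tuple((b[0], b[1], b[2]) for b in d["bonds"]),
        attachments=tuple(
            Attachment(a["unit_label"], a["sub_atom"], a["frag_atom"], a["order"]) for a in d["attachments"]
        ),
    )


def _rule_from_dict(d: dict) -> LookupRule:
    units = []
    for u in d["units"]:
        key = KeyTable(
            u["key"]["centre_type"],
            u["key"]["centre_charge"],
            tuple(
                AdjacentEntry(
                    a["code"], a["order"], a["charge"], tuple((x[0], x[1], x[2]) for x in a["distant"])
                )
                for a in u["key"]["adjacent"]
            ),
        )
        value = ValueTable(
            u["value"]["centre_type_product"],
            tuple((t[0], t[1]) for t in u["value"]["adjacent_product"]),
            tuple(u["value"]["fragment_added_idx"]),
            tuple(u["value"]["fragment_removed_idx"]),
            tuple(
                BondEdit(tuple(e["sub_atoms"]), e["old_order"], e["new_order"], e["action"])
                for e in u["value"]["bond_edits"]
            ),
            tuple(ChargeEdit(e["sub_atom"], e["delta"]) for e in u["value"]["charge_edits"]),
        )
        units.append(RuleUnit(u["label"], u["anchor"], u["is_centre"], key, value))
    return LookupRule(
        rule_id=d["rule_id"],
        reaction_id=d["reaction_id"],
        ec=tuple(d["ec"]),
        equation=d["equation"],
        template_substrate_id=d["template_substrate_id"],
        template_product_id=d["template_product_id"],
        substrate_molblock=d["substrate_molblock"],
        product_molblock=d["product_molblock"],
        substrate_smiles=d["substrate_smiles"],
        product_smiles=d["product_smiles"],
        alignment=AtomAlignment.from_json_dict(d["alignment"]),
        sub_codes=tuple(d["sub_codes"]),
        prod_codes=tuple(d["prod_codes"]),
        units=tuple(units),
        centres=tuple(
            ReactionCentre(
                c["substrate_atom"], c["product_atom"], c["substrate_type"], c["product_type"], c["label"]
            )
            for c in d["centres"]
        ),
        fragments_added=tuple(_frag_from_dict(f) for f in d["fragments_added"]),
        fragments_removed=tuple(_frag_from_dict(f) for f in d["fragments_removed"]),
        use_charges=d["use_charges"],
    )


def save_rules(rules: list[LookupRule], path: str | Path, config: EngineConfig | None = None) -> None:
    payload = {
        "schema_version": RULES_SCHEMA_VERSION,
        "config": (config or EngineConfig()).to_dict(),
        "rules": [_rule_to_dict(r) for r in rules],
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True, separators=(",", ":")) + "\n")


def load_rules(path: str | Path) -> tuple[list[LookupRule], EngineConfig]:
    payload = json.loads(Path(path).read_text())
    if payload.get("schema_version") != RULES_SCHEMA_VERSION:
        raise ValueError(f"unsupported rules schema version: {payload.get('schema_version')}")
    config = EngineConfig.from_dict(payload["config"])
    return [_rule_from_dict(d) for d in payload["rules"]], config
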