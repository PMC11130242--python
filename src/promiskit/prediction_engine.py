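"""Key matching and product generation.

A rule matches a query compound when every one of its units embeds into the
query: the unit's centre code must appear at some query atom whose radius-2
neighbourhood reproduces the key table (adjacent atoms and, per branch, the
distant atoms).  Embeddings of different units must agree on shared atoms
and never assign two template atoms to one query atom.

Applying a matched rule edits a copy of the query graph: formal-charge
edits, bond edits (introduce / delete / change order), removal of the
fragments deleted by the template chemistry (their query image is located by
an anchored, terminal subgraph match) and addition of the template's new
fragments.  Fragments shared between several centres are stored once on the
rule and therefore added exactly once — the duplicate-addition guard.
Charges on retained query atoms are preserved; charges carried by added
fragments are introduced and charges on removed atoms leave with them.  The
edited graph is re-sanitised (aromaticity re-perceived) before
canonicalisation; structures that fail sanitisation are rejected, not
emitted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from rdkit import Chem

from .chem import bond_order, bondtype_from_order, canonical_smiles
from .config import EngineConfig
from .atom_typing import assign_kegg_atom_types
from .metabolic_space import Metabolite
from .pairing import molecule_similarity
from .rule_builder import Fragment, KeyTable, LookupRule, RuleUnit, neighbourhood_key

log = logging.getLogger(__name__)

_MAX_UNIT_OPTIONS = 256
_MAX_MATCHES = 1024


class PredictionError(RuntimeError):
    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}{': ' + detail if detail else ''}")


@dataclass(frozen=True)
class QueryMatch:
    """A consistent embedding of every unit of a rule into a query."""

    rule_id: str
    unit_centres: tuple[tuple[str, int], ...]  # (unit label, query centre atom)
    combined: tuple[tuple[int, int], ...]  # template substrate atom -> query atom
    removed_maps: tuple[tuple[tuple[int, int], ...], ...]  # per removed fragment

    @property
    def combined_map(self) -> dict[int, int]:
        return dict(self.combined)

    @property
    def centre_atoms(self) -> tuple[int, ...]:
        return tuple(q for _, q in self.unit_centres)


@dataclass(frozen=True)
class Prediction:
    query_id: str
    query_name: str
    query_smiles: str
    product_smiles: str
    product_molblock: str
    co_products: tuple[str, ...]
    reaction_id: str
    ec: tuple[str, ...]
    equation: str
    rule_id: str
    centre_atoms: tuple[int, ...]


def enumerate_query_sites(query: Chem.Mol | Metabolite, use_charges: bool = True) -> list[KeyTable]:
    """Radius-2 neighbourhood descriptor for every heavy atom of the query,
    in the same shape as a rule's key table."""
    mol = query.mol if isinstance(query, Metabolite) else query
    codes = [t.type_code for t in assign_kegg_atom_types(mol)]
    return [neighbourhood_key(mol, codes, i, use_charges) for i in range(mol.GetNumAtoms())]


def similarity_prefilter(
    query: Metabolite | Chem.Mol, rule: LookupRule, threshold: float | None = None,
    config: EngineConfig | None = None,
) -> bool:
    """True iff Dice(query, template substrate) >= threshold (default 0.6)."""
    config = config or EngineConfig()
    if threshold is None:
        threshold = config.similarity_threshold
    qmol = query.mol if isinstance(query, Metabolite) else query
    return molecule_similarity(qmol, Chem.MolFromSmiles(rule.substrate_smiles), config) >= threshold


def _key_tables_equal(a: KeyTable, b: KeyTable, mode: str) -> bool:
    if a.centre_type != b.centre_type or a.centre_charge != b.centre_charge:
        return False
    if mode == "branch":
        return a.adjacent == b.adjacent
    flat_a = tuple(sorted((e.code, e.order, e.charge) for e in a.adjacent))
    flat_b = tuple(sorted((e.code, e.order, e.charge) for e in b.adjacent))
    return flat_a == flat_b and a.flat_distant == b.flat_distant


def _ball_atoms(mol: Chem.Mol, centre: int) -> tuple[list[int], dict[int, list[int]]]:
    """Distance-1 atoms and, per distance-1 atom, its distance-2 branch."""
    adj = [n.GetIdx() for n in mol.GetAtomWithIdx(centre).GetNeighbors()]
    adj_set = set(adj)
    branches: dict[int, list[int]] = {}
    for a in adj:
        branch = []
        for n in mol.GetAtomWithIdx(a).GetNeighbors():
            i = n.GetIdx()
            if i == centre or i in adj_set:
                continue
            branch.append(i)
        branches[a] = branch
    return adj, branches


def _embed_ball(
    tmol: Chem.Mol,
    tcodes: tuple[str, ...] | list[str],
    anchor: int,
    qmol: Chem.Mol,
    qcodes: list[str],
    qcentre: int,
    use_charges: bool,
    mode: str,
) -> list[dict[int, int]]:
    """All embeddings of the template's radius-2 ball around ``anchor`` onto
    the query ball around ``qcentre``.

    The centre and every adjacent atom must reproduce their exact arity
    (branch-exact matching); distant atoms are matched on code (and charge)
    only — they are the promiscuity boundary.  With ``mode="flat"`` the
    distance-2 atoms may be redistributed across branches.
    """

    def compat(t: int, q: int) -> bool:
        if tcodes[t] != qcodes[q]:
            return False
        if use_charges and (
            tmol.GetAtomWithIdx(t).GetFormalCharge() != qmol.GetAtomWithIdx(q).GetFormalCharge()
        ):
            return False
        return True

    if not compat(anchor, qcentre):
        return []
    t_adj, t_branches = _ball_atoms(tmol, anchor)
    q_adj, q_branches = _ball_atoms(qmol, qcentre)
    if len(t_adj) != len(q_adj):
        return []

    results: list[dict[int, int]] = []

    def order(mol: Chem.Mol, i: int, j: int) -> float:
        return bond_order(mol.GetBondBetweenAtoms(i, j))

    q_distant_all = sorted({q for b in q_branches.values() for q in b})

    def extend_branch(pairs: list[tuple[int, int]], emb: dict[int, int]) -> None:
        """Assign distance-2 atoms branch by branch (pairs of matched
        adjacent atoms).  In flat mode a distant atom may sit on any branch
        of the query, matching a flat-multiset reading of the key."""
        if not pairs:
            results.append(dict(emb))
            return
        (ta, qa), rest = pairs[0], pairs[1:]
        tb = t_branches[ta]
        qb = q_branches[qa] if mode == "branch" else q_distant_all
        if mode == "branch" and len(tb) != len(q_branches[qa]):
            return

        def branch_bond_ok(q: int) -> bool:
            if mode == "branch":
                b = qmol.GetBondBetweenAtoms(qa, q)
                return b is not None
            return any(qmol.GetBondBetweenAtoms(qa2, q) is not None for qa2 in q_adj)

        def branch_order(q: int) -> float | None:
            if mode == "branch":
                return order(qmol, qa, q)
            for qa2 in q_adj:
                if qmol.GetBondBetweenAtoms(qa2, q) is not None:
                    return order(qmol, qa2, q)
            return None

        def assign(i: int, used: set[int]) -> None:
            if i == len(tb):
                extend_branch(rest, emb)
                return
            t = tb[i]
            if t in emb:  # shared distant atom across branches (ring)
                q = emb[t]
                if branch_bond_ok(q) and order(tmol, ta, t) == branch_order(q):
                    assign(i + 1, used)
                return
            for q in qb:
                if q in used or q in emb.values():
                    continue
                if not compat(t, q):
                    continue
                if order(tmol, ta, t) != branch_order(q):
                    continue
                emb[t] = q
                assign(i + 1, used | {q})
                del emb[t]

        assign(0, set())

    def extend_adjacent(i: int, emb: dict[int, int], used: set[int]) -> None:
        if i == len(t_adj):
            pairs = [(ta, emb[ta]) for ta in t_adj]
            # template edges between adjacent atoms must exist in the query
            for a in range(len(t_adj)):
                for b in range(a + 1, len(t_adj)):
                    tb_ = tmol.GetBondBetweenAtoms(t_adj[a], t_adj[b])
                    if tb_ is None:
                        continue
                    qb_ = qmol.GetBondBetweenAtoms(emb[t_adj[a]], emb[t_adj[b]])
                    if qb_ is None or bond_order(qb_) != bond_order(tb_):
                        return
            extend_branch(pairs, emb)
            return
        ta = t_adj[i]
        for qa in q_adj:
            if qa in used:
                continue
            if not compat(ta, qa):
                continue
            if order(tmol, anchor, ta) != order(qmol, qcentre, qa):
                continue
            emb[ta] = qa
            extend_adjacent(i + 1, emb, used | {qa})
            del emb[ta]

    extend_adjacent(0, {anchor: qcentre}, set())
    # deterministic order, deduplicated
    seen = set()
    unique = []
    for emb in results:
        key = tuple(sorted(emb.items()))
        if key not in seen:
            seen.add(key)
            unique.append(emb)
    return unique


def _embed_fragment(
    frag: Fragment,
    qmol: Chem.Mol,
    attach_q: list[tuple[int, int, float]],  # (frag_atom, query attachment atom, order)
    blocked: set[int],
    use_charges: bool,
    forced: dict[int, int] | None = None,
) -> dict[int, int] | None:
    """Anchored, *terminal* embedding of a removed fragment into the query.

    Every neighbour of a matched query atom must itself be matched or be one
    of the attachment atoms, so that deleting the image severs only the
    attachment bonds.  ``forced`` pins fragment atoms whose query image is
    already fixed by the key embedding (fragment atoms sit inside the key
    neighbourhood whenever they are within two bonds of a centre).  Returns
    the first embedding in deterministic search order, or None.
    """
    atoms = list(frag.atoms)
    pos = {a: i for i, a in enumerate(atoms)}
    elements = {a: frag.elements[pos[a]] for a in atoms}
    charges = {a: frag.charges[pos[a]] for a in atoms}
    internal: dict[int, list[tuple[int, float]]] = {a: [] for a in atoms}
    for i, j, o in frag.bonds:
        internal[i].append((j, o))
        internal[j].append((i, o))
    att_by_frag: dict[int, list[tuple[int, float]]] = {}
    for fa, qa, o in attach_q:
        att_by_frag.setdefault(fa, []).append((qa, o))

    # search order: attachment-bearing atoms first, then BFS through bonds
    ordered: list[int] = []
    seenq: list[int] = sorted(att_by_frag)
    while seenq:
        a = seenq.pop(0)
        if a in ordered:
            continue
        ordered.append(a)
        seenq.extend(j for j, _ in sorted(internal[a]) if j not in ordered)
    for a in atoms:  # disconnected safety; build_rule forbids this
        if a not in ordered:
            ordered.append(a)

    emb: dict[int, int] = {}
    forced = forced or {}
    for a, q in forced.items():
        qa = qmol.GetAtomWithIdx(q)
        if qa.GetSymbol() != elements[a]:
            return None
        if use_charges and qa.GetFormalCharge() != charges[a]:
            return None
        emb[a] = q
    ordered = [a for a in ordered if a not in forced]

    def candidates(a: int) -> list[int]:
        cands: set[int] | None = None
        for qa, o in att_by_frag.get(a, []):
            near = {
                n.GetIdx()
                for n in qmol.GetAtomWithIdx(qa).GetNeighbors()
                if bond_order(qmol.GetBondBetweenAtoms(qa, n.GetIdx())) == o
            }
            cands = near if cands is None else cands & near
        for j, o in internal[a]:
            if j in emb:
                near = {
                    n.GetIdx()
                    for n in qmol.GetAtomWithIdx(emb[j]).GetNeighbors()
                    if bond_order(qmol.GetBondBetweenAtoms(emb[j], n.GetIdx())) == o
                }
                cands = near if cands is None else cands & near
        if cands is None:
            cands = set(range(qmol.GetNumAtoms()))
        return sorted(cands)

    def ok(a: int, q: int) -> bool:
        if q in blocked or q in emb.values():
            return False
        qa = qmol.GetAtomWithIdx(q)
        if qa.GetSymbol() != elements[a]:
            return False
        if use_charges and qa.GetFormalCharge() != charges[a]:
            return False
        return True

    def closure_ok() -> bool:
        image = set(emb.values())
        att_atoms = {qa for lst in att_by_frag.values() for qa, _ in lst}
        if not att_atoms.isdisjoint(image):
            return False
        for a, q in emb.items():
            expected = {emb[j] for j, _ in internal[a]} | {qa for qa, _ in att_by_frag.get(a, [])}
            actual = {n.GetIdx() for n in qmol.GetAtomWithIdx(q).GetNeighbors()}
            if actual != expected:
                return False
        return True

    def search(i: int) -> dict[int, int] | None:
        if i == len(ordered):
            return dict(emb) if closure_ok() else None
        a = ordered[i]
        for q in candidates(a):
            if not ok(a, q):
                continue
            emb[a] = q
            found = search(i + 1)
            if found is not None:
                return found
            del emb[a]
        return None

    return search(0)


def match_rule(
    query: Metabolite | Chem.Mol,
    rule: LookupRule,
    config: EngineConfig | None = None,
) -> list[QueryMatch]:
    """All consistent embeddings of the rule's units into the query.

    Multi-centre rules match only when *every* unit embeds, with mutually
    consistent atom assignments.  Matches that cannot resolve a removed
    fragment in the query are discarded.
    """
    config = config or EngineConfig()
    qmol = query.mol if isinstance(query, Metabolite) else query
    qcodes = [t.type_code for t in assign_kegg_atom_types(qmol)]
    tmol = rule.substrate_mol()

    per_unit: list[list[tuple[str, int, dict[int, int]]]] = []
    for unit in rule.units:
        options: list[tuple[str, int, dict[int, int]]] = []
        for q in range(qmol.GetNumAtoms()):
            if qcodes[q] != unit.key.centre_type:
                continue
            for emb in _embed_ball(
                tmol, rule.sub_codes, unit.anchor, qmol, qcodes, q,
                rule.use_charges, config.key_match_mode,
            ):
                options.append((unit.label, q, emb))
                if len(options) >= _MAX_UNIT_OPTIONS:
                    break
            if len(options) >= _MAX_UNIT_OPTIONS:
                break
        if not options:
            return []
        per_unit.append(options)

    raw: list[tuple[tuple[tuple[str, int], ...], dict[int, int]]] = []

    def rec(i: int, combined: dict[int, int], centres: list[tuple[str, int]]) -> None:
        if len(raw) >= _MAX_MATCHES:
            return
        if i == len(per_unit):
            raw.append((tuple(centres), dict(combined)))
            return
        for label, q, emb in per_unit[i]:
            merged = dict(combined)
            conflict = False
            for t, qq in emb.items():
                if t in merged:
                    if merged[t] != qq:
                        conflict = True
                        break
                elif qq in merged.values():
                    conflict = True
                    break
                else:
                    merged[t] = qq
            if conflict:
                continue
            rec(i + 1, merged, centres + [(label, q)])

    rec(0, {}, [])

    matches: list[QueryMatch] = []
    seen: set = set()
    for centres, combined in raw:
        removed_maps: list[tuple[tuple[int, int], ...]] = []
        feasible = True
        used_by_other_frags: set[int] = set()
        for frag in rule.fragments_removed:
            frag_atoms = set(frag.atoms)
            # Query atoms claimed by the key embedding for *retained* template
            # atoms are off limits; images of the fragment's own atoms are
            # pinned.
            blocked = {q for t, q in combined.items() if t not in frag_atoms} | used_by_other_frags
            forced = {t: q for t, q in combined.items() if t in frag_atoms}
            attach_q = []
            resolvable = True
            for att in frag.attachments:
                if att.sub_atom not in combined:
                    resolvable = False
                    break
                attach_q.append((att.frag_atom, combined[att.sub_atom], att.order))
            emb = (
                _embed_fragment(frag, qmol, attach_q, blocked, rule.use_charges, forced)
                if resolvable
                else None
            )
            if emb is None:
                feasible = False
                break
            removed_maps.append(tuple(sorted(emb.items())))
            used_by_other_frags |= set(emb.values())
        if not feasible:
            continue
        key = (centres, frozenset(q for m in removed_maps for _, q in m))
        if key in seen:
            continue
        seen.add(key)
        matches.append(
            QueryMatch(
                rule_id=rule.rule_id,
                unit_centres=centres,
                combined=tuple(sorted(combined.items())),
                removed_maps=tuple(removed_maps),
            )
        )
    return matches


def _extract_co_product(qmol: Chem.Mol, atom_ids: list[int]) -> str:
    """Canonical SMILES of the removed atoms as a free fragment (open
    valences filled with implicit hydrogens)."""
    keep = set(atom_ids)
    rw = Chem.RWMol()
    new = {}
    for a in sorted(keep):
        atom = qmol.GetAtomWithIdx(a)
        na = Chem.Atom(atom.GetSymbol())
        na.SetFormalCharge(atom.GetFormalCharge())
        na.SetIsAromatic(atom.GetIsAromatic())
        new[a] = rw.AddAtom(na)
    for bond in qmol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if i in keep and j in keep:
            rw.AddBond(new[i], new[j], bond.GetBondType())
    mol = rw.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return Chem.MolToSmiles(mol)
    return canonical_smiles(mol)


def apply_rule(
    query: Metabolite,
    rule: LookupRule,
    match: QueryMatch,
    config: EngineConfig | None = None,
) -> Prediction:
    """Generate the predicted product for one rule match.

    Raises :class:`PredictionError` (``"invalid_product"``) when the edited
    graph fails valence/aromaticity sanitisation.
    """
    config = config or EngineConfig()
    qmol = query.mol
    combined = match.combined_map
    rw = Chem.RWMol(qmol)
    track_charges = config.use_charges and rule.use_charges

    for unit in rule.units:
        if track_charges:
            for ce in unit.value.charge_edits:
                q = combined.get(ce.sub_atom)
                if q is None:
                    raise PredictionError("invalid_product", "charge edit outside match")
                atom = rw.GetAtomWithIdx(q)
                atom.SetFormalCharge(atom.GetFormalCharge() + ce.delta)
        for be in unit.value.bond_edits:
            q1, q2 = (combined.get(a) for a in be.sub_atoms)
            if q1 is None or q2 is None:
                raise PredictionError("invalid_product", "bond edit endpoint outside match")
            if be.action == "introduce":
                if rw.GetBondBetweenAtoms(q1, q2) is not None:
                    raise PredictionError("invalid_product", "introduced bond already present")
                rw.AddBond(q1, q2, bondtype_from_order(be.new_order))
            elif be.action == "delete":
                if rw.GetBondBetweenAtoms(q1, q2) is None:
                    raise PredictionError("invalid_product", "deleted bond absent")
                rw.RemoveBond(q1, q2)
            else:
                bond = rw.GetBondBetweenAtoms(q1, q2)
                if bond is None:
                    raise PredictionError("invalid_product", "changed bond absent")
                bond.SetBondType(bondtype_from_order(be.new_order))

    # fragments added: shared fragments are stored once on the rule, so each
    # is introduced exactly once regardless of how many units reference it.
    for frag in rule.fragments_added:
        new_idx: dict[int, int] = {}
        for a, el, ch in zip(frag.atoms, frag.elements, frag.charges):
            atom = Chem.Atom(el)
            if track_charges:
                atom.SetFormalCharge(ch)
            new_idx[a] = rw.AddAtom(atom)
        for i, j, o in frag.bonds:
            rw.AddBond(new_idx[i], new_idx[j], bondtype_from_order(o))
        for att in frag.attachments:
            qa = combined.get(att.sub_atom)
            if qa is None:
                raise PredictionError("invalid_product", "fragment attachment outside match")
            if rw.GetBondBetweenAtoms(qa, new_idx[att.frag_atom]) is None:
                rw.AddBond(qa, new_idx[att.frag_atom], bondtype_from_order(att.order))

    # fragments removed: delete the matched query atoms; each removed
    # component becomes a co-product.
    co_products: list[str] = []
    to_delete: list[int] = []
    for emb in match.removed_maps:
        atom_ids = [q for _, q in emb]
        co_products.append(_extract_co_product(qmol, atom_ids))
        to_delete.extend(atom_ids)
    for q in sorted(set(to_delete), reverse=True):
        rw.RemoveAtom(q)

    product = rw.GetMol()
    try:
        Chem.SanitizeMol(product)
    except Exception as exc:
        raise PredictionError("invalid_product", str(exc))
    if product.GetNumAtoms() == 0:
        raise PredictionError("invalid_product", "empty product")

    return Prediction(
        query_id=query.id,
        query_name=query.name,
        query_smiles=query.smiles,
        product_smiles=canonical_smiles(product),
        product_molblock=Chem.MolToMolBlock(product, kekulize=True),
        co_products=tuple(co_products) if config.emit_co_products else (),
        reaction_id=rule.reaction_id,
        ec=rule.ec,
        equation=rule.equation,
        rule_id=rule.rule_id,
        centre_atoms=match.centre_atoms,
    )


def predict_all(
    query: Metabolite,
    rules: list[LookupRule],
    config: EngineConfig | None = None,
    failures: list | None = None,
) -> list[Prediction]:
    """Apply every matching rule to the query.

    Predictions are deduplicated by (canonical product, template reaction)
    and returned in deterministic order (rule id, then product SMILES).
    Per-rule failures are isolated: they are logged (and appended to
    ``failures`` when given) and the batch continues.
    """
    config = config or EngineConfig()
    out: list[Prediction] = []
    seen: set[tuple[str, str]] = set()
    for rule in sorted(rules, key=lambda r: r.rule_id):
        try:
            if not similarity_prefilter(query, rule, config=config):
                continue
            for m in match_rule(query, rule, config):
                try:
                    pred = apply_rule(query, rule, m, config)
                except PredictionError as exc:
                    log.info("query %s rule %s: %s", query.id, rule.rule_id, exc)
                    if failures is not None:
                        failures.append((query.id, rule.rule_id, exc.reason))
                    continue
                key = (pred.product_smiles, pred.reaction_id)
                if key not in seen:
                    seen.add(key)
                    out.append(pred)
        except Exception as exc:  # isolate unexpected per-rule errors
            log.warning("query %s rule %s failed: %s", query.id, rule.rule_id, exc)
            if failures is not None:
                failures.append((query.id, rule.rule_id, f"error:{exc}"))
    return sorted(out, key=lambda p: (p.rule_id, p.product_smiles))


# ---------------------------------------------------------------------------
# predictions JSON (schema shipped in data/prediction_schema.json)
# ---------------------------------------------------------------------------

PREDICTIONS_SCHEMA_VERSION = 1


def predictions_to_payload(predictions: list[Prediction]) -> dict:
    return {
        "schema_version": PREDICTIONS_SCHEMA_VERSION,
        "predictions": [
            {
                "query": {"id": p.query_id, "name": p.query_name, "smiles": p.query_smiles},
                "product": {"smiles": p.product_smiles, "molblock": p.product_molblock},
                "co_products": list(p.co_products),
                "template": {"reaction_id": p.reaction_id, "ec": list(p.ec), "equation": p.equation},
                "rule_id": p.rule_id,
                "centre_atoms": list(p.centre_atoms),
            }
            for p in predictions
        ],
    }


def validate_predictions_payload(payload: dict) -> None:
    """Validate the predictions payload against the shipped schema document.

    Minimal structural validation (required keys and primitive types);
    raises ValueError on the first violation.
    """
    if not isinstance(payload, dict):
        raise ValueError("payload must be an object")
    if payload.get("schema_version") != PREDICTIONS_SCHEMA_VERSION:
        raise ValueError("bad or missing schema_version")
    preds = payload.get("predictions")
    if not isinstance(preds, list):
        raise ValueError("predictions must be an array")
    for i, p in enumerate(preds):
        for section, keys in (
            ("query", ("id", "name", "smiles")),
            ("product", ("smiles", "molblock")),
            ("template", ("reaction_id", "ec", "equation")),
        ):
            obj = p.get(section)
            if not isinstance(obj, dict):
                raise ValueError(f"predictions[{i}].{section} missing")
            for k in keys:
                if k not in obj:
                    raise ValueError(f"predictions[{i}].{section}.{k} missing")
        if not isinstance(p.get("co_products"), list):
            raise ValueError(f"predictions[{i}].co_products missing")
        if not isinstance(p.get("rule_id"), str):
            raise ValueError(f"predictions[{i}].rule_id missing")
        if not isinstance(p.get("centre_atoms"), list):
            raise ValueError(f"predictions[{i}].centre_atoms missing")


def write_predictions_json(predictions: list[Prediction], path: str | Path) -> None:
    payload = predictions_to_payload(predictions)
    validate_predictions_payload(payload)
    Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1) + "\n")


def load_predictions_json(path: str | Path) -> dict:
    payload = json.loads(Path(path).read_text())
    validate_predictions_payload(payload)
    return payload
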