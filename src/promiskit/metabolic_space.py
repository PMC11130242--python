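"""Metabolic-space construction.

Parses a reaction table, resolves metabolite structures from local sources,
strips cofactors and drops reactions that lose a whole side, yielding the
*simplified* reactions that drive rule induction.  Every reaction that is
dropped or rewritten carries a machine-readable record, so the bookkeeping
identity ``|input| = |simplified| + |dropped|`` always holds.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
from rdkit import Chem

from .chem import StructureError, bond_order, canonical_smiles, mol_from_smiles
from .config import EngineConfig


@dataclass(frozen=True)
class Metabolite:
    """An identified molecular structure.

    ``mol`` is the RDKit molecular graph (elements, formal charges, bond
    orders, ring/aromatic perception); ``smiles`` is its canonical,
    stereo-stripped line notation.
    """

    id: str
    name: str
    mol: Chem.Mol
    smiles: str
    source: str = ""

    @classmethod
    def from_smiles(cls, id: str, smiles: str, name: str = "", source: str = "") -> "Metabolite":
        mol = mol_from_smiles(smiles)
        return cls(id=id, name=name or id, mol=mol, smiles=canonical_smiles(mol), source=source)

    @property
    def graph(self) -> nx.Graph:
        """The molecular graph as a networkx Graph (atoms as nodes)."""
        g = nx.Graph()
        for atom in self.mol.GetAtoms():
            g.add_node(
                atom.GetIdx(),
                element=atom.GetSymbol(),
                charge=atom.GetFormalCharge(),
                aromatic=atom.GetIsAromatic(),
                in_ring=atom.IsInRing(),
            )
        for bond in self.mol.GetBonds():
            g.add_edge(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(), order=bond_order(bond))
        return g


@dataclass(frozen=True)
class Reaction:
    id: str
    ec: tuple[str, ...]
    substrates: tuple[str, ...]
    products: tuple[str, ...]
    equation_text: str = ""

    def replace_sides(self, substrates, products) -> "Reaction":
        return Reaction(self.id, self.ec, tuple(substrates), tuple(products), self.equation_text)


@dataclass(frozen=True)
class RowError:
    """A malformed input row, reported instead of silently dropped."""

    row: int
    reaction_id: str
    reason: str


@dataclass(frozen=True)
class DropRecord:
    """A reaction removed during simplification, with the stage and reason."""

    reaction_id: str
    stage: str  # "cofactor_removal" | "structure_filter"
    reason: str


_ARROW = re.compile(r"<=>|=>|->|<->|=")
_COEFF = re.compile(r"^\(?\d+(\.\d+)?\)?\s+")


def parse_equation(text: str) -> tuple[list[str], list[str]]:
    """Split ``"A + B -> C"`` into substrate and product id lists.

    Stoichiometric coefficients (``2 H2O``) are ignored: the method is
    structural and only cares about presence.
    """
    parts = _ARROW.split(text, maxsplit=1)
    if len(parts) != 2:
        raise ValueError(f"equation has no arrow: {text!r}")

    def side(s: str) -> list[str]:
        ids = []
        for token in s.split(" + "):
            token = _COEFF.sub("", token.strip())
            if token:
                ids.append(token)
        return ids

    return side(parts[0]), side(parts[1])


def load_reaction_table(
    path: str | Path, dialect: str = "tsv"
) -> tuple[list[Reaction], list[RowError]]:
    """Read a reaction table (columns: id, ec, equation).

    Direction is preserved as written.  Malformed rows are returned as
    :class:`RowError` records rather than raising.
    """
    if dialect not in ("tsv", "csv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    delim = "\t" if dialect == "tsv" else ","
    reactions: list[Reaction] = []
    errors: list[RowError] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        for i, row in enumerate(reader, start=2):
            rid = (row.get("id") or "").strip()
            if not rid:
                errors.append(RowError(i, "", "missing reaction id"))
                continue
            ec = tuple(e.strip() for e in (row.get("ec") or "").split(";") if e.strip())
            equation = (row.get("equation") or "").strip()
            try:
                subs, prods = parse_equation(equation)
            except ValueError as exc:
                errors.append(RowError(i, rid, str(exc)))
                continue
            if not subs or not prods:
                errors.append(RowError(i, rid, "equation side is empty"))
                continue
            reactions.append(Reaction(rid, ec, tuple(subs), tuple(prods), equation))
    return reactions, errors


def load_smiles_table(path: str | Path, source: str = "") -> dict[str, str]:
    """TSV id -> SMILES (optional third column: name)."""
    table: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header and header[0].lower() != "id":
            fh.seek(0)
            reader = csv.reader(fh, delimiter="\t")
        for row in reader:
            if len(row) >= 2 and row[0].strip():
                table.setdefault(row[0].strip(), row[1].strip())
    return table


def load_sdf(path: str | Path, id_prop: str = "id") -> dict[str, str]:
    """SDF with the metabolite id in a named property field -> SMILES map."""
    table: dict[str, str] = {}
    for mol in Chem.SDMolSupplier(str(path), sanitize=True):
        if mol is None or not mol.HasProp(id_prop):
            continue
        table.setdefault(mol.GetProp(id_prop), canonical_smiles(mol))
    return table


def resolve_structures(
    metabolite_ids: list[str],
    structure_sources: list[dict[str, str] | str | Path],
    names: dict[str, str] | None = None,
) -> tuple[dict[str, Metabolite], dict[str, str]]:
    """Resolve ids to structures; the first source containing an id wins.

    Sources are in-memory ``{id: smiles}`` maps or paths to SMILES-table TSV
    / SDF files.  Returns (resolved, unresolved-with-reason).
    """
    tables: list[tuple[str, dict[str, str]]] = []
    for i, src in enumerate(structure_sources):
        if isinstance(src, (str, Path)):
            label = str(src)
            table = load_sdf(src) if str(src).endswith(".sdf") else load_smiles_table(src)
        else:
            label, table = f"source_{i}", src
        tables.append((label, table))

    resolved: dict[str, Metabolite] = {}
    unresolved: dict[str, str] = {}
    names = names or {}
    for mid in metabolite_ids:
        for label, table in tables:
            if mid in table:
                try:
                    resolved[mid] = Metabolite.from_smiles(
                        mid, table[mid], name=names.get(mid, mid), source=label
                    )
                except StructureError as exc:
                    unresolved[mid] = f"unparsable structure: {exc}"
                break
        else:
            unresolved[mid] = "no structure in any source"
    return resolved, unresolved


def remove_cofactors(
    reaction: Reaction, cofactors: frozenset[str] | set[str]
) -> tuple[Reaction | None, DropRecord | None]:
    """Strip cofactor ids from both sides; drop the reaction if a side empties."""
    subs = [m for m in reaction.substrates if m not in cofactors]
    prods = [m for m in reaction.products if m not in cofactors]
    if not subs or not prods:
        return None, DropRecord(reaction.id, "cofactor_removal", "side empty after cofactor removal")
    return reaction.replace_sides(subs, prods), None


def filter_unstructured(
    reactions: list[Reaction], resolved: dict[str, Metabolite]
) -> tuple[list[Reaction], list[DropRecord]]:
    """Remove unresolved metabolite ids; delete reactions losing a side."""
    kept: list[Reaction] = []
    dropped: list[DropRecord] = []
    for rxn in reactions:
        subs = [m for m in rxn.substrates if m in resolved]
        prods = [m for m in rxn.products if m in resolved]
        if not subs or not prods:
            dropped.append(DropRecord(rxn.id, "structure_filter", "side empty after structure filter"))
        else:
            kept.append(rxn.replace_sides(subs, prods))
    return kept, dropped


@dataclass
class MetabolicSpace:
    """Simplified reactions plus their resolved structures and drop records."""

    reactions: list[Reaction]
    metabolites: dict[str, Metabolite]
    dropped: list[DropRecord] = field(default_factory=list)
    unresolved: dict[str, str] = field(default_factory=dict)
    n_input_reactions: int = 0

    @classmethod
    def build(
        cls,
        reactions: list[Reaction],
        structure_sources: list[dict[str, str] | str | Path],
        config: EngineConfig | None = None,
        names: dict[str, str] | None = None,
    ) -> "MetabolicSpace":
        """Run the full simplification: cofactor removal then structure filter."""
        config = config or EngineConfig()
        n_input = len(reactions)
        simplified: list[Reaction] = []
        dropped: list[DropRecord] = []
        for rxn in reactions:
            kept, drop = remove_cofactors(rxn, config.cofactors)
            if drop:
                dropped.append(drop)
            else:
                simplified.append(kept)

        ids = sorted({m for r in simplified for m in (*r.substrates, *r.products)})
        resolved, unresolved = resolve_structures(ids, structure_sources, names=names)
        simplified, dropped2 = filter_unstructured(simplified, resolved)
        dropped.extend(dropped2)

        used = {m for r in simplified for m in (*r.substrates, *r.products)}
        return cls(
            reactions=simplified,
            metabolites={k: v for k, v in resolved.items() if k in used},
            dropped=dropped,
            unresolved=unresolved,
            n_input_reactions=n_input,
        )
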