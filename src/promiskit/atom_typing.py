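"""KEGG atom typing.

Every heavy atom of a molecule is classified into a KEGG atom-type code
(``C8x``, ``O1a``, ...), the per-atom vocabulary in which reaction-rule keys
and values are expressed.  The code captures an atom's element and local
functional environment, so a chemical transformation shows up as a code
change on the atoms it touches.

The classification is data-driven: ``data/kegg_atom_types.tsv`` holds one
SMARTS environment pattern per code, evaluated in priority order; the first
pattern whose *first atom* matches wins.  Charged atoms receive the code of
their neutral environment — formal charge is carried separately in
:class:`TypedAtom` and handled by the rule machinery's charge tracking.

Elements or environments outside the table receive a deterministic fallback
code ``X:<element>:<hash of radius-1 environment>`` so that typing never
fails and distinct environments remain distinguishable.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

from rdkit import Chem

from .chem import bond_order


@dataclass(frozen=True)
class TypedAtom:
    atom_index: int
    type_code: str
    element: str
    charge: int


@dataclass(frozen=True)
class TypingRule:
    priority: int
    code: str
    element: str
    smarts: str


@lru_cache(maxsize=1)
def load_typing_rules() -> tuple[TypingRule, ...]:
    """The versioned typing rule table shipped with the package."""
    text = resources.files("promiskit.data").joinpath("kegg_atom_types.tsv").read_text()
    rules = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        prio, code, element, smarts = line.split("\t")
        rules.append(TypingRule(int(prio), code, element, smarts))
    return tuple(sorted(rules, key=lambda r: r.priority))


@lru_cache(maxsize=1)
def _compiled_rules() -> tuple[tuple[TypingRule, Chem.Mol], ...]:
    compiled = []
    for rule in load_typing_rules():
        patt = Chem.MolFromSmarts(rule.smarts)
        if patt is None:  # pragma: no cover - table is validated by tests
            raise ValueError(f"bad SMARTS in typing table: {rule.smarts}")
        compiled.append((rule, patt))
    return tuple(compiled)


def _radius1_signature(atom: Chem.Atom) -> str:
    nbrs = sorted(
        (n.GetSymbol(), bond_order(atom.GetOwningMol().GetBondBetweenAtoms(atom.GetIdx(), n.GetIdx())))
        for n in atom.GetNeighbors()
    )
    return repr(
        (
            atom.GetSymbol(),
            atom.GetFormalCharge(),
            atom.GetTotalNumHs(),
            atom.GetIsAromatic(),
            atom.IsInRing(),
            nbrs,
        )
    )


def _fallback_code(atom: Chem.Atom) -> str:
    digest = hashlib.sha1(_radius1_signature(atom).encode()).hexdigest()[:8]
    return f"X:{atom.GetSymbol()}:{digest}"


def assign_kegg_atom_types(mol: Chem.Mol) -> list[TypedAtom]:
    """Classify every heavy atom of ``mol`` into a KEGG atom-type code.

    Deterministic and independent of atom input order (SMARTS environment
    matching sees only the graph).  Unknown environments fall back to a
    hashed code rather than raising.
    """
    n = mol.GetNumAtoms()
    codes: dict[int, str] = {}
    for rule, patt in _compiled_rules():
        if len(codes) == n:
            break
        for match in mol.GetSubstructMatches(patt, uniquify=False, maxMatches=10 * n + 100):
            idx = match[0]
            if idx not in codes:
                codes[idx] = rule.code
    typed = []
    for atom in mol.GetAtoms():
        idx = atom.GetIdx()
        code = codes.get(idx) or _fallback_code(atom)
        typed.append(TypedAtom(idx, code, atom.GetSymbol(), atom.GetFormalCharge()))
    return typed


def type_codes(mol: Chem.Mol) -> list[str]:
    """Just the per-atom code strings, indexed by atom index."""
    return [t.type_code for t in assign_kegg_atom_types(mol)]
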