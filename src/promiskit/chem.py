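"""Small RDKit helpers shared across the pipeline.

Stereochemistry is ignored throughout: structures are compared as flat
molecular graphs (canonical SMILES without stereo descriptors).
"""

from __future__ import annotations

from rdkit import Chem, RDLogger

# RDKit is chatty about valence problems we handle ourselves.
RDLogger.DisableLog("rdApp.*")


class StructureError(ValueError):
    """A structure string could not be parsed into a valid molecule."""


def mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(f"unparsable SMILES: {smiles!r}")
    Chem.RemoveStereochemistry(mol)
    return mol


def mol_from_molblock(block: str) -> Chem.Mol:
    mol = Chem.MolFromMolBlock(block)
    if mol is None:
        raise StructureError("unparsable MOL block")
    Chem.RemoveStereochemistry(mol)
    return mol


def canonical_smiles(mol: Chem.Mol) -> str:
    """Canonical SMILES with stereochemistry stripped."""
    flat = Chem.Mol(mol)
    Chem.RemoveStereochemistry(flat)
    return Chem.MolToSmiles(flat)


def canonicalize_smiles(smiles: str) -> str:
    return canonical_smiles(mol_from_smiles(smiles))


def same_structure(a: str | Chem.Mol, b: str | Chem.Mol) -> bool:
    """Stereo-agnostic structural identity of two molecules."""
    sa = canonicalize_smiles(a) if isinstance(a, str) else canonical_smiles(a)
    sb = canonicalize_smiles(b) if isinstance(b, str) else canonical_smiles(b)
    return sa == sb


def bond_order(bond: Chem.Bond) -> float:
    """Bond order as a number; aromatic bonds are 1.5."""
    return bond.GetBondTypeAsDouble()


_ORDER_TO_BONDTYPE = {
    1.0: Chem.BondType.SINGLE,
    1.5: Chem.BondType.AROMATIC,
    2.0: Chem.BondType.DOUBLE,
    3.0: Chem.BondType.TRIPLE,
}


def bondtype_from_order(order: float) -> Chem.BondType:
    try:
        return _ORDER_TO_BONDTYPE[float(order)]
    except KeyError:
        raise ValueError(f"unsupported bond order {order}")
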