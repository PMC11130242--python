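"""Worked-example and synthetic fixture spaces.

``builtin_examples`` packages the small panel of real transformations used
throughout the documentation and tests: the aromatic hydroxylation
4-hydroxybenzoate → 3,4-dihydroxybenzoate (KEGG R01296, applied to
L-tyrosine it yields 3,4-dihydroxy-L-phenylalanine), the two-centre amino
mutase reaction L-leucine → (3R)-beta-leucine (R01091), the glucuronidase
cleavage of phloretin 2'-O-glucuronide, the amide hydrolysis of
4-hydroxyhippurate, and an O-methylation of the lignan isolariciresinol.
Structure strings are encoded once here, from the compound names.

.. note::
   The product of the isolariciresinol reaction is a *synthetic stand-in*
   (4'-O-methyl-isolariciresinol): the natural product reported for this
   transformation has no structure in any local source, so the fixture
   exercises the same rule chemistry (an O-methylation on the lignan
   scaffold) with a constructed product.

``generate_synthetic_space`` emits toy reaction sets whose ground-truth
products are constructed by direct graph editing of random scaffolds — by
construction, a correct engine must reach 100% self-recovery on them.  The
edit vocabulary covers every rule-unit variety: fragment addition
(hydroxylation, O-methylation), fragment removal (deglucuronidation),
multi-product hydrolysis (amide), bond-order change and charge toggling.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from rdkit import Chem

from .chem import canonical_smiles, canonicalize_smiles, mol_from_smiles
from .config import EngineConfig
from .metabolic_space import MetabolicSpace, Reaction


@dataclass
class FixtureSet:
    """A self-contained reaction table + structure table + expectations."""

    metabolites: dict[str, str]  # id -> canonical SMILES
    names: dict[str, str]
    reactions: list[Reaction]
    expected: dict[str, dict] = field(default_factory=dict)

    def build_space(self, config: EngineConfig | None = None) -> MetabolicSpace:
        return MetabolicSpace.build(self.reactions, [self.metabolites], config, names=self.names)

    def to_files(self, directory: str | Path) -> tuple[Path, Path]:
        """Write reactions.tsv and structures.tsv (the formats consumed by
        the metabolic-space loader); byte-identical for identical content."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        rpath = directory / "reactions.tsv"
        spath = directory / "structures.tsv"
        with open(rpath, "w") as fh:
            fh.write("id\tec\tequation\n")
            for r in self.reactions:
                fh.write(f"{r.id}\t{';'.join(r.ec)}\t{r.equation_text}\n")
        with open(spath, "w") as fh:
            fh.write("id\tsmiles\tname\n")
            for mid in sorted(self.metabolites):
                fh.write(f"{mid}\t{self.metabolites[mid]}\t{self.names.get(mid, mid)}\n")
        return rpath, spath


# ---------------------------------------------------------------------------
# in-repo worked examples
# ---------------------------------------------------------------------------

_BUILTIN_SMILES = {
    "4-Hydroxybenzoate": "OC(=O)c1ccc(O)cc1",
    "3,4-Dihydroxybenzoate": "OC(=O)c1ccc(O)c(O)c1",
    "L-Leucine": "CC(C)CC(N)C(O)=O",
    "(3R)-beta-Leucine": "CC(C)C(N)CC(O)=O",
    "L-Tyrosine": "NC(Cc1ccc(O)cc1)C(O)=O",
    "3,4-Dihydroxy-L-phenylalanine": "NC(Cc1ccc(O)c(O)c1)C(O)=O",
    "p-Cresol": "Cc1ccc(O)cc1",
    "Phloretin": "Oc1ccc(CCC(=O)c2c(O)cc(O)cc2O)cc1",
    "Phloretin-2'-O-glucuronide": "OC(=O)C1OC(Oc2cc(O)cc(O)c2C(=O)CCc2ccc(O)cc2)C(O)C(O)C1O",
    "Glucuronate": "OC(=O)C1OC(O)C(O)C(O)C1O",
    "4-Hydroxyhippurate": "OC(=O)CNC(=O)c1ccc(O)cc1",
    "Glycine": "NCC(O)=O",
    "Isolariciresinol": "COc1cc2c(cc1O)CC(CO)C(CO)C2c1ccc(O)c(OC)c1",
    # synthetic stand-in product (4'-O-methyl-isolariciresinol)
    "Scaphopetalone": "COc1cc2c(cc1OC)CC(CO)C(CO)C2c1ccc(O)c(OC)c1",
}

_BUILTIN_REACTIONS = [
    ("R01296", "1.14.13.2", "4-Hydroxybenzoate + O2 + NADH + H(+) -> 3,4-Dihydroxybenzoate + H2O + NAD(+)"),
    ("R01091", "5.4.3.7", "L-Leucine -> (3R)-beta-Leucine"),
    ("GLCRD1", "3.2.1.31", "Phloretin-2'-O-glucuronide + H2O -> Phloretin + Glucuronate"),
    ("AMHYD1", "3.5.1.32", "4-Hydroxyhippurate + H2O -> Glycine + 4-Hydroxybenzoate"),
    ("LIGOMT1", "2.1.1.-", "Isolariciresinol + SAM -> Scaphopetalone + SAH"),
]


def builtin_examples() -> FixtureSet:
    """The packaged worked-example space (see module docstring)."""
    mets = {k: canonicalize_smiles(v) for k, v in _BUILTIN_SMILES.items()}
    reactions = []
    from .metabolic_space import parse_equation

    for rid, ec, eq in _BUILTIN_REACTIONS:
        subs, prods = parse_equation(eq)
        reactions.append(Reaction(rid, (ec,), tuple(subs), tuple(prods), eq))
    expected = {
        "R01296": {
            "centres": 1,
            "products": {
                "L-Tyrosine": [mets["3,4-Dihydroxy-L-phenylalanine"]],
                "p-Cresol": [canonicalize_smiles("Cc1ccc(O)c(O)c1")],
            },
        },
        "R01091": {"centres": 2, "products": {}},
        "GLCRD1": {"centres": None, "products": {}},
        "AMHYD1": {"centres": None, "products": {}},
        "LIGOMT1": {"centres": None, "products": {}},
    }
    return FixtureSet(mets, {k: k for k in mets}, reactions, expected)


# ---------------------------------------------------------------------------
# synthetic spaces with ground truth by construction
# ---------------------------------------------------------------------------

EDIT_TYPES = (
    "hydroxylation",
    "o_methylation",
    "deglucuronidation",
    "amide_hydrolysis",
    "bond_order_change",
    "charge_toggle",
)

_GLUCURONYL = "C1OC(C(=O)O)C(O)C(O)C1O"  # anomeric carbon first


def _graft(mol: Chem.Mol, atom_idx: int, frag_smiles: str, attach_pos: int = 0) -> Chem.Mol:
    """Attach a fragment to ``atom_idx`` with a single bond and sanitise."""
    frag = Chem.MolFromSmiles(frag_smiles)
    combo = Chem.RWMol(Chem.CombineMols(mol, frag))
    combo.AddBond(atom_idx, mol.GetNumAtoms() + attach_pos, Chem.BondType.SINGLE)
    out = combo.GetMol()
    Chem.SanitizeMol(out)
    return out


def _aromatic_ch_indices(mol: Chem.Mol) -> list[int]:
    return [a.GetIdx() for a in mol.GetAtoms() if a.GetIsAromatic() and a.GetTotalNumHs() > 0]


def _hydroxyl_indices(mol: Chem.Mol) -> list[int]:
    return [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetSymbol() == "O" and a.GetTotalNumHs() == 1 and a.GetDegree() == 1
        and not any(n.GetSymbol() == "C" and any(b.GetBondTypeAsDouble() == 2 for b in n.GetBonds()) for n in a.GetNeighbors())
    ]


def _random_aromatic_scaffold(rng: random.Random, need_phenol: bool = False) -> Chem.Mol:
    mol = mol_from_smiles("c1ccccc1")
    options = ["C", "CC", "Cl", "OC", "O"]
    for _ in range(rng.randint(0, 2)):
        sites = _aromatic_ch_indices(mol)
        if len(sites) <= 2:
            break
        mol = _graft(mol, rng.choice(sites), rng.choice(options))
    if need_phenol and not _hydroxyl_indices(mol):
        mol = _graft(mol, rng.choice(_aromatic_ch_indices(mol)), "O")
    return mol


def _random_aliphatic_scaffold(rng: random.Random) -> Chem.Mol:
    n = rng.randint(3, 6)
    smi = "C" * n
    mol = mol_from_smiles(smi)
    if rng.random() < 0.5:
        mol = _graft(mol, rng.randrange(n), "C")
    return mol


def _make_edit(edit: str, rng: random.Random) -> tuple[Chem.Mol, list[Chem.Mol], int | None]:
    """Return (substrate, ground-truth products, expected centre count)."""
    if edit == "hydroxylation":
        sub = _random_aromatic_scaffold(rng)
        pos = rng.choice(_aromatic_ch_indices(sub))
        return sub, [_graft(sub, pos, "O")], 1
    if edit == "o_methylation":
        sub = _random_aromatic_scaffold(rng, need_phenol=True)
        pos = rng.choice(_hydroxyl_indices(sub))
        return sub, [_graft(sub, pos, "C")], 1
    if edit == "deglucuronidation":
        base = _random_aromatic_scaffold(rng, need_phenol=True)
        pos = rng.choice(_hydroxyl_indices(base))
        sub = _graft(base, pos, _GLUCURONYL)
        return sub, [base], 1
    if edit == "amide_hydrolysis":
        base = _random_aromatic_scaffold(rng)
        pos = rng.choice(_aromatic_ch_indices(base))
        sub = _graft(base, pos, "C(=O)NCC(=O)O")
        acid = _graft(base, pos, "C(=O)O")
        glycine = mol_from_smiles("NCC(O)=O")
        return sub, [acid, glycine], None
    if edit == "bond_order_change":
        base = _random_aromatic_scaffold(rng) if rng.random() < 0.5 else _random_aliphatic_scaffold(rng)
        sites = _aromatic_ch_indices(base) or [0]
        pos = rng.choice(sites)
        sub = _graft(base, pos, "C=C")
        prod = _graft(base, pos, "CC")
        return sub, [prod], 2
    if edit == "charge_toggle":
        base = _random_aromatic_scaffold(rng) if rng.random() < 0.5 else _random_aliphatic_scaffold(rng)
        sites = _aromatic_ch_indices(base) or [0]
        pos = rng.choice(sites)
        sub = _graft(base, pos, "C(=O)O")
        prod = _graft(base, pos, "C(=O)[O-]")
        return sub, [prod], 0
    raise ValueError(f"unknown edit type {edit!r}")


def generate_synthetic_space(
    n_reactions: int,
    edit_types: tuple[str, ...] | list[str] = EDIT_TYPES,
    seed: int = 0,
) -> FixtureSet:
    """Random single-edit reactions over decorated benzene / aliphatic
    scaffolds; self-recovery accuracy is 1.0 by construction.

    Deterministic under a fixed seed (byte-identical ``to_files`` output).
    """
    if n_reactions < 1:
        raise ValueError("n_reactions must be >= 1")
    bad = set(edit_types) - set(EDIT_TYPES)
    if bad:
        raise ValueError(f"unknown edit types: {sorted(bad)}")
    rng = random.Random(seed)
    edit_types = sorted(edit_types)

    metabolites: dict[str, str] = {}
    names: dict[str, str] = {}
    reactions: list[Reaction] = []
    expected: dict[str, dict] = {}
    for i in range(n_reactions):
        edit = edit_types[i % len(edit_types)] if n_reactions >= len(edit_types) else rng.choice(edit_types)
        sub, prods, centres = _make_edit(edit, rng)
        sid = f"SYNM{2 * i + 1:04d}"
        metabolites[sid] = canonical_smiles(sub)
        names[sid] = f"{edit} substrate {i}"
        pids = []
        for j, prod in enumerate(prods):
            pid = f"SYNM{2 * i + 2:04d}" + (f"_{j}" if len(prods) > 1 else "")
            metabolites[pid] = canonical_smiles(prod)
            names[pid] = f"{edit} product {i}.{j}"
            pids.append(pid)
        rid = f"SYNR{i:04d}"
        equation = f"{sid} -> {' + '.join(pids)}"
        reactions.append(Reaction(rid, ("9.9.9.9",), (sid,), tuple(pids), equation))
        expected[rid] = {
            "edit": edit,
            "centres": centres,
            "products": {sid: [metabolites[p] for p in pids]},
        }
    return FixtureSet(metabolites, names, reactions, expected)
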