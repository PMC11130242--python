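"""Substrate-product pairing by chemical similarity.

A simplified reaction can carry several substrates and products; rules are
induced from one substrate-product pair at a time.  Pairs are formed
greedily on descending Morgan-fingerprint Dice similarity (ties broken by
lexicographic id), and leftovers on the larger side are attached to their
most similar counterpart, so every species with a structure appears in at
least one pair.  A single substrate (or product) is paired with each member
of the other side.
"""

from __future__ import annotations

from dataclasses import dataclass

from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

from .config import EngineConfig
from .metabolic_space import Metabolite, Reaction

_generators: dict[tuple[int, int], object] = {}


def _generator(radius: int, nbits: int):
    key = (radius, nbits)
    if key not in _generators:
        _generators[key] = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=nbits)
    return _generators[key]


def fingerprint(mol: Chem.Mol | Metabolite, radius: int = 2, nbits: int = 2048, counts: bool = True):
    """Morgan (circular) fingerprint as a fixed-length vector.

    Deterministic for a given canonical structure; defaults radius 2, 2048
    slots.  The default is the count (frequency) variant — the classic
    Morgan + Dice combination, under which e.g. L-tyrosine clears the 0.6
    prefilter against 4-hydroxybenzoate; ``counts=False`` gives the plain
    bit vector.
    """
    if isinstance(mol, Metabolite):
        mol = mol.mol
    gen = _generator(radius, nbits)
    return gen.GetCountFingerprint(mol) if counts else gen.GetFingerprint(mol)


def dice_similarity(a, b) -> float:
    """Dice coefficient 2|A∩B| / (|A|+|B|) on fingerprint bits."""
    return DataStructs.DiceSimilarity(a, b)


def molecule_similarity(a: Chem.Mol | Metabolite, b: Chem.Mol | Metabolite, config: EngineConfig | None = None) -> float:
    config = config or EngineConfig()
    fa = fingerprint(a, config.fingerprint_radius, config.fingerprint_bits, config.fingerprint_counts)
    fb = fingerprint(b, config.fingerprint_radius, config.fingerprint_bits, config.fingerprint_counts)
    return dice_similarity(fa, fb)


@dataclass(frozen=True)
class ReactantPair:
    reaction_id: str
    substrate_id: str
    product_id: str
    similarity: float


def pair_reactants(
    reaction: Reaction,
    space: dict[str, Metabolite],
    config: EngineConfig | None = None,
) -> list[ReactantPair]:
    """Pair the reaction's substrates and products by Dice similarity.

    Greedy one-to-one assignment on the sorted similarity matrix; leftover
    species on the larger side are then paired many-to-one with their most
    similar counterpart.  Permutation-invariant: ties are broken by
    (substrate id, product id) lexicographic order.
    """
    config = config or EngineConfig()
    subs = sorted(set(reaction.substrates))
    prods = sorted(set(reaction.products))
    if not subs or not prods:
        raise ValueError(f"reaction {reaction.id} has an empty side")
    missing = [m for m in (*subs, *prods) if m not in space]
    if missing:
        raise KeyError(f"reaction {reaction.id}: unresolved metabolites {missing}")

    fps = {
        m: fingerprint(space[m], config.fingerprint_radius, config.fingerprint_bits, config.fingerprint_counts)
        for m in {*subs, *prods}
    }
    sim = {(s, p): dice_similarity(fps[s], fps[p]) for s in subs for p in prods}

    cells = sorted(sim.items(), key=lambda kv: (-kv[1], kv[0][0], kv[0][1]))
    used_s: set[str] = set()
    used_p: set[str] = set()
    pairs: list[ReactantPair] = []
    for (s, p), value in cells:
        if s in used_s or p in used_p:
            continue
        pairs.append(ReactantPair(reaction.id, s, p, value))
        used_s.add(s)
        used_p.add(p)

    # Many-to-one for the larger side's leftovers.
    for s in subs:
        if s not in used_s:
            p = max(prods, key=lambda p: (sim[(s, p)], p))
            p = min((q for q in prods if sim[(s, q)] == sim[(s, p)]), key=str)
            pairs.append(ReactantPair(reaction.id, s, p, sim[(s, p)]))
    for p in prods:
        if p not in used_p:
            s = max(subs, key=lambda s: (sim[(s, p)], s))
            s = min((t for t in subs if sim[(t, p)] == sim[(s, p)]), key=str)
            pairs.append(ReactantPair(reaction.id, s, p, sim[(s, p)]))

    return sorted(pairs, key=lambda pr: (pr.substrate_id, pr.product_id))


def pairs_to_tsv(pairs: list[ReactantPair], path) -> None:
    with open(path, "w") as fh:
        fh.write("reaction_id\tsubstrate_id\tproduct_id\tsimilarity\n")
        for p in pairs:
            fh.write(f"{p.reaction_id}\t{p.substrate_id}\t{p.product_id}\t{p.similarity:.6f}\n")
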