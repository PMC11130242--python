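"""Atom alignment of a substrate-product pair via their maximum common
substructure.

The MCS is computed with two chemistry-motivated constraints, both on by
default: a ring atom may only match a ring atom, and matched atoms must carry
the same formal charge.  Bond orders are deliberately *not* compared inside
the MCS — an order change within the conserved core (e.g. a double bond
becoming single) must stay inside the alignment so it can later be detected
as a bond rearrangement.

The MCS pattern usually embeds into both molecules in several symmetric
ways; a single embedding is chosen deterministically as the one minimising
the lexicographic sequence of (substrate index, product index) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem
from rdkit.Chem import rdFMCS

from .config import EngineConfig

#: Cap on (substrate x product) embedding combinations examined when picking
#: the deterministic representative.  Enumeration order is deterministic, so
#: the selected embedding is stable even when the cap bites.
_MAX_COMBINATIONS = 200_000


class AlignmentError(RuntimeError):
    """MCS alignment failed; ``reason`` is machine-readable."""

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}{': ' + detail if detail else ''}")


@dataclass(frozen=True)
class AtomAlignment:
    """Injective atom mapping between a substrate and a product."""

    mapping: tuple[tuple[int, int], ...]
    unmapped_substrate: tuple[int, ...]
    unmapped_product: tuple[int, ...]
    mcs_size: int

    @property
    def sub_to_prod(self) -> dict[int, int]:
        return dict(self.mapping)

    @property
    def prod_to_sub(self) -> dict[int, int]:
        return {p: s for s, p in self.mapping}

    def to_json_dict(self) -> dict:
        return {
            "mapping": [list(p) for p in self.mapping],
            "unmapped_substrate": list(self.unmapped_substrate),
            "unmapped_product": list(self.unmapped_product),
            "mcs_size": self.mcs_size,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "AtomAlignment":
        return cls(
            tuple((s, p) for s, p in d["mapping"]),
            tuple(d["unmapped_substrate"]),
            tuple(d["unmapped_product"]),
            d["mcs_size"],
        )


def _mcs_params(config: EngineConfig) -> rdFMCS.MCSParameters:
    ps = rdFMCS.MCSParameters()
    ps.AtomTyper = rdFMCS.AtomCompare.CompareElements
    ps.BondTyper = rdFMCS.BondCompare.CompareAny
    ps.AtomCompareParameters.MatchFormalCharge = config.match_formal_charge
    ps.AtomCompareParameters.RingMatchesRingOnly = config.ring_matches_ring
    # Maximise atom count (not bond count): the alignment's figure of merit
    # is the number of atoms carried over from substrate to product.
    ps.MaximizeBonds = False
    ps.Timeout = config.mcs_timeout
    return ps


def _embedding_ok(sub: Chem.Mol, prod: Chem.Mol, s_match, p_match, config: EngineConfig) -> bool:
    for si, pi in zip(s_match, p_match):
        sa = sub.GetAtomWithIdx(si)
        pa = prod.GetAtomWithIdx(pi)
        if sa.GetSymbol() != pa.GetSymbol():
            return False
        if config.match_formal_charge and sa.GetFormalCharge() != pa.GetFormalCharge():
            return False
        if config.ring_matches_ring and sa.IsInRing() != pa.IsInRing():
            return False
    return True


def compute_mcs_alignment(
    sub: Chem.Mol, prod: Chem.Mol, config: EngineConfig | None = None
) -> AtomAlignment:
    """Align substrate and product atoms over their MCS.

    Raises
    ------
    AlignmentError
        ``"mcs_timeout"`` when the search exceeds the configured budget,
        ``"no_common_substructure"`` when the MCS is empty, and
        ``"no_consistent_embedding"`` when no embedding satisfies the ring
        and charge constraints (not expected in practice).
    """
    config = config or EngineConfig()
    result = rdFMCS.FindMCS([sub, prod], _mcs_params(config))
    if result.canceled:
        raise AlignmentError("mcs_timeout")
    if result.numAtoms == 0:
        raise AlignmentError("no_common_substructure")

    query = result.queryMol
    s_matches = sorted(sub.GetSubstructMatches(query, uniquify=False, maxMatches=20_000))
    p_matches = sorted(prod.GetSubstructMatches(query, uniquify=False, maxMatches=20_000))

    best: tuple[tuple[int, int], ...] | None = None
    examined = 0
    for s_match in s_matches:
        for p_match in p_matches:
            examined += 1
            if examined > _MAX_COMBINATIONS:
                break
            if not _embedding_ok(sub, prod, s_match, p_match, config):
                continue
            mapping = tuple(sorted(zip(s_match, p_match)))
            if best is None or mapping < best:
                best = mapping
        if examined > _MAX_COMBINATIONS:
            break
    if best is None:
        raise AlignmentError("no_consistent_embedding")

    mapped_s = {s for s, _ in best}
    mapped_p = {p for _, p in best}
    return AtomAlignment(
        mapping=best,
        unmapped_substrate=tuple(i for i in range(sub.GetNumAtoms()) if i not in mapped_s),
        unmapped_product=tuple(i for i in range(prod.GetNumAtoms()) if i not in mapped_p),
        mcs_size=len(best),
    )
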