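"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's own algorithms: the MCS oracle is a
plain recursive maximum-common-connected-subgraph search on adjacency sets,
the key-embedding oracle a direct backtracking subgraph matcher built from
RDKit adjacency only, and the proportion test a textbook formula.
"""

from __future__ import annotations

import math

from rdkit import Chem


def _atom_info(mol: Chem.Mol):
    return [
        (a.GetSymbol(), a.GetFormalCharge(), a.IsInRing()) for a in mol.GetAtoms()
    ]


def _adjacency(mol: Chem.Mol) -> dict[int, set[int]]:
    adj: dict[int, set[int]] = {i: set() for i in range(mol.GetNumAtoms())}
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        adj[i].add(j)
        adj[j].add(i)
    return adj


def brute_force_mcs_size(
    mol_a: Chem.Mol,
    mol_b: Chem.Mol,
    ring_matches_ring: bool = True,
    match_charge: bool = True,
) -> int:
    """Size (atom count) of the maximum common *connected* subgraph.

    Atoms are compatible when elements agree, charges agree (optional) and
    ring membership agrees (optional); bond orders are not compared,
    mirroring the alignment contract.  Exhaustive; fixture molecules are
    kept to <= 12 heavy atoms.
    """
    info_a, info_b = _atom_info(mol_a), _atom_info(mol_b)
    adj_a, adj_b = _adjacency(mol_a), _adjacency(mol_b)

    def compat(i: int, j: int) -> bool:
        ea, ca, ra = info_a[i]
        eb, cb, rb = info_b[j]
        if ea != eb:
            return False
        if match_charge and ca != cb:
            return False
        if ring_matches_ring and ra != rb:
            return False
        return True

    best = 0
    visited: set[frozenset] = set()

    def extend(mapping: dict[int, int]) -> None:
        nonlocal best
        key = frozenset(mapping.items())
        if key in visited:
            return
        visited.add(key)
        best = max(best, len(mapping))
        used_b = set(mapping.values())
        cands = set()
        for a1, b1 in mapping.items():
            for a2 in adj_a[a1]:
                if a2 in mapping:
                    continue
                for b2 in adj_b[b1]:
                    if b2 in used_b or not compat(a2, b2):
                        continue
                    cands.add((a2, b2))
        for a2, b2 in sorted(cands):
            mapping[a2] = b2
            extend(mapping)
            del mapping[a2]

    for i in range(mol_a.GetNumAtoms()):
        for j in range(mol_b.GetNumAtoms()):
            if compat(i, j):
                extend({i: j})
    return best


def enumerate_key_embeddings(
    tmol: Chem.Mol,
    tcodes: list[str],
    anchor: int,
    qmol: Chem.Mol,
    qcodes: list[str],
) -> set[int]:
    """Query atoms at which the radius-2 ball of ``anchor`` embeds.

    Independent matcher: builds the ball (atoms within two bonds of the
    anchor) and searches query embeddings that preserve atom-type codes,
    formal charges, bond orders, and the exact neighbour counts of the
    anchor and its distance-1 atoms.
    """
    t_adj = _adjacency(tmol)
    q_adj = _adjacency(qmol)
    d1 = sorted(t_adj[anchor])
    d2 = sorted({x for a in d1 for x in t_adj[a]} - {anchor} - set(d1))
    ball = [anchor] + d1 + d2
    boundary = set(d2)  # no arity constraint at distance 2

    def order(mol, i, j):
        return mol.GetBondBetweenAtoms(i, j).GetBondTypeAsDouble()

    def compat(t, q):
        if tcodes[t] != qcodes[q]:
            return False
        return tmol.GetAtomWithIdx(t).GetFormalCharge() == qmol.GetAtomWithIdx(q).GetFormalCharge()

    hits: set[int] = set()
    for qc in range(qmol.GetNumAtoms()):
        if not compat(anchor, qc):
            continue

        def search(i: int, emb: dict[int, int]) -> bool:
            if i == len(ball):
                return True
            t = ball[i]
            for q in range(qmol.GetNumAtoms()):
                if q in emb.values() or not compat(t, q):
                    continue
                if t not in boundary and len(q_adj[q]) != len(t_adj[t]):
                    continue
                ok = True
                for t2, q2 in emb.items():
                    has_t = t2 in t_adj[t]
                    has_q = q2 in q_adj[q]
                    if has_t != has_q and not (t in boundary and t2 in boundary):
                        ok = False
                        break
                    if has_t and has_q and order(tmol, t, t2) != order(qmol, q, q2):
                        ok = False
                        break
                if not ok:
                    continue
                emb[t] = q
                if search(i + 1, emb):
                    return True
                del emb[t]
            return False

        if len(q_adj[qc]) == len(t_adj[anchor]) and search(1, {anchor: qc}):
            hits.add(qc)
    return hits


def two_proportion_z(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Textbook pooled two-proportion z statistic and two-sided p-value."""
    p1, p2 = k1 / n1, k2 / n2
    pool = (k1 + k2) / (n1 + n2)
    se = math.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
    z = (p1 - p2) / se
    p = math.erfc(abs(z) / math.sqrt(2))
    return z, p
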