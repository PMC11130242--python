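"""Evaluation harnesses for a rule space.

Self-recovery is the central correctness check of the whole system: a rule
built from a substrate-product pair must regenerate the annotated product
when its own template substrate is submitted as the query.  Rules that pass
have captured the underlying chemistry of their reaction.  Leave-one-out
recovery asks the harder generalisation question: is the product recovered
by rules induced from *other* reactions?

Three self-recovery scenarios mirror the engine's feature ladder:

* Case 1 — single-centre reactions only, charge tracking off;
* Case 2 — single-centre reactions only, charge tracking on;
* Case 3 — all reactions (multi-centre rules included), charges on.

"Single centre" is classified from the engine's own centre detection: a
reaction qualifies when every pair yields at most one reaction centre and no
bond rearrangement.  "Recovered" means the annotated product appears among
the predictions for its substrate, compared stereo-agnostically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from statsmodels.stats.proportion import proportions_ztest

from .config import EngineConfig
from .metabolic_space import MetabolicSpace, Metabolite
from .pairing import fingerprint, dice_similarity
from .prediction_engine import Prediction, predict_all
from .rule_builder import LookupRule, RuleFailure, induce_rules


@dataclass(frozen=True)
class ReactionStatus:
    reaction_id: str
    built: bool
    recovered: bool
    n_pairs: int
    fail_reasons: tuple[str, ...] = ()


@dataclass
class RecoveryReport:
    n_reactions: int
    n_rules_built: int
    n_recovered: int
    statuses: list[ReactionStatus] = field(default_factory=list)

    @property
    def accuracy_all(self) -> float:
        """Recovered fraction over all reactions of the space."""
        return self.n_recovered / self.n_reactions if self.n_reactions else float("nan")

    @property
    def accuracy_built(self) -> float:
        """Recovered fraction over reactions with complete look-up tables."""
        return self.n_recovered / self.n_rules_built if self.n_rules_built else float("nan")


_CASE_SETTINGS = {
    1: dict(single_centre_only=True, use_charges=False),
    2: dict(single_centre_only=True, use_charges=True),
    3: dict(single_centre_only=False, use_charges=True),
}


def config_for_case(case: int, config: EngineConfig | None = None) -> EngineConfig:
    if case not in _CASE_SETTINGS:
        raise ValueError(f"case must be 1, 2 or 3, got {case}")
    return (config or EngineConfig()).replace(**_CASE_SETTINGS[case])


def _rule_recovers(rule: LookupRule, space: MetabolicSpace, config: EngineConfig) -> bool:
    substrate = space.metabolites[rule.template_substrate_id]
    product = space.metabolites[rule.template_product_id]
    preds = predict_all(substrate, [rule], config)
    return any(p.product_smiles == product.smiles for p in preds)


def self_recovery(
    space: MetabolicSpace, config: EngineConfig | None = None, case: int | None = None
) -> RecoveryReport:
    """Per-reaction self-recovery over the space.

    A reaction counts as *built* when every one of its pairs produced a
    rule, and as *recovered* when it is built and every pair's annotated
    product is regenerated from its substrate.
    """
    config = config or EngineConfig()
    if case is not None:
        config = config_for_case(case, config)
    rules, failures = induce_rules(space, config)
    rules_by_rxn: dict[str, list[LookupRule]] = {}
    for r in rules:
        rules_by_rxn.setdefault(r.reaction_id, []).append(r)
    fails_by_rxn: dict[str, list[RuleFailure]] = {}
    for f in failures:
        fails_by_rxn.setdefault(f.reaction_id, []).append(f)

    report = RecoveryReport(n_reactions=len(space.reactions), n_rules_built=0, n_recovered=0)
    for reaction in space.reactions:
        rxn_rules = rules_by_rxn.get(reaction.id, [])
        rxn_fails = fails_by_rxn.get(reaction.id, [])
        built = bool(rxn_rules) and not rxn_fails
        recovered = built and all(_rule_recovers(r, space, config) for r in rxn_rules)
        if built:
            report.n_rules_built += 1
        if recovered:
            report.n_recovered += 1
        report.statuses.append(
            ReactionStatus(
                reaction.id,
                built,
                recovered,
                n_pairs=len(rxn_rules),
                fail_reasons=tuple(f.reason for f in rxn_fails),
            )
        )
    assert report.n_recovered <= report.n_rules_built <= report.n_reactions
    return report


@dataclass(frozen=True)
class LeaveOneOutRecord:
    reaction_id: str
    substrate_id: str
    product_id: str
    recovered: bool


@dataclass
class LeaveOneOutReport:
    records: list[LeaveOneOutRecord]

    @property
    def fraction_recovered(self) -> float:
        if not self.records:
            return float("nan")
        return sum(r.recovered for r in self.records) / len(self.records)


def leave_one_out(space: MetabolicSpace, config: EngineConfig | None = None) -> LeaveOneOutReport:
    """For each pair, is its product recovered by rules from *other*
    reactions applied to its substrate?"""
    config = config or EngineConfig()
    rules, _ = induce_rules(space, config)
    if len(rules) < 2:
        raise ValueError("leave-one-out needs at least 2 rules")
    records = []
    for rule in rules:
        foreign = [r for r in rules if r.reaction_id != rule.reaction_id]
        substrate = space.metabolites[rule.template_substrate_id]
        product = space.metabolites[rule.template_product_id]
        preds = predict_all(substrate, foreign, config)
        records.append(
            LeaveOneOutRecord(
                rule.reaction_id,
                rule.template_substrate_id,
                rule.template_product_id,
                any(p.product_smiles == product.smiles for p in preds),
            )
        )
    return LeaveOneOutReport(records)


def product_similarity_matrix(
    predicted: list[Metabolite | Chem.Mol],
    annotated: list[Metabolite | Chem.Mol],
    config: EngineConfig | None = None,
) -> np.ndarray:
    """Dice similarity matrix between predicted and annotated products.

    Entry (i, j) is 1.0 exactly when the two fingerprints are identical;
    the recovery criterion elsewhere is similarity equal to 1.
    """
    config = config or EngineConfig()

    def fp(m):
        mol = m.mol if isinstance(m, Metabolite) else m
        return fingerprint(mol, config.fingerprint_radius, config.fingerprint_bits, config.fingerprint_counts)

    fps_p = [fp(m) for m in predicted]
    fps_a = [fp(m) for m in annotated]
    out = np.zeros((len(fps_p), len(fps_a)))
    for i, fa in enumerate(fps_p):
        for j, fb in enumerate(fps_a):
            out[i, j] = dice_similarity(fa, fb)
    return out


def compare_proportions(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Two-proportion z-test (pooled, two-sided): returns (z, p)."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("denominators must be positive")
    z, p = proportions_ztest([k1, k2], [n1, n2])
    return float(z), float(p)


def total_formal_charge(smiles_or_mol: str | Chem.Mol) -> int:
    mol = Chem.MolFromSmiles(smiles_or_mol) if isinstance(smiles_or_mol, str) else smiles_or_mol
    return sum(a.GetFormalCharge() for a in mol.GetAtoms())


def charge_ledger_delta(prediction: Prediction, rule: LookupRule) -> tuple[int, int]:
    """(observed, expected) charge-book entries for one prediction.

    Observed: total formal charge of product plus co-products minus the
    query.  Expected: the signed sum of the rule's charge edits plus the
    charges carried by its added fragments (removed-fragment charges leave
    with the co-products and cancel).
    """
    observed = (
        total_formal_charge(prediction.product_smiles)
        + sum(total_formal_charge(s) for s in prediction.co_products)
        - total_formal_charge(prediction.query_smiles)
    )
    expected = sum(f.total_charge for f in rule.fragments_added) + sum(
        e.delta for u in rule.units for e in u.value.charge_edits
    )
    return observed, expected
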