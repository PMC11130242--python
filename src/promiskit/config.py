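"""Engine configuration.

All tunable behaviour of the pipeline is collected in a single dataclass so
that every run can log the exact settings it used (cofactor list included).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml


def default_cofactors() -> frozenset[str]:
    """Cofactor identifiers stripped during reaction simplification.

    Shipped as an editable YAML file (``data/cofactors.yaml``); this loads the
    packaged default.
    """
    text = resources.files("promiskit.data").joinpath("cofactors.yaml").read_text()
    return frozenset(yaml.safe_load(text)["cofactors"])


@dataclass(frozen=True)
class EngineConfig:
    """Settings for rule induction and product prediction.

    Parameters
    ----------
    fingerprint_radius, fingerprint_bits, fingerprint_counts:
        Morgan (circular) fingerprint parameters used for pairing and the
        query prefilter; the count (frequency) variant is the default.
    similarity_threshold:
        Minimum Dice similarity between a query compound and a rule's
        template substrate for the rule to be applied (default 0.6).
    ring_matches_ring:
        MCS constraint: a ring atom may only be aligned to a ring atom.
    match_formal_charge:
        MCS constraint: aligned atoms must carry the same formal charge.
    use_charges:
        Track formal charges through rules (charge edits, charges on
        added/removed fragments).  Turning this off reproduces the engine's
        charge-blind mode.
    single_centre_only:
        Restrict rule induction to reactions in which every pair yields at
        most one reaction centre and no bond rearrangements.
    mcs_timeout:
        Per-pair MCS time budget in seconds.
    key_match_mode:
        ``"branch"``: distance-2 neighbours must match per distance-1 branch;
        ``"flat"``: they are compared as one flat multiset.
    bidirectional:
        Additionally induce rules for the reversed substrate/product pairs.
    emit_co_products:
        Report removed fragments as co-products of a prediction.
    """

    fingerprint_radius: int = 2
    fingerprint_bits: int = 2048
    fingerprint_counts: bool = True
    similarity_threshold: float = 0.6
    ring_matches_ring: bool = True
    match_formal_charge: bool = True
    use_charges: bool = True
    single_centre_only: bool = False
    mcs_timeout: int = 60
    key_match_mode: str = "branch"
    bidirectional: bool = False
    emit_co_products: bool = True
    cofactors: frozenset[str] = field(default_factory=default_cofactors)

    def __post_init__(self) -> None:
        if self.key_match_mode not in ("branch", "flat"):
            raise ValueError(f"key_match_mode must be 'branch' or 'flat', got {self.key_match_mode!r}")

    def replace(self, **kwargs) -> "EngineConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cofactors"] = sorted(self.cofactors)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EngineConfig":
        d = dict(d)
        if "cofactors" in d:
            d["cofactors"] = frozenset(d["cofactors"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "EngineConfig":
        """Load settings from a YAML or JSON config file."""
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(data)
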