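import pytest

from promiskit import EngineConfig, Metabolite, builtin_examples, induce_rules


@pytest.fixture(scope="session")
def cfg():
    return EngineConfig()


@pytest.fixture(scope="session")
def builtin():
    return builtin_examples()


@pytest.fixture(scope="session")
def builtin_space(builtin, cfg):
    return builtin.build_space(cfg)


@pytest.fixture(scope="session")
def builtin_rules(builtin_space, cfg):
    """Rules of the worked-example space, grouped by reaction id."""
    rules, failures = induce_rules(builtin_space, cfg)
    assert not failures, failures
    grouped = {}
    for r in rules:
        grouped.setdefault(r.reaction_id, []).append(r)
    return grouped


def met(mid: str, smiles: str, name: str = "") -> Metabolite:
    return Metabolite.from_smiles(mid, smiles, name=name or mid)
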