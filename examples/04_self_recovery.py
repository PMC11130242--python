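"""Self-recovery over a whole reaction space.

A synthetic space of 30 single-edit reactions is generated with known
ground truth (products built by direct graph editing), rules are induced
for every substrate-product pair, and each rule is applied back to its own
template substrate.  Because the ground truth is constructed, a correct
engine recovers 100% of the annotated products.
"""

from promiskit import EngineConfig, generate_synthetic_space, self_recovery

cfg = EngineConfig()
fixture = generate_synthetic_space(30, seed=17)
space = fixture.build_space(cfg)

for case in (1, 2, 3):
    report = self_recovery(space, cfg, case=case)
    print(
        f"case {case}: {report.n_recovered}/{report.n_reactions} reactions recovered "
        f"({100 * report.accuracy_all:.1f}%); look-up tables built for {report.n_rules_built}"
    )

# Case 1 restricts to single-centre reactions with charge tracking off,
# case 2 turns charges on, case 3 admits every reaction.  Charge-toggling
# and multi-centre edits in the space are only recoverable in the richer
# configurations, so the recovered fraction rises monotonically with the
# case number.
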