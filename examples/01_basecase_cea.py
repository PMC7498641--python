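"""Deterministic base-case cost-effectiveness per skin-tone subgroup.

Builds the two-arm decision tree from the bundled default parameters and
prints expected discounted costs and QALYs per child over the 4-year
horizon, plus the incremental result.  An ICER is pounds per QALY gained;
'Dominant' means the supplementation programme is both cheaper and more
effective than current practice.
"""

import vitdcea as v

cfg = v.default_config()
print(f"{'subgroup':<8} {'arm':<13} {'cost £':>8} {'QALYs':>10}   incremental")
for label in ("light", "medium", "dark"):
    bundle = v.build_bundle(cfg, label)
    comparator, intervention = bundle.evaluate()
    res = bundle.cea()
    print(f"{label:<8} {'comparator':<13} {comparator.expected_cost:8.2f} "
          f"{comparator.expected_qalys:10.6f}")
    print(f"{'':<8} {'intervention':<13} {intervention.expected_cost:8.2f} "
          f"{intervention.expected_qalys:10.6f}   "
          f"dC={res.delta_cost:+.2f}, dQ={res.delta_qalys:+.6f}, "
          f"ICER={v.format_icer(res)}")
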