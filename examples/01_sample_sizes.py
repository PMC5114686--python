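"""Closed-form sample sizes for the reference designs.

The planning setting: normally distributed endpoint, standardized
effect delta = 0.2, sigma = 1, one-sided alpha = 2.5%, 80% power.
"""

from thresholdcross import (
    DesignParams,
    RuleTag,
    ThresholdRule,
    parallel_group_sample_size,
    planned_trial_size,
    round_to_hundred,
    single_arm_sample_size,
)

params = DesignParams(delta=0.2)

n2 = parallel_group_sample_size(params)
print(f"two-arm RCT: {n2} per group ({2 * n2} total, "
      f"about {round_to_hundred(2 * n2)})")

n1 = single_arm_sample_size(params.delta)
print(f"single-arm at the full effect (threshold known exactly): {n1} "
      f"(about {round_to_hundred(n1)}) — a quarter of the RCT total")

for n_h in (200, 500, 1000, 5000):
    n = planned_trial_size(ThresholdRule(RuleTag.CI_UPPER), n_h, params)
    print(f"CI-upper threshold from {n_h:>5} historical controls: "
          f"planned single-arm size {n}")

# The adjusted size shrinks toward 197 as historical data accumulate:
# with ~1000 historical controls the single-arm trial needs about 400
# patients, half of the 800-patient two-arm total.
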