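"""Learn a compact state space for the otter problem with CU-Tree.

CU-Tree simulates the population, estimates per-state models, and splits
states only where the distribution of one-step return estimates differs
significantly across a candidate threshold (two-sample KS test).  The
result is a small set of intervals, each with an optimal management
action; the interesting structure is the boundary near the lower edge of
the reward band (497 otters) where the action changes.
"""

import numpy as np

from otterpomdp import (
    stage_rng,
    CutreeConfig,
    PopulationParams,
    RewardParams,
    action_change_boundary,
    run_cutree,
)

rng = stage_rng(0, "discretize")
disc, policy = run_cutree(PopulationParams(), RewardParams(), CutreeConfig(), rng)

print(disc.policy_table())
print(f"\nstates learned        : {disc.n_leaves}")
print(f"datapoints stored     : {len(disc.x)}")
print(f"action-change boundary: {action_change_boundary(disc):.1f} otters"
      "  (the band edge is 497)")
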