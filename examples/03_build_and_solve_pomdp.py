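"""Build the partially observed problem and solve it with Perseus.

States near the action-change boundary can only be classified as "small"
or "large" with probability 0.5 unless the manager pays 2 units to
monitor (probability 0.95).  The solved policy is summarized as a policy
graph: starting from complete ignorance the manager re-introduces otters,
and monitoring enters the policy only where observations conflict.
"""

import numpy as np

from otterpomdp import (
    stage_rng,
    CutreeConfig,
    ObservationParams,
    PopulationParams,
    RewardParams,
    action_change_boundary,
    assemble_pomdp,
    extract_policy_graph,
    policy_graph_to_dot,
    run_cutree,
    solve_perseus,
    write_pomdp,
)

rng = stage_rng(0, "discretize")
disc, _ = run_cutree(PopulationParams(), RewardParams(), CutreeConfig(), rng)
op = ObservationParams(boundary=action_change_boundary(disc))
model = assemble_pomdp(disc, op, RewardParams())
write_pomdp(model, "otter.pomdp")  # standard interchange format

solution = solve_perseus(model, rng=np.random.default_rng(1))
graph = extract_policy_graph(solution, model)

start = graph.graph["start"]
print(f"POMDP: {model.n_states} states, {model.n_actions} actions, "
      f"{model.n_observations} observations -> otter.pomdp")
print(f"alpha vectors        : {len(solution)}")
print(f"value at uniform b0  : {solution.value(model.b0):.1f}")
print(f"policy graph         : {len(graph)} reachable nodes")
print(f"first action         : {graph.nodes[start]['action_name']}")
actions = sorted({d['action_name'] for _, d in graph.nodes(data=True)})
print(f"actions in the graph : {', '.join(actions)}")
open("policy.dot", "w").write(policy_graph_to_dot(graph))
print("policy graph written to policy.dot")
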