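# Methods

This note documents the models, algorithms and design choices behind
`otterpomdp`, in the spirit of a statistical software methods appendix.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Population model

The population is continuous-valued on `[0, x_max]` (default
`x_max = 1000` animals) and evolves annually:

    x' = clip( x · exp( r (1 − x/K) + ε ) · (1 − D) + I(a), 0, x_max )

with `ε ~ N(0, σ²)`; `D = d · 1[u < f_a]`, `u ~ U(0,1)`,
`d ~ U(d_min, d_max,a)`; `I(a)` the number of re-introduced animals.
Populations below one animal are truncated to zero, making extinction
absorbing in the absence of re-introduction.  The order of operations —
growth with noise, then multiplicative spill mortality, then additive
introduction, then clipping — keeps a re-introduction effective even in
a spill year.

Parameters and defaults:

| parameter | default | units | role |
|---|---|---|---|
| `r` | 0.26 | 1/yr | intrinsic growth rate (Ricker fit for the Washington population) |
| `K` | 622 | animals | carrying capacity; the reward band is K ± 20% |
| `sigma` | 0.1 | — | s.d. of log-scale environmental noise |
| `f` | 0.3 | 1/yr | annual oil-spill probability |
| `damage_min, damage_max` | 0, 0.5 | fraction | spill mortality range |
| `intro_count` | 50 | animals | re-introduction size |
| `effect_freq_reduction` | 0.2 | fraction | spill-frequency cut under REDUCE_FREQ |
| `effect_damage_reduction` | 0.2 | fraction | damage-cap cut under REDUCE_DAMAGE |
| `band_lo, band_hi` | 497, 746 | animals | reward band (inclusive) |
| `band_reward, action_cost, monitor_cost` | 100, 10, 2 | points | annual reward and costs |

Every `step` consumes its three random draws (noise, spill uniform,
damage) in a fixed order regardless of which branches fire, so that
seeded trajectories are bitwise reproducible and two policies given the
same seed experience the same environment until their actions diverge.

## CU-Tree state discretization

CU-Tree alternates a data-gathering phase and an expansion phase.  The
defaults run 250 sampling loops; each loop simulates one 50-step
trajectory (12,500 stored transitions in total) from a uniform-random
initial population under uniform-random management actions, an
exploration scheme that guarantees coverage of every (region, action)
pair.  One trajectory per sampling loop keeps the stored-data scale at
which the split test settles on a compact partition; more trajectories
per loop are a configuration knob (`n_trajectories`).

Each expansion phase:

1. estimates `T(s,a,s')` and `R(s,a)` as empirical transition fractions
   and mean rewards over the stored datapoints (unvisited pairs
   self-loop with zero reward, which keeps `T` row-stochastic and is
   conservative);
2. solves the Bellman equations by value iteration (warm-started,
   sup-norm tolerance 1e-9) for `Q` and `V`;
3. assigns every datapoint the one-step return estimate
   `q = r_t + γ V(leaf(x_next))`, pooled across actions;
4. for every leaf with at least `2 · min_leaf_size` datapoints
   (default 10), sorts the datapoints by population size, evaluates the
   two-sample Kolmogorov–Smirnov statistic of q-left vs q-right at every
   threshold lying between adjacent *distinct* population sizes with at
   least `min_leaf_size` points per side, and selects the threshold with
   maximal D (ties to the smallest threshold).

The selected split is accepted when significant at `alpha = 0.05`.
Because the selected statistic is the maximum over many correlated
candidate tests, the default decision rule Bonferroni-corrects the
selected p-value by the number of candidates
(`split_correction="bonferroni"`); without a correction the test is
guaranteed to make spurious splits as data accumulate.  P-values are
asymptotic (`scipy.stats.ks_2samp(method="asymp")`).  The all-candidate
D scan is computed exactly in one vectorized pass over the pooled unique
q values.

All significant winners across leaves are applied in the same phase, and
datapoints are never discarded.  The run always executes the configured
number of sampling loops: because data accumulate, a phase with no
significant split is not terminal — later phases have more power — so a
quiet phase does not stop the run.  The greedy policy is
`π(s) = argmax_a Q(s,a)` with ties to the lowest action index, stable
across runs.

Two boundary summaries are provided: `policy_boundary` returns the edge
where the policy switches INTRODUCE → REDUCE_DAMAGE (the canonical
structure of this problem), and `action_change_boundary` falls back to
the first edge where the policy leaves INTRODUCE.  The fallback matters
because inside the reward band the three candidate actions are nearly
value-equivalent under the default parameters: doing nothing is free,
damage reduction saves roughly `f · Δd · x ≈ 9` expected animals per
year for 10 units, and re-introduction adds 50 animals for the same 10
units but risks overshooting the band top.  The learner therefore
reports different band actions in different seeded runs, while the
*location* of the action change concentrates tightly at the lower band
edge.  Downstream code treats the boundary location, not the identity of
the in-band action, as the robust output.

## Observation model and POMDP assembly

Only two observations matter — "small" (below the boundary) and "large"
— because the fully observed solution uses one action on each side.  A
state is classified by which side of the boundary it lies on (the
boundary always coincides with a leaf edge).  Detection is perfect
except inside a window centred on the boundary; there the correct class
is observed with probability 0.5, rising to 0.95 under monitoring.

Two window conventions exist in practice; this package defaults to
`window_radius = 125` (a window of total width 250 animals) and counts a
state as ambiguous only when its interval lies *wholly inside* the
window.  Under this containment rule only the narrow states flanking the
boundary are ambiguous; the wide reward-band state extends beyond the
window and is observed exactly.  The alternative readings (radius 250,
or partial overlap counting as inside) make the entire reward band
permanently ambiguous, which changes the problem qualitatively: a
memoryless manager then flips a coin inside the band forever and
belief tracking acquires a large, permanent advantage.  Both the radius
and the rule are configurable.

The POMDP copies the empirical `T` and `R` for the four management
actions; monitoring clones the do-nothing dynamics (monitoring does not
touch the population) and subtracts the monitoring cost.  The initial
belief is uniform.  Models round-trip through the Cassandra `.pomdp`
format (named states/actions/observations, `T:`/`O:`/`R:` blocks with
`uniform`/`identity` keywords) to 1e-12; solutions are written in the
companion `.alpha` format and policy graphs as DOT text.

## Solvers

*Exact finite horizon*: incremental pruning.  For each action and
observation the projected set `{R(·,a)/|O| + γ T_a(O_{a,o} ⊙ α)}` is
pruned, cross-sums over observations are pruned incrementally, and the
union over actions is pruned again.  Pruning removes duplicates (1e-9),
then pointwise-dominated vectors, then LP-dominated vectors via Lark's
witness-agenda filter (seeded with the maximizers at the simplex
corners; each LP searches for a belief where a candidate strictly beats
everything kept, and the vector installed is the best remaining
candidate at that witness).  Ties resolve toward the earlier-generated
vector.  A configurable vector budget raises an error advising the
point-based solver; the otter model itself is beyond exact horizon-6
reach (the per-action undominated sets grow into the thousands by stage
5), which is why the evaluation experiments use the Perseus solution at
both horizons.

*Perseus* (randomized point-based value iteration): a belief set
(default 1000) is sampled by random-action forward simulation from the
initial belief with occasional restarts; the value function starts at
the blind lower bound `min R/(1−γ)`; each sweep backs up randomly chosen
not-yet-improved beliefs, keeping a new vector only if it improves that
belief and otherwise retaining the best old vector, until every belief
has improved.  Sweeps stop when the largest value change over the belief
set drops below `epsilon` (default 1e-4) or after `max_iter` (500)
sweeps.  Values at the sampled beliefs are non-decreasing by
construction, and a fixed seed reproduces the vector set exactly.  Note
the stopping rule leaves a convergence tail of order
`epsilon · γ/(1−γ)`; comparisons against exact values at tolerance 1e-3
therefore use a tighter `epsilon`.

*Policy graphs*: nodes are the alpha vectors reachable from the initial
belief under breadth-first execution; each node carries its action, each
edge the triggering observation, and each vector is represented by the
first belief that reached it.  Zero-probability observations produce no
edge.

## Value-of-monitoring evaluation

The true continuous population is simulated while a manager follows
either strategy:

* **MDP strategy** — trusts observations.  Outside the detection window
  the true state is read exactly and its learned action applied; inside,
  only the observed class is available and the class-side representative
  action is applied (the visit-weighted modal policy action of that
  side, robust to narrow boundary leaves).  Monitoring is never chosen.
* **POMDP strategy** — tracks a belief from the uniform prior, acts by
  the maximizing alpha vector (which may monitor), and updates by Bayes'
  rule after each observation.  If the discrete model assigns zero
  probability to an observation the continuous simulation produced, the
  belief resets to uniform over observation-consistent states; resets
  are counted and are rare in practice.

Both strategies earn rewards from the *true* population.  Each of the 20
runs per scenario draws one seed and one starting population shared by
both strategies and by all monitoring-cost scenarios (1, 2 and 10
units), so comparisons are paired throughout.  The default start is 50
animals — a newly re-introduced population about which the manager knows
nothing, matching the uniform prior's spirit; with a uniform random
start the population often begins inside the band and the short-horizon
comparison reduces to noise.  Reported quantities: mean cumulative
reward per year (with standard errors), the 6-year means, the mean
per-year reward over years 20–40, and a paired t-test on the latter.

## What the simulator does and does not emulate

The generator captures density-dependent growth, log-scale environmental
noise, random catastrophic mortality and the four management levers.  It
does not represent age or spatial structure, demographic stochasticity
at small sizes (extinction below one animal is a hard threshold),
correlated spill years, or uncertainty in the growth parameters
themselves.  Tests passing on this generator therefore demonstrate the
correctness of the decision machinery under the stated model, not the
adequacy of that model for any real population.

## Known limitations

* The in-band action tie described above is a property of the stated
  costs and dynamics; analyses that depend on *which* action is optimal
  inside the band (rather than where the action changes) are fragile
  across seeds.
* CU-Tree is one-dimensional by construction; multi-dimensional state
  spaces would need a different ranking of candidate splits.
* Exact solving is practical only for small models; all otter-scale
  results rest on the point-based approximation.
* The KS split test assumes the pooled q sample is informative for the
  split; per-action stratification is not implemented (the pooled form
  follows the algorithm's original formulation).
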