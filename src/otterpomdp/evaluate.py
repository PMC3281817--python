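"""Value-of-monitoring experiments.

The true population evolves continuously while a manager follows either

* the MDP strategy — trusts the (possibly wrong) observation: outside the
  detection window the state is read exactly and the learned policy's
  action for that state is applied; inside the window only the
  small/large class is seen and the class-side optimal action is applied;
  monitoring is never chosen; or
* the POMDP strategy — maintains a belief over the discrete states,
  acts with the maximizing alpha vector (which may monitor), and updates
  the belief by Bayes' rule after each observation.

Rewards accrue from the *true* population for both strategies, so the
comparison measures what imperfect detection actually costs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .cutree import Discretization
from .pomdp import LARGE, SMALL, ObservationParams, PomdpModel, window_state_mask
from .population import Action, PopulationParams, RewardParams, reward, step
from .solvers import (
    AlphaVectorSet,
    ImpossibleObservationError,
    belief_update,
)

__all__ = ["StrategyRun", "ComparisonSummary", "run_mdp_strategy",
           "run_pomdp_strategy", "compare_strategies"]


@dataclass
class StrategyRun:
    """Trace of one simulated management run."""

    strategy: str
    seed: Optional[int]
    x: list[float] = field(default_factory=list)
    state: list[int] = field(default_factory=list)
    observation: list[int] = field(default_factory=list)
    action: list[int] = field(default_factory=list)
    rewards: list[float] = field(default_factory=list)
    beliefs: list[np.ndarray] = field(default_factory=list)
    belief_resets: int = 0

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.rewards)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": np.arange(len(self.rewards)),
                "x": self.x,
                "state": self.state,
                "observation": self.observation,
                "action": [Action(a).name for a in self.action],
                "reward": self.rewards,
                "cumulative": self.cumulative,
            }
        )


def _observe(
    true_state: int,
    prev_action: int,
    m: PomdpModel,
    rng: np.random.Generator,
) -> int:
    p_large = m.O[prev_action, true_state, LARGE]
    return LARGE if rng.uniform() < p_large else SMALL




def _side_action(
    disc: Discretization,
    policy: np.ndarray,
    below: Optional[float] = None,
    above: Optional[float] = None,
) -> int:
    """Representative policy action on one side of the boundary: the
    visit-weighted modal action over that side's leaves (robust to narrow,
    sparsely visited leaves right at the boundary)."""
    bnd = below if below is not None else above
    hi = disc.edges[1:]
    lo = disc.edges[:-1]
    sel = hi <= bnd + 1e-9 if below is not None else lo >= bnd - 1e-9
    weights = disc.N.sum(axis=1) if disc.N is not None else np.ones(disc.n_leaves)
    votes = np.zeros(int(policy.max()) + 1)
    for s in np.flatnonzero(sel):
        votes[int(policy[s])] += weights[s]
    return int(np.argmax(votes))


def run_mdp_strategy(
    m: PomdpModel,
    disc: Discretization,
    policy: np.ndarray,
    op: ObservationParams,
    params: PopulationParams,
    rp: RewardParams,
    horizon: int,
    rng: np.random.Generator,
    x0: Optional[float] = None,
    boundary: Optional[float] = None,
) -> StrategyRun:
    """Simulate a manager who treats observations as the truth.

    Outside the detection window states are identified exactly and the
    learned per-state policy applies; inside it, only the observed class
    is available and the action is the class-side optimum (the policy of
    the leaf adjacent to the boundary on that side).
    """
    from .cutree import action_change_boundary  # local import avoids a cycle

    if boundary is None:
        boundary = op.boundary
    if boundary is None:
        boundary = action_change_boundary(disc)
    if boundary is None:
        raise ValueError("discretization has no policy boundary")
    window = set(np.flatnonzero(window_state_mask(disc, op, boundary)))
    action_small = _side_action(disc, policy, below=boundary)
    action_large = _side_action(disc, policy, above=boundary)

    run = StrategyRun(strategy="MDP", seed=None)
    x = rng.uniform(0.0, params.pop_max) if x0 is None else float(x0)
    prev_a = int(Action.DO_NOTHING)
    for _ in range(horizon):
        s = int(disc.leaf_index(x))
        o = _observe(s, prev_a, m, rng)
        if s in window:
            a = action_small if o == SMALL else action_large
        else:
            a = int(policy[s])
        r = reward(x, Action(a), rp)
        run.x.append(x)
        run.state.append(s)
        run.observation.append(o)
        run.action.append(a)
        run.rewards.append(r)
        x = step(x, Action(a), params, rng)
        prev_a = a
    return run


def run_pomdp_strategy(
    m: PomdpModel,
    G: AlphaVectorSet,
    op: ObservationParams,
    params: PopulationParams,
    rp: RewardParams,
    horizon: int,
    rng: np.random.Generator,
    disc: Optional[Discretization] = None,
    x0: Optional[float] = None,
) -> StrategyRun:
    """Simulate a belief-tracking manager following an alpha-vector policy.

    The belief starts uniform.  If the discrete model assigns zero
    probability to an observation that the continuous simulation
    nevertheless produced, the belief resets to the uniform distribution
    over observation-consistent states (counted in ``belief_resets``).
    """
    if disc is None:
        raise ValueError("a discretization is required to map x to states")
    run = StrategyRun(strategy="POMDP", seed=None)
    b = m.b0.copy()
    x = rng.uniform(0.0, params.pop_max) if x0 is None else float(x0)
    for _ in range(horizon):
        s = int(disc.leaf_index(x))
        a = int(G.action(b))
        r = reward(x, Action(a), rp)
        run.x.append(x)
        run.state.append(s)
        run.action.append(a)
        run.rewards.append(r)
        run.beliefs.append(b.copy())
        # dynamics: monitoring does not alter the population
        a_dyn = Action.DO_NOTHING if a == Action.MONITOR else Action(a)
        x = step(x, a_dyn, params, rng)
        s_next = int(disc.leaf_index(x))
        o = _observe(s_next, a, m, rng)
        run.observation.append(o)
        try:
            b, _ = belief_update(b, a, o, m)
        except ImpossibleObservationError:
            consistent = m.O[a, :, o] > 0
            b = consistent / consistent.sum()
            run.belief_resets += 1
    return run


@dataclass
class ComparisonSummary:
    """Mean cumulative-reward trajectories and the long-run paired test."""

    per_scenario: pd.DataFrame  # per (scenario, strategy, t): mean, se
    tests: pd.DataFrame  # per scenario: 6-step means, 20-40 step means, p-value

    def to_csv(self, prefix: str) -> None:
        self.per_scenario.to_csv(f"{prefix}_curves.csv", index=False)
        self.tests.to_csv(f"{prefix}_tests.csv", index=False)

    def plot(self, path: str) -> None:
        """Accumulated-reward curves per scenario (MDP vs POMDP, ±1 s.e.)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        scenarios = list(self.per_scenario["scenario"].unique())
        fig, axes = plt.subplots(
            1, len(scenarios), figsize=(4.5 * len(scenarios), 3.6),
            sharey=True, squeeze=False,
        )
        for ax, name in zip(axes[0], scenarios):
            for label, color in (("MDP", "tab:orange"), ("POMDP", "tab:blue")):
                sub = self.per_scenario.query(
                    "scenario == @name and strategy == @label"
                )
                ax.plot(sub["t"], sub["mean_cumulative"], label=label, color=color)
                ax.fill_between(
                    sub["t"],
                    sub["mean_cumulative"] - sub["se"],
                    sub["mean_cumulative"] + sub["se"],
                    alpha=0.25, color=color, linewidth=0,
                )
            ax.set_title(name)
            ax.set_xlabel("year")
        axes[0][0].set_ylabel("mean accumulated reward")
        axes[0][0].legend()
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def compare_strategies(
    scenarios: dict[str, tuple[PomdpModel, AlphaVectorSet]],
    disc: Discretization,
    policy: np.ndarray,
    op: ObservationParams,
    params: PopulationParams,
    rp_by_scenario: dict[str, RewardParams],
    rng: np.random.Generator,
    n_runs: int = 20,
    horizon: int = 40,
    finite_horizon: int = 6,
    long_window: tuple[int, int] = (20, 40),
    x0: Optional[float] = 50.0,
) -> ComparisonSummary:
    """Paired MDP-vs-POMDP comparison across monitoring-cost scenarios.

    For each scenario both strategies run ``n_runs`` times with paired
    seeds.  The true population starts at ``x0`` (default 50 animals — a
    newly re-introduced population, while the manager's belief is
    uniform; pass None to draw the start uniformly instead).  Reports
    mean cumulative reward (with standard errors) per timestep, the
    finite-horizon means, and a paired t-test on mean per-step reward
    over the long-run window.
    """
    if n_runs < 2:
        raise ValueError("need n_runs >= 2 for standard errors")
    curve_rows = []
    test_rows = []
    # one seed and one start per run index, shared by both strategies and by
    # every scenario: comparisons are paired within and across scenarios
    run_seeds = [int(rng.integers(2**31 - 1)) for _ in range(n_runs)]
    starts = [
        rng.uniform(0.0, params.pop_max) if x0 is None else float(x0)
        for _ in range(n_runs)
    ]
    for name, (m, G) in scenarios.items():
        rp = rp_by_scenario[name]
        cum_mdp = np.zeros((n_runs, horizon))
        cum_pomdp = np.zeros((n_runs, horizon))
        monitor_used = 0
        for k in range(n_runs):
            x0_k = starts[k]
            # both strategies consume an identical random stream, so their
            # environments coincide until the chosen actions diverge
            r1 = run_mdp_strategy(
                m, disc, policy, op, params, rp, horizon,
                np.random.default_rng(run_seeds[k]), x0=x0_k,
            )
            r2 = run_pomdp_strategy(
                m, G, op, params, rp, horizon,
                np.random.default_rng(run_seeds[k]), disc=disc, x0=x0_k,
            )
            cum_mdp[k] = r1.cumulative
            cum_pomdp[k] = r2.cumulative
            monitor_used += sum(a == Action.MONITOR for a in r2.action)
        for label, cum in (("MDP", cum_mdp), ("POMDP", cum_pomdp)):
            mean = cum.mean(axis=0)
            se = cum.std(axis=0, ddof=1) / np.sqrt(n_runs)
            for t in range(horizon):
                curve_rows.append(
                    {"scenario": name, "strategy": label, "t": t + 1,
                     "mean_cumulative": mean[t], "se": se[t]}
                )
        lo, hi = long_window
        hi = min(hi, horizon)
        lo = min(lo, hi - 1)
        per_step_mdp = (cum_mdp[:, hi - 1] - cum_mdp[:, lo - 1]) / (hi - lo)
        per_step_pomdp = (cum_pomdp[:, hi - 1] - cum_pomdp[:, lo - 1]) / (hi - lo)
        tt = stats.ttest_rel(per_step_pomdp, per_step_mdp)
        test_rows.append(
            {
                "scenario": name,
                "mdp_mean_finite": cum_mdp[:, finite_horizon - 1].mean(),
                "pomdp_mean_finite": cum_pomdp[:, finite_horizon - 1].mean(),
                "mdp_per_step_long": per_step_mdp.mean(),
                "pomdp_per_step_long": per_step_pomdp.mean(),
                "paired_t_pvalue": float(tt.pvalue),
                "monitor_actions": monitor_used,
            }
        )
    return ComparisonSummary(
        per_scenario=pd.DataFrame(curve_rows), tests=pd.DataFrame(test_rows)
    )
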