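"""Stochastic Ricker dynamics for the Washington sea otter population.

The population is modelled in continuous numbers on an annual time step.
Growth follows a Ricker map with multiplicative log-normal environmental
noise; in any year an oil spill may occur with fixed probability and, if it
does, kills a uniformly drawn fraction of the population.  Management can
reduce spill frequency, reduce spill damage, re-introduce animals, do
nothing, or (in the partially observed setting) monitor, which leaves the
dynamics untouched.

The annual update applied by :func:`step` is

    x' = clip( x * exp(r * (1 - x/K) + eps) * (1 - D) + I(a), 0, pop_max )

with ``eps ~ Normal(0, sigma^2)``, spill mortality ``D = d * 1[u < f_eff]``
(``u ~ U(0,1)``, ``d ~ U(damage_min, damage_max_eff)``), and ``I(a)`` the
number of re-introduced animals.  Populations that fall below one animal
are truncated to zero (extinction is absorbing in the absence of
re-introduction).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Action",
    "MANAGEMENT_ACTIONS",
    "PopulationParams",
    "RewardParams",
    "Datapoint",
    "step",
    "step_detail",
    "reward",
    "simulate_trajectory",
    "trajectory_to_csv",
]


class Action(IntEnum):
    """Management actions; one is taken each year.

    MONITOR is only admissible in the partially observed problem; it has
    the same effect on the population dynamics as DO_NOTHING.
    """

    DO_NOTHING = 0
    REDUCE_FREQ = 1
    REDUCE_DAMAGE = 2
    INTRODUCE = 3
    MONITOR = 4


#: Actions available in the fully observed (MDP) problem.
MANAGEMENT_ACTIONS: tuple[Action, ...] = (
    Action.DO_NOTHING,
    Action.REDUCE_FREQ,
    Action.REDUCE_DAMAGE,
    Action.INTRODUCE,
)


@dataclass
class PopulationParams:
    """Biological and action-effect parameters of the otter model.

    Defaults are the sea otter configuration: intrinsic growth rate
    r = 0.26 / yr and carrying capacity K = 622 otters (Ricker fit for the
    Washington population), annual spill probability 0.3, spill mortality
    uniform on 0-50%, management effects of 20% on spill frequency or
    maximum damage, and re-introductions of 50 animals.
    """

    r: float = 0.26
    K: float = 622.0
    sigma: float = 0.1
    f: float = 0.3
    damage_min: float = 0.0
    damage_max: float = 0.5
    intro_count: float = 50.0
    effect_freq_reduction: float = 0.2
    effect_damage_reduction: float = 0.2
    pop_max: float = 1000.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.f <= 1.0:
            raise ValueError(f"spill frequency f must be in [0, 1], got {self.f}")
        if not 0.0 <= self.damage_min <= self.damage_max <= 1.0:
            raise ValueError(
                "damage range must satisfy 0 <= damage_min <= damage_max <= 1, "
                f"got [{self.damage_min}, {self.damage_max}]"
            )
        if self.K <= 0:
            raise ValueError("carrying capacity K must be positive")
        if self.sigma < 0:
            raise ValueError("environmental noise sigma must be non-negative")
        if self.pop_max <= self.K:
            raise ValueError("pop_max must exceed the carrying capacity")
        if self.intro_count < 0:
            raise ValueError("intro_count must be non-negative")
        if not 0.0 <= self.effect_freq_reduction <= 1.0:
            raise ValueError("effect_freq_reduction must be in [0, 1]")
        if not 0.0 <= self.effect_damage_reduction <= 1.0:
            raise ValueError("effect_damage_reduction must be in [0, 1]")


@dataclass
class RewardParams:
    """Annual reward: 100 points inside the target band minus action costs.

    The band [497, 746] is within 20% of the carrying capacity estimate.
    Management actions cost 10 units; monitoring costs 2; doing nothing is
    free.
    """

    band_lo: float = 497.0
    band_hi: float = 746.0
    band_reward: float = 100.0
    action_cost: float = 10.0
    monitor_cost: float = 2.0

    def __post_init__(self) -> None:
        if not self.band_lo < self.band_hi:
            raise ValueError("reward band must satisfy band_lo < band_hi")
        if not self.band_reward > self.action_cost >= self.monitor_cost >= 0:
            raise ValueError(
                "costs must satisfy band_reward > action_cost >= monitor_cost >= 0"
            )


@dataclass
class Datapoint:
    """One simulated transition (x_t, a_t, x_{t+1}, r_t) plus a scalar
    return estimate q used by the state-splitting test."""

    x_t: float
    a_t: Action
    x_next: float
    r_t: float
    q: float = field(default=float("nan"))
    spill: bool = False


def _action_cost(a: Action, rp: RewardParams) -> float:
    if a == Action.DO_NOTHING:
        return 0.0
    if a == Action.MONITOR:
        return rp.monitor_cost
    return rp.action_cost


def reward(x: float, a: Action, rp: RewardParams) -> float:
    """Immediate reward for population ``x`` under action ``a``.

    band_reward inside [band_lo, band_hi] (inclusive), minus the action's
    cost.
    """
    if x < 0:
        raise ValueError(f"population size must be non-negative, got {x}")
    in_band = rp.band_lo <= x <= rp.band_hi
    return (rp.band_reward if in_band else 0.0) - _action_cost(Action(a), rp)


def step_detail(
    x: float,
    a: Action,
    params: PopulationParams,
    rng: np.random.Generator,
) -> tuple[float, bool, float]:
    """Advance the population one year; also report spill occurrence.

    Returns ``(x_next, spill_occurred, damage_fraction)``.  The three
    random draws (noise, spill uniform, damage) are consumed in a fixed
    order every call so that trajectories are reproducible regardless of
    which branches are taken.
    """
    a = Action(a)
    if not 0.0 <= x <= params.pop_max:
        raise ValueError(f"population {x} outside [0, {params.pop_max}]")

    eps = rng.normal(0.0, params.sigma)
    u = rng.uniform()
    f_eff = params.f
    damage_hi = params.damage_max
    if a == Action.REDUCE_FREQ:
        f_eff = params.f * (1.0 - params.effect_freq_reduction)
    elif a == Action.REDUCE_DAMAGE:
        damage_hi = params.damage_max * (1.0 - params.effect_damage_reduction)
    d = rng.uniform(params.damage_min, damage_hi)

    spill = bool(u < f_eff)
    damage = d if spill else 0.0
    grown = x * np.exp(params.r * (1.0 - x / params.K) + eps)
    x_next = grown * (1.0 - damage)
    if a == Action.INTRODUCE:
        x_next += params.intro_count
    x_next = float(np.clip(x_next, 0.0, params.pop_max))
    if x_next < 1.0:  # fewer than one animal: extinct
        x_next = 0.0
    return x_next, spill, damage


def step(
    x: float,
    a: Action,
    params: PopulationParams,
    rng: np.random.Generator,
) -> float:
    """Advance the population one year under action ``a``; see module docs."""
    return step_detail(x, a, params, rng)[0]


def simulate_trajectory(
    x0: float,
    policy: Callable[[float], Action],
    length: int,
    params: PopulationParams,
    rp: RewardParams,
    rng: np.random.Generator,
) -> list[Datapoint]:
    """Simulate ``length`` annual transitions starting from ``x0``.

    ``policy`` maps the current population size to an action.  Consecutive
    datapoints chain: datapoint i's ``x_next`` is datapoint i+1's ``x_t``.
    """
    if length < 1:
        raise ValueError("trajectory length must be >= 1")
    out: list[Datapoint] = []
    x = float(x0)
    for _ in range(length):
        a = Action(policy(x))
        x_next, spill, _ = step_detail(x, a, params, rng)
        out.append(
            Datapoint(x_t=x, a_t=a, x_next=x_next, r_t=reward(x, a, rp), spill=spill)
        )
        x = x_next
    return out


def trajectory_to_csv(datapoints: Sequence[Datapoint], path: str) -> None:
    """Write a trajectory as CSV (t, x_t, action, x_next, reward, spill_occurred)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["t", "x_t", "action", "x_next", "reward", "spill_occurred"])
        for t, d in enumerate(datapoints):
            w.writerow(
                [t, f"{d.x_t:.6f}", Action(d.a_t).name, f"{d.x_next:.6f}", d.r_t,
                 int(d.spill)]
            )
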