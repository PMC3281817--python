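"""Assemble the finite POMDP from a learned discretization.

The fully observed problem needs only two actions in practice (re-introduce
below the policy boundary, reduce spill damage above it), so the manager
only ever has to distinguish "small" from "large" populations.  The POMDP
therefore uses a two-letter observation alphabet.  States far from the
boundary are always observed correctly; states within a window around the
boundary are observed correctly with probability 0.5, rising to 0.95 when
the monitoring action is taken.  Monitoring leaves the population dynamics
untouched and costs less than a management action.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .cutree import Discretization, policy_boundary
from .population import Action, RewardParams

__all__ = [
    "SMALL",
    "LARGE",
    "OBSERVATIONS",
    "ObservationParams",
    "PomdpModel",
    "classify_state",
    "build_observation_model",
    "assemble_pomdp",
    "uniform_belief",
]

SMALL, LARGE = 0, 1
OBSERVATIONS = ("small", "large")


@dataclass
class ObservationParams:
    """Detection model around the policy boundary.

    ``boundary`` is the population size where the optimal management
    action changes; if None it is taken from the discretization's own
    policy.  States overlapping [boundary - window_radius,
    boundary + window_radius] are observed correctly with probability
    ``p_correct_inside`` (``p_correct_inside_monitor`` under monitoring);
    all other states are observed perfectly.  The default radius of 125
    otters gives a detection window 250 otters wide in total.
    """

    boundary: Optional[float] = None
    window_radius: float = 125.0
    p_correct_inside: float = 0.5
    p_correct_inside_monitor: float = 0.95

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_correct_inside <= self.p_correct_inside_monitor <= 1.0:
            raise ValueError(
                "need 0 <= p_correct_inside <= p_correct_inside_monitor <= 1"
            )
        if self.window_radius <= 0:
            raise ValueError("window_radius must be positive")


@dataclass
class PomdpModel:
    """Finite POMDP: named states over leaf intervals, 5 actions, 2 observations.

    Tensor conventions: ``T[a, s, s']`` transition probabilities,
    ``R[s, a]`` immediate rewards, ``O[a, s', o]`` probability of observing
    ``o`` after action ``a`` lands the system in ``s'``.
    """

    state_intervals: list[tuple[float, float]]
    T: np.ndarray  # (A, S, S)
    R: np.ndarray  # (S, A)
    O: np.ndarray  # (A, S, |O|)
    gamma: float
    b0: np.ndarray
    actions: tuple[Action, ...] = tuple(Action)
    observations: tuple[str, ...] = OBSERVATIONS
    state_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        self.O = np.asarray(self.O, dtype=float)
        self.b0 = np.asarray(self.b0, dtype=float)
        if not self.state_names:
            self.state_names = [
                f"s{i}_{int(lo)}_{int(hi)}"
                for i, (lo, hi) in enumerate(self.state_intervals)
            ]
        self.validate()

    @property
    def n_states(self) -> int:
        return self.T.shape[1]

    @property
    def n_actions(self) -> int:
        return self.T.shape[0]

    @property
    def n_observations(self) -> int:
        return self.O.shape[2]

    def validate(self) -> None:
        A, S = self.T.shape[0], self.T.shape[1]
        if self.T.shape != (A, S, S):
            raise ValueError("T must have shape (A, S, S)")
        if self.R.shape != (S, A):
            raise ValueError("R must have shape (S, A)")
        if self.O.shape[0] != A or self.O.shape[1] != S:
            raise ValueError("O must have shape (A, S, n_obs)")
        if not np.allclose(self.T.sum(axis=2), 1.0, atol=1e-9):
            raise ValueError("T rows must sum to 1")
        if not np.allclose(self.O.sum(axis=2), 1.0, atol=1e-9):
            raise ValueError("O rows must sum to 1")
        if not np.isclose(self.b0.sum(), 1.0, atol=1e-9) or np.any(self.b0 < -1e-12):
            raise ValueError("b0 must be a probability distribution")
        if not 0.0 < self.gamma < 1.0:
            raise ValueError("gamma must lie in (0, 1)")


def uniform_belief(n_states: int) -> np.ndarray:
    return np.full(n_states, 1.0 / n_states)


def classify_state(lo: float, hi: float, boundary: float) -> int:
    """SMALL if the leaf [lo, hi) lies below the boundary, LARGE above.

    A leaf straddling the boundary signals a discretization/boundary
    mismatch and is an error.
    """
    if lo < boundary < hi:
        raise ValueError(
            f"leaf [{lo}, {hi}) straddles the observation boundary {boundary}"
        )
    return SMALL if hi <= boundary else LARGE


def window_state_mask(
    disc: Discretization,
    op: ObservationParams,
    boundary: Optional[float] = None,
) -> np.ndarray:
    """Boolean mask of leaves subject to observation error.

    A leaf is ambiguously observed only when it lies wholly inside the
    detection window [boundary - window_radius, boundary + window_radius];
    states extending beyond the window (in particular the wide reward-band
    state) are observed exactly.
    """
    boundary = boundary if boundary is not None else op.boundary
    if boundary is None:
        boundary = policy_boundary(disc)
    if boundary is None:
        raise ValueError("no policy boundary available for the observation model")
    lo_w, hi_w = boundary - op.window_radius, boundary + op.window_radius
    lo = disc.edges[:-1]
    hi = disc.edges[1:]
    return (lo >= lo_w) & (hi <= hi_w)


def build_observation_model(
    disc: Discretization,
    op: ObservationParams,
    n_actions: int = len(Action),
) -> np.ndarray:
    """Observation tensor O[a, s', o] for the two-letter alphabet.

    States wholly inside the detection window are observed correctly with
    probability ``p_correct_inside`` (rising under monitoring); all other
    states are observed perfectly.
    """
    boundary = op.boundary if op.boundary is not None else policy_boundary(disc)
    if boundary is None:
        raise ValueError("no policy boundary available for the observation model")
    if not np.any(np.isclose(disc.edges, boundary)):
        raise ValueError(f"boundary {boundary} does not coincide with a leaf edge")
    inside = window_state_mask(disc, op, boundary)
    S = disc.n_leaves
    O = np.zeros((n_actions, S, 2))
    for s in range(S):
        lo, hi = float(disc.edges[s]), float(disc.edges[s + 1])
        correct = classify_state(lo, hi, boundary)
        for a in range(n_actions):
            if not inside[s]:
                p = 1.0
            elif a == Action.MONITOR:
                p = op.p_correct_inside_monitor
            else:
                p = op.p_correct_inside
            O[a, s, correct] = p
            O[a, s, 1 - correct] = 1.0 - p
    return O


def assemble_pomdp(
    disc: Discretization,
    op: ObservationParams,
    rp: RewardParams,
    gamma: Optional[float] = None,
) -> PomdpModel:
    """Build the 5-action POMDP over the discretization's leaf states.

    Transitions and rewards for the four management actions are the
    empirical CU-Tree estimates; monitoring clones the do-nothing dynamics
    and subtracts the monitoring cost from its reward.  The initial belief
    is uniform.
    """
    if disc.T is None or disc.R is None:
        raise ValueError("discretization carries no estimated models")
    if disc.n_leaves < 2:
        raise ValueError("need at least 2 states to build the POMDP")
    S = disc.n_leaves
    A = len(Action)
    T = np.zeros((A, S, S))
    R = np.zeros((S, A))
    for a in range(4):
        T[a] = disc.T[:, a, :]
        R[:, a] = disc.R[:, a]
    T[Action.MONITOR] = disc.T[:, Action.DO_NOTHING, :]
    R[:, Action.MONITOR] = disc.R[:, Action.DO_NOTHING] - rp.monitor_cost
    O = build_observation_model(disc, op)
    intervals = [(float(disc.edges[i]), float(disc.edges[i + 1])) for i in range(S)]
    return PomdpModel(
        state_intervals=intervals,
        T=T,
        R=R,
        O=O,
        gamma=disc.gamma if gamma is None else gamma,
        b0=uniform_belief(S),
    )
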