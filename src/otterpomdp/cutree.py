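"""Continuous U-Tree discretization of the population axis.

CU-Tree alternates a data-gathering phase (simulating the population under
an exploratory policy) with an expansion phase.  In the expansion phase
each leaf of the current partition estimates empirical transition and
reward models, value iteration produces state values, every stored
datapoint receives a one-step return estimate

    q = r_t + gamma * V(leaf(x_next)),

and each leaf is tested for a split: candidate thresholds lie midway
between adjacent distinct sorted population sizes, the threshold with the
largest two-sample Kolmogorov-Smirnov statistic between the q samples on
either side is selected, and the split is kept if it is statistically
significant.  Splitting stops when no leaf can be split or after a fixed
number of sampling loops.

Because the selected threshold is the maximum of many correlated KS
statistics, the default significance rule Bonferroni-corrects the selected
p-value by the number of candidate thresholds; set
``split_correction="none"`` for the uncorrected per-test rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import stats

from .population import (
    MANAGEMENT_ACTIONS,
    Action,
    PopulationParams,
    RewardParams,
    simulate_trajectory,
)

__all__ = [
    "LeafState",
    "SplitCandidate",
    "CutreeConfig",
    "Discretization",
    "estimate_models",
    "bellman_solve",
    "assign_datapoint_q",
    "best_split",
    "run_cutree",
    "policy_boundary",
    "action_change_boundary",
]

N_ACTIONS = len(MANAGEMENT_ACTIONS)


@dataclass(frozen=True)
class LeafState:
    """A leaf of the partition: the half-open interval [lo, hi)."""

    lo: float
    hi: float
    id: int


@dataclass(frozen=True)
class SplitCandidate:
    """The best trial split found inside one leaf."""

    leaf_id: int
    threshold: float
    ks_statistic: float
    p_value: float  # raw asymptotic two-sample KS p-value
    p_adjusted: float  # after multiple-candidate correction


@dataclass
class CutreeConfig:
    """Knobs of the CU-Tree run.

    One 50-step trajectory is simulated per sampling loop and the sampling
    loop repeats 250 times, so a full run stores up to 12,500 datapoints.
    """

    n_loops: int = 250
    n_trajectories: int = 1
    traj_length: int = 50
    alpha: float = 0.05
    gamma: float = 0.95
    min_leaf_size: int = 10
    split_correction: str = "bonferroni"  # or "none"
    bellman_tol: float = 1e-9

    def __post_init__(self) -> None:
        if not 0.0 < self.gamma < 1.0:
            raise ValueError("gamma must lie in (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.split_correction not in ("bonferroni", "none"):
            raise ValueError("split_correction must be 'bonferroni' or 'none'")


@dataclass
class Discretization:
    """An ordered partition of [0, pop_max) with per-state MDP estimates.

    ``edges`` has length L+1 (edges[0] = 0, edges[-1] = pop_max); leaf i is
    [edges[i], edges[i+1]).  The final leaf also absorbs x = pop_max.
    Datapoints are stored as parallel arrays; T, R, Q, V are the empirical
    transition tensor, expected immediate rewards, action values and state
    values over the current leaves.
    """

    edges: np.ndarray
    gamma: float = 0.95
    x: np.ndarray = field(default_factory=lambda: np.empty(0))
    a: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    xn: np.ndarray = field(default_factory=lambda: np.empty(0))
    r: np.ndarray = field(default_factory=lambda: np.empty(0))
    q: np.ndarray = field(default_factory=lambda: np.empty(0))
    T: Optional[np.ndarray] = None  # (L, A, L)
    R: Optional[np.ndarray] = None  # (L, A)
    N: Optional[np.ndarray] = None  # visit counts, (L, A)
    Q: Optional[np.ndarray] = None  # (L, A)
    V: Optional[np.ndarray] = None  # (L,)

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        if self.edges.size < 2 or np.any(np.diff(self.edges) <= 0):
            raise ValueError("edges must be strictly increasing with >= 2 entries")

    @property
    def n_leaves(self) -> int:
        return len(self.edges) - 1

    @property
    def leaves(self) -> list[LeafState]:
        return [
            LeafState(lo=float(self.edges[i]), hi=float(self.edges[i + 1]), id=i)
            for i in range(self.n_leaves)
        ]

    def leaf_index(self, x) -> np.ndarray:
        """Map population sizes to leaf ids (vectorized)."""
        idx = np.searchsorted(self.edges, np.asarray(x, dtype=float), side="right") - 1
        return np.clip(idx, 0, self.n_leaves - 1)

    def add_datapoints(self, x, a, xn, r) -> None:
        self.x = np.concatenate([self.x, np.asarray(x, dtype=float)])
        self.a = np.concatenate([self.a, np.asarray(a, dtype=np.int64)])
        self.xn = np.concatenate([self.xn, np.asarray(xn, dtype=float)])
        self.r = np.concatenate([self.r, np.asarray(r, dtype=float)])
        self.q = np.concatenate([self.q, np.full(len(np.atleast_1d(x)), np.nan)])

    def split_leaf(self, leaf_id: int, threshold: float) -> None:
        lo, hi = self.edges[leaf_id], self.edges[leaf_id + 1]
        if not lo < threshold < hi:
            raise ValueError(
                f"threshold {threshold} not inside leaf [{lo}, {hi})"
            )
        self.edges = np.insert(self.edges, leaf_id + 1, threshold)
        # model arrays are stale after a split
        self.T = self.R = self.N = self.Q = self.V = None

    @property
    def policy(self) -> np.ndarray:
        """Greedy policy: argmax_a Q(s, a); ties break to the lowest action id."""
        if self.Q is None:
            raise ValueError("run bellman_solve before extracting a policy")
        return np.argmax(self.Q, axis=1)

    def to_json(self, path: str) -> None:
        if self.Q is None or self.T is None:
            raise ValueError("estimate models and solve before serializing")
        payload = {
            "edges": self.edges.tolist(),
            "gamma": self.gamma,
            "T": self.T.tolist(),
            "R": self.R.tolist(),
            "Q": self.Q.tolist(),
            "V": self.V.tolist(),
            "policy": [Action(int(p)).name for p in self.policy],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "Discretization":
        with open(path) as fh:
            payload = json.load(fh)
        disc = cls(edges=np.asarray(payload["edges"]), gamma=payload["gamma"])
        disc.T = np.asarray(payload["T"])
        disc.R = np.asarray(payload["R"])
        disc.Q = np.asarray(payload["Q"])
        disc.V = np.asarray(payload["V"])
        return disc

    def policy_table(self) -> str:
        """Human-readable interval -> optimal action table."""
        pol = self.policy
        lines = ["interval (otters)      optimal action"]
        for i in range(self.n_leaves):
            lines.append(
                f"[{self.edges[i]:7.1f}, {self.edges[i+1]:7.1f})   "
                f"{Action(int(pol[i])).name}"
            )
        return "\n".join(lines)


def estimate_models(disc: Discretization) -> Discretization:
    """Empirical transition/reward estimates from the stored datapoints.

    T(s, a, s') is the fraction of stored transitions from leaf s under a
    that land in leaf s'; R(s, a) the mean stored reward.  (s, a) pairs
    with no data self-loop with zero reward.
    """
    L, A = disc.n_leaves, N_ACTIONS
    if L < 1:
        raise ValueError("empty discretization")
    s = disc.leaf_index(disc.x)
    sn = disc.leaf_index(disc.xn)
    a = disc.a
    counts = np.bincount(
        (s * A + a) * L + sn, minlength=L * A * L
    ).reshape(L, A, L).astype(float)
    n_sa = counts.sum(axis=2)
    r_sum = np.bincount(s * A + a, weights=disc.r, minlength=L * A).reshape(L, A)

    T = np.zeros((L, A, L))
    has = n_sa > 0
    T[has] = counts[has] / n_sa[has][:, None]
    for i in range(L):  # unvisited pairs: self-loop
        for j in range(A):
            if not has[i, j]:
                T[i, j, i] = 1.0
    R = np.zeros((L, A))
    R[has] = r_sum[has] / n_sa[has]
    disc.T, disc.R, disc.N = T, R, n_sa
    return disc


def bellman_solve(
    disc: Discretization,
    tol: float = 1e-9,
    max_iter: int = 100000,
) -> Discretization:
    """Value iteration to a sup-norm fixed point of the Bellman equation.

    Q(s,a) = R(s,a) + gamma * sum_s' T(s,a,s') V(s');  V(s) = max_a Q(s,a).
    A previous V, if present, warm-starts the iteration.
    """
    if disc.T is None or disc.R is None:
        raise ValueError("run estimate_models first")
    T, R, gamma = disc.T, disc.R, disc.gamma
    row_sums = T.sum(axis=2)
    if not np.allclose(row_sums, 1.0, atol=1e-9):
        raise ValueError("transition matrix rows must sum to 1")
    V = disc.V if disc.V is not None and disc.V.shape == (disc.n_leaves,) else np.zeros(
        disc.n_leaves
    )
    if gamma == 0.0:
        Q = R.copy()
        disc.Q, disc.V = Q, Q.max(axis=1)
        return disc
    for _ in range(max_iter):
        Q = R + gamma * np.einsum("sat,t->sa", T, V)
        V_new = Q.max(axis=1)
        if np.max(np.abs(V_new - V)) < tol:
            V = V_new
            break
        V = V_new
    disc.Q = R + gamma * np.einsum("sat,t->sa", T, V)
    disc.V = disc.Q.max(axis=1)
    return disc


def assign_datapoint_q(disc: Discretization, gamma: Optional[float] = None) -> Discretization:
    """Set every datapoint's return estimate q = r_t + gamma * V(leaf(x_next))."""
    if disc.V is None:
        raise ValueError("run bellman_solve first")
    g = disc.gamma if gamma is None else gamma
    if np.any(disc.xn < 0) or np.any(disc.xn > disc.edges[-1]):
        raise ValueError("x_next outside the modelled population range")
    disc.q = disc.r + g * disc.V[disc.leaf_index(disc.xn)]
    return disc


def _ks_scan(xs: np.ndarray, qs: np.ndarray, min_leaf_size: int):
    """KS statistic of q-left vs q-right at every admissible threshold.

    ``xs`` must be sorted ascending.  Admissible thresholds fall between
    adjacent *distinct* x values with at least ``min_leaf_size`` points on
    each side.  Returns (split_positions m, D values); left = first m
    points.  Exact D, computed against the pooled unique q values.
    """
    n = len(xs)
    m_all = np.arange(min_leaf_size, n - min_leaf_size + 1)
    if m_all.size == 0:
        return m_all, np.empty(0)
    distinct = xs[m_all] > xs[m_all - 1]
    M = m_all[distinct]
    if M.size == 0:
        return M, np.empty(0)
    _, codes = np.unique(qs, return_inverse=True)
    u = codes.max() + 1
    if u == 1:
        return M, np.zeros(M.size)
    onehot = np.zeros((n, u))
    onehot[np.arange(n), codes] = 1.0
    C = np.vstack([np.zeros(u), np.cumsum(onehot, axis=0)])  # (n+1, u)
    tot = C[-1]
    Csel = C[M]
    # per-atom mass left/right of each split; cumulative sum gives the CDFs
    FL = np.cumsum(Csel / M[:, None], axis=1)
    FR = np.cumsum((tot - Csel) / (n - M)[:, None], axis=1)
    D = np.abs(FL - FR).max(axis=1)
    return M, D


def best_split(
    disc: Discretization,
    leaf_id: int,
    cfg: CutreeConfig,
) -> Optional[SplitCandidate]:
    """Best significant trial split of one leaf, or None.

    Datapoints in the leaf are sorted by population size; the threshold
    with the largest KS statistic between the q samples left and right is
    tested for significance (asymptotic two-sample KS p-value, corrected
    for the number of candidates under the default rule).
    """
    in_leaf = disc.leaf_index(disc.x) == leaf_id
    if in_leaf.sum() < max(2, 2 * cfg.min_leaf_size):
        return None
    xs = disc.x[in_leaf]
    qs = disc.q[in_leaf]
    order = np.argsort(xs, kind="stable")
    xs, qs = xs[order], qs[order]
    M, D = _ks_scan(xs, qs, cfg.min_leaf_size)
    if M.size == 0 or np.all(D <= 0):
        return None
    i_best = int(np.argmax(D))
    m = int(M[i_best])
    res = stats.ks_2samp(qs[:m], qs[m:], method="asymp")
    p_raw = float(res.pvalue)
    n_cand = M.size
    p_adj = min(1.0, p_raw * n_cand) if cfg.split_correction == "bonferroni" else p_raw
    threshold = float(0.5 * (xs[m - 1] + xs[m]))
    lo, hi = disc.edges[leaf_id], disc.edges[leaf_id + 1]
    if not lo < threshold < hi:
        return None
    cand = SplitCandidate(
        leaf_id=leaf_id,
        threshold=threshold,
        ks_statistic=float(D[i_best]),
        p_value=p_raw,
        p_adjusted=p_adj,
    )
    return cand if p_adj < cfg.alpha else None


def run_cutree(
    params: PopulationParams,
    rp: RewardParams,
    cfg: CutreeConfig,
    rng: np.random.Generator,
) -> tuple[Discretization, np.ndarray]:
    """Learn a discretization and greedy policy for the population model.

    Alternates data gathering (uniform-random exploration: initial
    populations uniform on [0, pop_max), uniform-random management action
    each step) with expansion (model estimation, value iteration, q
    assignment, and a split attempt on every leaf).  Runs for
    ``cfg.n_loops`` sampling loops; datapoints accumulate across loops, so
    an expansion phase that adds no split is not terminal — later loops
    have more statistical power and may split again.
    """
    disc = Discretization(edges=np.array([0.0, params.pop_max]), gamma=cfg.gamma)

    def explore_policy(_x: float) -> Action:
        return MANAGEMENT_ACTIONS[rng.integers(N_ACTIONS)]

    for _ in range(cfg.n_loops):
        for _ in range(cfg.n_trajectories):
            x0 = rng.uniform(0.0, params.pop_max)
            traj = simulate_trajectory(x0, explore_policy, cfg.traj_length, params, rp, rng)
            disc.add_datapoints(
                [d.x_t for d in traj],
                [int(d.a_t) for d in traj],
                [d.x_next for d in traj],
                [d.r_t for d in traj],
            )
        estimate_models(disc)
        bellman_solve(disc, tol=cfg.bellman_tol)
        assign_datapoint_q(disc)
        candidates = [
            c
            for lid in range(disc.n_leaves)
            if (c := best_split(disc, lid, cfg)) is not None
        ]
        if candidates:
            # apply right-to-left so earlier leaf ids stay valid
            for c in sorted(candidates, key=lambda c: c.leaf_id, reverse=True):
                disc.split_leaf(c.leaf_id, c.threshold)
            estimate_models(disc)
            bellman_solve(disc, tol=cfg.bellman_tol)
            assign_datapoint_q(disc)

    estimate_models(disc)
    bellman_solve(disc, tol=cfg.bellman_tol)
    assign_datapoint_q(disc)
    return disc, disc.policy


def policy_boundary(
    disc: Discretization,
    from_action: Action = Action.INTRODUCE,
    to_action: Action = Action.REDUCE_DAMAGE,
) -> Optional[float]:
    """Smallest leaf edge where the greedy policy switches from
    ``from_action`` (below) to ``to_action`` (above); None if absent."""
    pol = disc.policy
    for i in range(disc.n_leaves - 1):
        if pol[i] == from_action and pol[i + 1] == to_action:
            return float(disc.edges[i + 1])
    return None


def action_change_boundary(disc: Discretization) -> Optional[float]:
    """Population size where the learned management action changes.

    The strict INTRODUCE-to-REDUCE_DAMAGE edge when the policy contains
    one; otherwise the first edge where the policy switches away from
    INTRODUCE; otherwise the first action change at all.  None only for a
    constant policy.
    """
    strict = policy_boundary(disc)
    if strict is not None:
        return strict
    pol = disc.policy
    for i in range(disc.n_leaves - 1):
        if pol[i] == Action.INTRODUCE and pol[i + 1] != Action.INTRODUCE:
            return float(disc.edges[i + 1])
    for i in range(disc.n_leaves - 1):
        if pol[i] != pol[i + 1]:
            return float(disc.edges[i + 1])
    return None
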