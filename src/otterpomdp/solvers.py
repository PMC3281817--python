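"""POMDP solvers over alpha-vector value functions.

The optimal finite-horizon value function of a POMDP is piecewise linear
and convex in the belief: the upper surface of a finite set of alpha
vectors, each tagged with the action of the conditional plan it
represents.  Two solvers are provided:

* :func:`solve_exact_finite` — exact value iteration by incremental
  pruning: per action and observation the projected sets are pruned, the
  observation cross-sums are pruned incrementally, and the union over
  actions is pruned again.  Pruning removes pointwise-dominated vectors
  first and then vectors with no witness belief (an LP per vector).
* :func:`solve_perseus` — randomized point-based value iteration for the
  infinite horizon: backups are performed at beliefs sampled by random
  exploration, and each sweep improves the value at every sampled belief
  while typically adding far fewer vectors than exact iteration.

Policies are executed by taking the action of the maximizing vector at
the current belief; :func:`extract_policy_graph` turns a solution into a
finite-state controller.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx
import numpy as np
from scipy.optimize import linprog

from .pomdp import PomdpModel
from .population import Action

__all__ = [
    "AlphaVector",
    "AlphaVectorSet",
    "ImpossibleObservationError",
    "VectorBudgetExceeded",
    "belief_update",
    "point_backup",
    "prune",
    "solve_exact_finite",
    "solve_perseus",
    "extract_policy_graph",
    "policy_graph_to_dot",
]


class ImpossibleObservationError(ValueError):
    """Raised when conditioning a belief on a zero-probability observation."""


class VectorBudgetExceeded(RuntimeError):
    """Exact solve produced more vectors than the configured budget."""


@dataclass(frozen=True)
class AlphaVector:
    """A linear value function over beliefs, tagged with its action."""

    coefficients: np.ndarray
    action: int

    def __post_init__(self):
        object.__setattr__(
            self, "coefficients", np.asarray(self.coefficients, dtype=float)
        )
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("alpha vector coefficients must be finite")

    def value(self, b: np.ndarray) -> float:
        return float(self.coefficients @ b)


@dataclass
class AlphaVectorSet:
    """A set of alpha vectors; the value at b is the max dot product."""

    vectors: list[AlphaVector] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.vectors)

    def __iter__(self):
        return iter(self.vectors)

    def matrix(self) -> np.ndarray:
        return np.stack([v.coefficients for v in self.vectors])

    def value(self, b: np.ndarray) -> float:
        return float(np.max(self.matrix() @ b))

    def best(self, b: np.ndarray) -> AlphaVector:
        """Maximizing vector at b; ties break to the earliest vector."""
        return self.vectors[int(np.argmax(self.matrix() @ b))]

    def action(self, b: np.ndarray) -> int:
        return self.best(b).action


def belief_update(
    b: np.ndarray, a: int, o: int, m: PomdpModel
) -> tuple[np.ndarray, float]:
    """Bayes filter step: posterior over states after action a, observation o.

    Returns the normalized posterior and the normalizing constant
    P(o | b, a).  A zero-probability observation raises
    :class:`ImpossibleObservationError`.
    """
    pred = m.T[a].T @ b
    unnorm = m.O[a, :, o] * pred
    prob = float(unnorm.sum())
    if prob <= 0.0:
        raise ImpossibleObservationError(
            f"observation {o} has zero probability after action {a}"
        )
    return unnorm / prob, prob


def _projections(M: np.ndarray, m: PomdpModel) -> list[list[np.ndarray]]:
    """proj[a][o][k] = T_a (O_{a,o} * alpha_k): the gamma-free successor
    projections of every vector, reusable across backups of one sweep."""
    return [
        [(M * m.O[a, :, o]) @ m.T[a].T for o in range(m.n_observations)]
        for a in range(m.n_actions)
    ]


def point_backup(
    b: np.ndarray,
    G: AlphaVectorSet,
    m: PomdpModel,
    proj: Optional[list[list[np.ndarray]]] = None,
) -> AlphaVector:
    """One Bellman backup of the value function G at belief b.

    For each action the best successor vector per observation is chosen at
    b, and the action maximizing the backed-up value at b is returned.
    ``proj`` may carry precomputed projections of G (see
    :func:`_projections`) when many beliefs are backed up against the same
    vector set.
    """
    if len(G) == 0:
        raise ValueError("cannot back up an empty vector set")
    if proj is None:
        proj = _projections(G.matrix(), m)
    best_val = -np.inf
    best_vec: Optional[AlphaVector] = None
    for a in range(m.n_actions):
        g = m.R[:, a].astype(float).copy()
        for o in range(m.n_observations):
            p = proj[a][o]
            k = int(np.argmax(p @ b))
            g = g + m.gamma * p[k]
        val = float(g @ b)
        if val > best_val:
            best_val = val
            best_vec = AlphaVector(g, a)
    return best_vec


def _pointwise_prune(M: np.ndarray) -> np.ndarray:
    """Keep-mask dropping vectors pointwise-dominated by an earlier-or-
    strictly-better vector (rows assumed already deduplicated)."""
    n = M.shape[0]
    keep = np.ones(n, dtype=bool)
    for j in range(n):
        if not keep[j]:
            continue
        dominated = np.all(M <= M[j], axis=1)
        dominated[j] = False
        dominated &= keep
        keep[dominated] = False
    return keep


def _witness(alpha: np.ndarray, kept: np.ndarray, tol: float) -> Optional[np.ndarray]:
    """Belief where ``alpha`` strictly beats every vector in ``kept``.

    LP: max d  s.t.  b (alpha - psi) >= d for all psi in kept, b in simplex.
    Returns the witness belief, or None if alpha is dominated.
    """
    S = alpha.size
    if kept.shape[0] == 0:
        b = np.zeros(S)
        b[0] = 1.0
        return b
    c = np.zeros(S + 1)
    c[-1] = -1.0  # maximize d
    A_ub = np.hstack([kept - alpha, np.ones((kept.shape[0], 1))])
    b_ub = np.zeros(kept.shape[0])
    A_eq = np.zeros((1, S + 1))
    A_eq[0, :S] = 1.0
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=np.array([1.0]),
                  bounds=[(0.0, 1.0)] * S + [(None, None)], method="highs")
    if not res.success or -res.fun <= tol:
        return None
    return res.x[:S]


def prune(vectors: list[AlphaVector], tol: float = 1e-12) -> list[AlphaVector]:
    """Remove duplicated, pointwise-dominated and LP-dominated vectors.

    The surviving set represents exactly the same value function.  Uses
    Lark's witness-agenda filter: a candidate is kept only after an LP
    finds a belief where it beats everything kept so far, and the vector
    actually installed is the best remaining candidate at that belief.
    Ties (duplicates, equal values at a witness) resolve toward the
    earlier-generated vector.
    """
    if len(vectors) <= 1:
        return list(vectors)
    M0 = np.stack([v.coefficients for v in vectors])
    # deduplicate via rounding, earliest kept
    _, first = np.unique(np.round(M0, 9), axis=0, return_index=True)
    order = np.sort(first)
    M = M0[order]
    keep = _pointwise_prune(M)
    M, order = M[keep], order[keep]
    n = M.shape[0]
    in_agenda = np.ones(n, dtype=bool)
    kept_idx: list[int] = []
    # seed with the maximizers at the simplex corners (classic speed-up)
    for s in range(M.shape[1]):
        i = int(np.argmax(M[:, s]))
        if in_agenda[i]:
            in_agenda[i] = False
            kept_idx.append(i)
    agenda = [i for i in range(n) if in_agenda[i]]
    while agenda:
        i = agenda[0]
        b = _witness(M[i], M[kept_idx], tol)
        if b is None:
            agenda.pop(0)
            continue
        vals = M[agenda] @ b
        j = agenda[int(np.argmax(vals))]  # argmax -> earliest on ties
        kept_idx.append(j)
        agenda.remove(j)
    kept_idx.sort()
    return [vectors[order[i]] for i in kept_idx]


def _cross_sum(
    A_set: list[AlphaVector], B_set: list[AlphaVector], action: int
) -> list[AlphaVector]:
    return [
        AlphaVector(a.coefficients + b.coefficients, action)
        for a in A_set
        for b in B_set
    ]


def solve_exact_finite(
    m: PomdpModel,
    horizon: int,
    max_vectors: int = 100000,
) -> list[AlphaVectorSet]:
    """Exact optimal value functions for horizons 1..horizon.

    Incremental pruning: per action a and observation o the projected set
    { R(.,a)/|O| + gamma * T_a (O_{a,o} * alpha) : alpha in G } is pruned,
    cross-sums over observations are pruned incrementally, and the union
    over actions is pruned once more.  Raises
    :class:`VectorBudgetExceeded` if an intermediate set outgrows
    ``max_vectors`` (use the point-based solver instead).
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    stages: list[AlphaVectorSet] = []
    G = [AlphaVector(np.zeros(m.n_states), Action.DO_NOTHING)]
    Z = m.n_observations
    for _ in range(horizon):
        M = np.stack([v.coefficients for v in G])
        new_vectors: list[AlphaVector] = []
        for a in range(m.n_actions):
            per_obs: list[list[AlphaVector]] = []
            for o in range(Z):
                proj = (M * m.O[a, :, o]) @ m.T[a].T
                cand = [
                    AlphaVector(m.R[:, a] / Z + m.gamma * proj[k], a)
                    for k in range(proj.shape[0])
                ]
                per_obs.append(prune(cand))
            acc = per_obs[0]
            for o in range(1, Z):
                acc = prune(_cross_sum(acc, per_obs[o], a))
                if len(acc) > max_vectors:
                    raise VectorBudgetExceeded(
                        f"{len(acc)} vectors exceed the budget {max_vectors}; "
                        "use solve_perseus for long horizons"
                    )
            new_vectors.extend(acc)
        G = prune(new_vectors)
        if len(G) > max_vectors:
            raise VectorBudgetExceeded(
                f"{len(G)} vectors exceed the budget {max_vectors}"
            )
        stages.append(AlphaVectorSet(list(G)))
    return stages


def sample_beliefs(
    m: PomdpModel,
    n_beliefs: int,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Belief set for Perseus: random-action forward exploration from b0."""
    beliefs = [m.b0.copy()]
    b = m.b0.copy()
    while len(beliefs) < n_beliefs:
        a = int(rng.integers(m.n_actions))
        obs_probs = m.O[a].T @ (m.T[a].T @ b)
        obs_probs = np.clip(obs_probs, 0.0, None)
        total = obs_probs.sum()
        if total <= 0:
            b = m.b0.copy()
            continue
        o = int(rng.choice(m.n_observations, p=obs_probs / total))
        b, _ = belief_update(b, a, o, m)
        beliefs.append(b.copy())
        if rng.uniform() < 0.05:  # occasional restart for coverage
            b = m.b0.copy()
    return beliefs


def solve_perseus(
    m: PomdpModel,
    n_beliefs: int = 1000,
    rng: Optional[np.random.Generator] = None,
    epsilon: float = 1e-4,
    max_iter: int = 500,
) -> AlphaVectorSet:
    """Randomized point-based value iteration (Perseus).

    Starts from the blind lower bound min R / (1 - gamma) and sweeps:
    while some sampled belief has not yet improved, back up at a random
    such belief and keep the new vector only if it improves that belief.
    The value at every sampled belief is non-decreasing across sweeps;
    iteration stops when the largest improvement drops below ``epsilon``.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    B = np.stack(sample_beliefs(m, n_beliefs, rng))
    base = float(m.R.min()) / (1.0 - m.gamma)
    G = AlphaVectorSet(
        [AlphaVector(np.full(m.n_states, base), int(np.argmax(m.R.min(axis=0))))]
    )
    vals = (B @ G.matrix().T).max(axis=1)
    for _ in range(max_iter):
        proj = _projections(G.matrix(), m)
        improved = np.zeros(len(B), dtype=bool)
        new_vectors: list[AlphaVector] = []
        while not improved.all():
            pending = np.flatnonzero(~improved)
            i = int(pending[rng.integers(pending.size)])
            alpha = point_backup(B[i], G, m, proj=proj)
            if alpha.value(B[i]) >= vals[i] - 1e-12:
                new_vectors.append(alpha)
            else:
                new_vectors.append(G.best(B[i]))
            newM = new_vectors[-1].coefficients
            improved |= B @ newM >= vals - 1e-12
        G_new = AlphaVectorSet(_dedupe(new_vectors))
        vals_new = (B @ G_new.matrix().T).max(axis=1)
        delta = float(np.max(np.abs(vals_new - vals)))
        G, vals = G_new, vals_new
        if delta < epsilon:
            break
    return G


def _dedupe(vectors: list[AlphaVector], decimals: int = 9) -> list[AlphaVector]:
    out: list[AlphaVector] = []
    seen: set[bytes] = set()
    for v in vectors:
        key = np.round(v.coefficients, decimals).tobytes() + bytes([v.action])
        if key not in seen:
            seen.add(key)
            out.append(v)
    return out


def extract_policy_graph(
    G: AlphaVectorSet,
    m: PomdpModel,
    b0: Optional[np.ndarray] = None,
    max_nodes: int = 10000,
) -> nx.DiGraph:
    """Finite-state controller reachable from the initial belief.

    Nodes are the alpha vectors reached while executing the policy from
    ``b0`` (breadth-first over observations); each node carries its action,
    and edges are labelled with the observation that triggers them.  Each
    vector is represented by the first belief that reached it.
    """
    b0 = m.b0 if b0 is None else np.asarray(b0, dtype=float)
    M = G.matrix()

    def node_of(b: np.ndarray) -> int:
        return int(np.argmax(M @ b))

    g = nx.DiGraph()
    start = node_of(b0)
    g.add_node(start, action=int(G.vectors[start].action),
               action_name=Action(int(G.vectors[start].action)).name)
    g.graph["start"] = start
    queue = [(start, b0)]
    seen = {start}
    while queue and len(g) < max_nodes:
        node, b = queue.pop(0)
        a = int(G.vectors[node].action)
        for o in range(m.n_observations):
            try:
                b_next, prob = belief_update(b, a, o, m)
            except ImpossibleObservationError:
                continue
            nxt = node_of(b_next)
            if nxt not in seen:
                seen.add(nxt)
                g.add_node(nxt, action=int(G.vectors[nxt].action),
                           action_name=Action(int(G.vectors[nxt].action)).name)
                queue.append((nxt, b_next))
            if not g.has_edge(node, nxt):
                g.add_edge(node, nxt, observation=m.observations[o])
            else:
                lbl = g.edges[node, nxt]["observation"]
                if m.observations[o] not in lbl.split(","):
                    g.edges[node, nxt]["observation"] = lbl + "," + m.observations[o]
    return g


def policy_graph_to_dot(g: nx.DiGraph) -> str:
    """Render a policy graph as DOT text."""
    lines = ["digraph policy {", "  rankdir=LR;"]
    start = g.graph.get("start")
    for n, data in g.nodes(data=True):
        shape = "doublecircle" if n == start else "circle"
        lines.append(f'  n{n} [label="{data["action_name"]}", shape={shape}];')
    for u, v, data in g.edges(data=True):
        lines.append(f'  n{u} -> n{v} [label="{data["observation"]}"];')
    lines.append("}")
    return "\n".join(lines)
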