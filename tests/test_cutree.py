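"""Tests for the Continuous U-Tree discretization learner."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from otterpomdp import (
    Action,
    CutreeConfig,
    Discretization,
    PopulationParams,
    RewardParams,
    assign_datapoint_q,
    bellman_solve,
    best_split,
    estimate_models,
    policy_boundary,
    run_cutree,
    simulate_trajectory,
)
from otterpomdp.cutree import MANAGEMENT_ACTIONS, N_ACTIONS


def _disc_with_data(edges, x, a, xn, r, gamma=0.95):
    disc = Discretization(edges=np.asarray(edges, dtype=float), gamma=gamma)
    disc.add_datapoints(x, a, xn, r)
    return disc


class TestEstimateModels:
    def test_single_leaf_self_loops_for_every_action(self):
        disc = _disc_with_data(
            [0.0, 1000.0],
            x=[100, 200, 300, 400],
            a=[0, 1, 2, 3],
            xn=[150, 250, 350, 450],
            r=[0, 0, 0, 0],
        )
        estimate_models(disc)
        for a in range(N_ACTIONS):
            assert disc.T[0, a, 0] == 1.0

    def test_hand_counted_transition_fractions(self):
        # leaves [0,500) and [500,1000); 3 DO_NOTHING transitions from leaf 0,
        # 2 of which land in leaf 1; plus 1 INTRODUCE transition from leaf 1
        disc = _disc_with_data(
            [0.0, 500.0, 1000.0],
            x=[100, 200, 300, 600],
            a=[0, 0, 0, 3],
            xn=[600, 700, 400, 650],
            r=[0.0, 0.0, 0.0, 90.0],
        )
        estimate_models(disc)
        assert disc.T[0, 0, 1] == pytest.approx(2 / 3)
        assert disc.T[0, 0, 0] == pytest.approx(1 / 3)
        assert disc.T[1, 3, 1] == 1.0
        assert disc.R[1, 3] == 90.0
        # unvisited pairs self-loop with zero reward
        assert disc.T[1, 0, 1] == 1.0
        assert disc.R[1, 0] == 0.0

    def test_in_band_leaf_mean_reward_is_band_reward(self, det_params, rp):
        rng = np.random.default_rng(0)
        traj = simulate_trajectory(
            600.0, lambda x: Action.DO_NOTHING, 20, det_params, rp, rng
        )
        disc = _disc_with_data(
            [0.0, 497.0, 746.0, 1000.0],
            x=[d.x_t for d in traj],
            a=[int(d.a_t) for d in traj],
            xn=[d.x_next for d in traj],
            r=[d.r_t for d in traj],
        )
        estimate_models(disc)
        assert disc.R[1, 0] == 100.0

    def test_empty_discretization_rejected(self):
        with pytest.raises(ValueError):
            Discretization(edges=np.array([0.0]))


class TestBellman:
    def test_gamma_zero_gives_myopic_q(self):
        disc = _disc_with_data([0, 500, 1000], [100, 600], [0, 1], [600, 100], [5, 7])
        disc.gamma = 1e-12  # effectively myopic
        estimate_models(disc)
        bellman_solve(disc)
        assert disc.Q == pytest.approx(disc.R, abs=1e-6)

    def test_absorbing_state_geometric_series(self):
        disc = Discretization(edges=np.array([0.0, 1000.0]), gamma=0.95)
        disc.T = np.ones((1, N_ACTIONS, 1))
        disc.R = np.array([[100.0, 0.0, 0.0, 0.0]])
        bellman_solve(disc, tol=1e-12)
        assert disc.V[0] == pytest.approx(100.0 / (1 - 0.95), abs=1e-6)

    def test_random_mdp_matches_policy_enumeration_oracle(self):
        # brute force: enumerate all stationary policies of a 5-state MDP and
        # solve each by a linear system; the best must equal value iteration
        rng = np.random.default_rng(42)
        S, A, gamma = 5, N_ACTIONS, 0.9
        T = rng.dirichlet(np.ones(S), size=(S, A))
        R = rng.uniform(-10, 10, size=(S, A))
        disc = Discretization(edges=np.linspace(0, 1000, S + 1), gamma=gamma)
        disc.T, disc.R = T, R
        bellman_solve(disc, tol=1e-13)
        best = np.full(S, -np.inf)
        for pol in itertools.product(range(A), repeat=S):
            Tp = T[np.arange(S), pol]
            Rp = R[np.arange(S), pol]
            V = np.linalg.solve(np.eye(S) - gamma * Tp, Rp)
            best = np.maximum(best, V)
        assert disc.V == pytest.approx(best, abs=1e-6)

    def test_value_is_max_q(self):
        disc = _disc_with_data(
            [0, 250, 500, 1000],
            [100, 300, 600, 700],
            [0, 1, 2, 3],
            [300, 600, 700, 100],
            [0, 0, 100, 90],
        )
        estimate_models(disc)
        bellman_solve(disc)
        assert disc.V == pytest.approx(disc.Q.max(axis=1))

    def test_non_stochastic_transitions_rejected(self):
        disc = Discretization(edges=np.array([0.0, 1000.0]), gamma=0.9)
        disc.T = np.full((1, N_ACTIONS, 1), 0.5)
        disc.R = np.zeros((1, N_ACTIONS))
        with pytest.raises(ValueError):
            bellman_solve(disc)


class TestAssignQ:
    def test_gamma_zero_returns_immediate_reward(self):
        disc = _disc_with_data([0, 1000], [1, 2], [0, 0], [3, 4], [7.0, 9.0])
        disc.gamma = 0.5
        estimate_models(disc)
        bellman_solve(disc)
        assign_datapoint_q(disc, gamma=0.0)
        assert disc.q == pytest.approx(disc.r)

    def test_one_step_return_arithmetic(self):
        disc = _disc_with_data([0, 1000], [10.0], [0], [20.0], [90.0])
        disc.gamma = 0.95
        disc.T = np.ones((1, N_ACTIONS, 1))
        disc.R = np.zeros((1, N_ACTIONS))
        disc.V = np.array([2000.0])
        disc.Q = np.tile(disc.V[:, None], (1, N_ACTIONS))
        assign_datapoint_q(disc)
        assert disc.q[0] == pytest.approx(90.0 + 0.95 * 2000.0)

    def test_identical_transitions_get_identical_q(self):
        disc = _disc_with_data(
            [0, 500, 1000], [100, 150], [0, 0], [600, 650], [5.0, 5.0]
        )
        estimate_models(disc)
        bellman_solve(disc)
        assign_datapoint_q(disc)
        assert disc.q[0] == disc.q[1]


def _brute_force_ks(left, right):
    """Independent two-sample KS oracle: exhaustive D over pooled values,
    asymptotic p from the Kolmogorov series."""
    left, right = np.sort(left), np.sort(right)
    values = np.unique(np.concatenate([left, right]))
    D = 0.0
    for v in values:
        d = abs(
            np.searchsorted(left, v, side="right") / len(left)
            - np.searchsorted(right, v, side="right") / len(right)
        )
        D = max(D, d)
    en = len(left) * len(right) / (len(left) + len(right))
    lam = (math.sqrt(en) + 0.12 + 0.11 / math.sqrt(en)) * D
    p = 2 * sum((-1) ** (k - 1) * math.exp(-2 * k**2 * lam**2) for k in range(1, 101))
    return D, min(max(p, 0.0), 1.0)


class TestBestSplit:
    def _leaf_disc(self, x, q):
        disc = _disc_with_data([0.0, 1000.0], x, [0] * len(x), x, [0.0] * len(x))
        disc.q = np.asarray(q, dtype=float)
        return disc

    def test_identical_q_yields_no_split(self):
        x = np.linspace(10, 900, 40)
        disc = self._leaf_disc(x, np.full(40, 5.0))
        assert best_split(disc, 0, CutreeConfig()) is None

    def test_maximal_separation_splits_at_group_midpoint(self):
        x = np.concatenate([np.linspace(10, 400, 20), np.linspace(600, 990, 20)])
        q = np.concatenate([np.zeros(20), np.full(20, 100.0)])
        cand = self._split(x, q)
        assert cand is not None
        assert cand.ks_statistic == pytest.approx(1.0)
        assert cand.threshold == pytest.approx(500.0)

    def _split(self, x, q):
        return best_split(self._leaf_disc(x, q), 0, CutreeConfig())

    def test_ks_statistic_and_p_match_independent_oracle(self):
        rng = np.random.default_rng(9)
        x = np.sort(rng.uniform(0, 1000, 60))
        q = np.concatenate([rng.normal(0, 1, 30), rng.normal(1.2, 1, 30)])
        cfg = CutreeConfig(min_leaf_size=30 - 1)  # force the midpoint split
        cand = best_split(self._leaf_disc(x, q), 0, cfg)
        # oracle at the same split position
        m = 30
        D_oracle, p_oracle = _brute_force_ks(q[:m], q[m:])
        scipy_res = stats.ks_2samp(q[:m], q[m:], method="asymp")
        assert abs(scipy_res.statistic - D_oracle) < 1e-6
        assert abs(scipy_res.pvalue - p_oracle) < 1e-3
        if cand is not None:  # the chosen split maximizes D over positions
            assert cand.ks_statistic >= D_oracle - 1e-12

    def test_all_candidate_positions_scanned_match_oracle(self):
        rng = np.random.default_rng(4)
        x = np.sort(rng.uniform(0, 1000, 36))
        q = rng.choice([0.0, 1.0, 5.0], size=36)
        disc = self._leaf_disc(x, q)
        from otterpomdp.cutree import _ks_scan

        M, D = _ks_scan(x, q, min_leaf_size=5)
        for m, d in zip(M, D):
            d_oracle, _ = _brute_force_ks(q[:m], q[m:])
            assert d == pytest.approx(d_oracle, abs=1e-12)

    def test_too_few_datapoints_yield_none(self):
        disc = self._leaf_disc([100.0], [1.0])
        assert best_split(disc, 0, CutreeConfig()) is None


class TestRunCutree:
    def test_constant_reward_keeps_single_state(self):
        params = PopulationParams()
        rp = RewardParams(band_lo=-1.0, band_hi=2000.0)  # reward everywhere
        cfg = CutreeConfig(n_loops=3, gamma=1e-9)
        disc, policy = run_cutree(params, rp, cfg, np.random.default_rng(0))
        assert disc.n_leaves == 1
        assert policy.shape == (1,)

    def test_partition_tiles_axis_and_houses_all_datapoints(self, params, rp):
        cfg = CutreeConfig(n_loops=25)
        disc, _ = run_cutree(params, rp, cfg, np.random.default_rng(2))
        assert disc.edges[0] == 0.0 and disc.edges[-1] == params.pop_max
        assert np.all(np.diff(disc.edges) > 0)
        idx = disc.leaf_index(disc.x)
        assert np.all(disc.x >= disc.edges[idx])
        assert np.all(disc.x < disc.edges[idx + 1])

    def test_expansion_refines_monotonically(self, params, rp):
        # drive the phases manually through the public operations
        cfg = CutreeConfig()
        disc = Discretization(edges=np.array([0.0, params.pop_max]), gamma=cfg.gamma)
        rng = np.random.default_rng(7)
        counts = []
        for _ in range(12):
            traj = simulate_trajectory(
                rng.uniform(0, params.pop_max),
                lambda x: MANAGEMENT_ACTIONS[rng.integers(4)],
                50,
                params,
                rp,
                rng,
            )
            disc.add_datapoints(
                [d.x_t for d in traj],
                [int(d.a_t) for d in traj],
                [d.x_next for d in traj],
                [d.r_t for d in traj],
            )
            estimate_models(disc)
            bellman_solve(disc)
            assign_datapoint_q(disc)
            for lid in reversed(range(disc.n_leaves)):
                cand = best_split(disc, lid, cfg)
                if cand is not None:
                    disc.split_leaf(cand.leaf_id, cand.threshold)
                    estimate_models(disc)
                    bellman_solve(disc)
                    assign_datapoint_q(disc)
            counts.append(disc.n_leaves)
        assert counts == sorted(counts)
        assert counts[-1] > 1  # the reward band is eventually discovered

    def test_splits_locate_the_reward_band_edges(self, params, rp):
        cfg = CutreeConfig(n_loops=60)
        disc, _ = run_cutree(params, rp, cfg, np.random.default_rng(1))
        # some learned edge within 25 otters of each band edge
        for target in (rp.band_lo, rp.band_hi):
            assert np.min(np.abs(disc.edges - target)) < 25.0

    def test_policy_boundary_none_when_pattern_absent(self, band_disc):
        assert policy_boundary(band_disc) == 497.0
        band_disc.Q = band_disc.Q[:, [3, 1, 2, 0]]  # scramble actions
        assert policy_boundary(band_disc) is None


class TestAggregationSoundness:
    def test_greedy_policy_matches_fine_grid_oracle_regions(self):
        """State aggregation preserves the optimal policy: away from the
        action-region boundaries, the CU-Tree policy on a spill-free
        problem agrees with a fine uniform-grid value-iteration oracle."""
        params = PopulationParams(sigma=0.05, f=0.0)
        rp = RewardParams()
        cfg = CutreeConfig(n_loops=120)
        disc, policy = run_cutree(params, rp, cfg, np.random.default_rng(3))

        centers, pol_oracle = _grid_policy_oracle(params, rp, gamma=cfg.gamma)
        # region boundaries of the oracle policy
        switches = centers[1:][np.diff(pol_oracle) != 0]
        cell = centers[1] - centers[0]
        agree = 0
        total = 0
        for i, x in enumerate(centers):
            if any(abs(x - s) <= 25.0 + cell for s in switches):
                continue
            total += 1
            if policy[int(disc.leaf_index(x))] == pol_oracle[i]:
                agree += 1
        assert agree / total > 0.9


def _grid_policy_oracle(params, rp, gamma, n_cells=400, n_eps=31):
    """Value iteration on a fine uniform grid with quadrature transitions."""
    from otterpomdp import reward as reward_fn

    edges = np.linspace(0, params.pop_max, n_cells + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    eps_q, eps_w = np.polynomial.hermite_e.hermegauss(n_eps)
    eps_w = eps_w / eps_w.sum()
    eps_q = eps_q * params.sigma
    T = np.zeros((n_cells, N_ACTIONS, n_cells))
    R = np.zeros((n_cells, N_ACTIONS))
    for ai, a in enumerate(MANAGEMENT_ACTIONS):
        I = params.intro_count if a == Action.INTRODUCE else 0.0
        for i, x in enumerate(centers):
            grown = x * np.exp(params.r * (1 - x / params.K) + eps_q)
            xn = np.clip(grown + I, 0, params.pop_max)
            xn[xn < 1] = 0
            idx = np.clip(np.searchsorted(edges, xn, side="right") - 1, 0, n_cells - 1)
            np.add.at(T[i, ai], idx, eps_w)
            R[i, ai] = reward_fn(x, a, rp)
    V = np.zeros(n_cells)
    for _ in range(3000):
        Q = R + gamma * np.einsum("sat,t->sa", T, V)
        V_new = Q.max(axis=1)
        if np.max(np.abs(V_new - V)) < 1e-10:
            V = V_new
            break
        V = V_new
    Q = R + gamma * np.einsum("sat,t->sa", T, V)
    return centers, Q.argmax(axis=1)
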