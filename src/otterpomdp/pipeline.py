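"""End-to-end pipeline: discretize -> build POMDP -> solve -> evaluate.

Each stage draws from its own random generator seeded deterministically
from the master seed, so every artifact is re-creatable from the
configuration alone.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from typing import Optional

import numpy as np

from .config import RunConfig
from .cutree import Discretization, action_change_boundary, run_cutree
from .evaluate import ComparisonSummary, compare_strategies
from .pomdp import ObservationParams, PomdpModel, assemble_pomdp
from .pomdp_file import write_alpha, write_pomdp
from .solvers import AlphaVectorSet, extract_policy_graph, policy_graph_to_dot, \
    solve_exact_finite, solve_perseus

__all__ = ["stage_rng", "run_pipeline"]

log = logging.getLogger("otterpomdp")

_STAGE_OFFSETS = {"discretize": 1, "solve": 2, "evaluate": 3, "beliefs": 4}


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    """Independent generator for a named pipeline stage."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=master_seed, spawn_key=(_STAGE_OFFSETS[stage],))
    )


def run_pipeline(cfg: RunConfig, out_dir: str) -> dict:
    """Run every stage and write disc.json, model.pomdp, sol.alpha,
    policy.dot and summary CSVs under ``out_dir``.

    Returns the in-memory artifacts (discretization, model, solution,
    policy graph, comparison summary).
    """
    os.makedirs(out_dir, exist_ok=True)
    seed = cfg.seed

    log.info("[discretize seed=%s] running CU-Tree", seed)
    disc, policy = run_cutree(
        cfg.model, cfg.reward, cfg.cutree, stage_rng(seed, "discretize")
    )
    disc.to_json(os.path.join(out_dir, "disc.json"))
    boundary = action_change_boundary(disc)
    log.info("[discretize seed=%s] %d states, boundary=%s", seed, disc.n_leaves, boundary)

    op = cfg.observation
    if op.boundary is None:
        op = dataclasses.replace(op, boundary=boundary)
    model = assemble_pomdp(disc, op, cfg.reward)
    write_pomdp(model, os.path.join(out_dir, "model.pomdp"))

    log.info("[solve seed=%s] method=%s", seed, cfg.solver.method)
    if cfg.solver.method == "exact":
        stages = solve_exact_finite(model, cfg.solver.horizon)
        sol = stages[-1]
    else:
        sol = solve_perseus(
            model,
            n_beliefs=cfg.solver.n_beliefs,
            rng=stage_rng(seed, "solve"),
            epsilon=cfg.solver.epsilon,
            max_iter=cfg.solver.max_iter,
        )
    write_alpha(sol, os.path.join(out_dir, "sol.alpha"))

    graph = extract_policy_graph(sol, model)
    with open(os.path.join(out_dir, "policy.dot"), "w") as fh:
        fh.write(policy_graph_to_dot(graph) + "\n")

    log.info("[evaluate seed=%s] comparing strategies", seed)
    scenarios: dict[str, tuple[PomdpModel, AlphaVectorSet]] = {}
    rp_by_scenario = {}
    for cost in cfg.evaluation.monitor_costs:
        rp_c = dataclasses.replace(cfg.reward, monitor_cost=cost)
        m_c = assemble_pomdp(disc, op, rp_c)
        sol_c = solve_perseus(
            m_c,
            n_beliefs=cfg.solver.n_beliefs,
            rng=stage_rng(seed, "solve"),
            epsilon=cfg.solver.epsilon,
            max_iter=cfg.solver.max_iter,
        )
        name = f"monitor_cost_{cost:g}"
        scenarios[name] = (m_c, sol_c)
        rp_by_scenario[name] = rp_c
    summary = compare_strategies(
        scenarios,
        disc,
        policy,
        op,
        cfg.model,
        rp_by_scenario,
        stage_rng(seed, "evaluate"),
        n_runs=cfg.evaluation.n_runs,
        horizon=cfg.evaluation.horizon,
        finite_horizon=cfg.evaluation.finite_horizon,
        long_window=cfg.evaluation.long_window,
        x0=cfg.evaluation.x0,
    )
    summary.to_csv(os.path.join(out_dir, "summary"))
    summary.plot(os.path.join(out_dir, "performance.png"))
    return {
        "disc": disc,
        "policy": policy,
        "boundary": boundary,
        "model": model,
        "solution": sol,
        "graph": graph,
        "summary": summary,
    }
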