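"""Run configuration: one YAML/JSON document driving the whole pipeline.

Unknown keys are rejected so that typos in overrides of the redacted
biological parameters fail loudly rather than silently using defaults.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Any

import yaml

from .cutree import CutreeConfig
from .pomdp import ObservationParams
from .population import PopulationParams, RewardParams

__all__ = ["SolverConfig", "EvaluationConfig", "RunConfig", "load_config", "save_config"]


@dataclass
class SolverConfig:
    method: str = "perseus"  # or "exact"
    horizon: int = 6
    n_beliefs: int = 1000
    epsilon: float = 1e-4
    max_iter: int = 500

    def __post_init__(self) -> None:
        if self.method not in ("perseus", "exact"):
            raise ValueError("solver method must be 'perseus' or 'exact'")


@dataclass
class EvaluationConfig:
    n_runs: int = 20
    horizon: int = 40
    finite_horizon: int = 6
    long_window: tuple[int, int] = (20, 40)
    monitor_costs: tuple[float, ...] = (1.0, 2.0, 10.0)
    x0: float | None = 50.0

    def __post_init__(self) -> None:
        self.long_window = tuple(self.long_window)
        self.monitor_costs = tuple(self.monitor_costs)


@dataclass
class RunConfig:
    model: PopulationParams = field(default_factory=PopulationParams)
    reward: RewardParams = field(default_factory=RewardParams)
    cutree: CutreeConfig = field(default_factory=CutreeConfig)
    observation: ObservationParams = field(default_factory=ObservationParams)
    solver: SolverConfig = field(default_factory=SolverConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if not isinstance(self.seed, int) or self.seed < 0:
            raise ValueError("seed must be a non-negative integer")


_BLOCKS = {
    "model": PopulationParams,
    "reward": RewardParams,
    "cutree": CutreeConfig,
    "observation": ObservationParams,
    "solver": SolverConfig,
    "evaluation": EvaluationConfig,
}


def _build(cls, data: dict[str, Any], where: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown keys in '{where}' block: {sorted(unknown)}")
    return cls(**data)


def config_from_dict(payload: dict[str, Any]) -> RunConfig:
    unknown = set(payload) - set(_BLOCKS) - {"seed"}
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for name, cls in _BLOCKS.items():
        if name in payload:
            kwargs[name] = _build(cls, dict(payload[name] or {}), name)
    if "seed" in payload:
        kwargs["seed"] = payload["seed"]
    return RunConfig(**kwargs)


def config_to_dict(cfg: RunConfig) -> dict[str, Any]:
    out: dict[str, Any] = {}
    for name in _BLOCKS:
        block = dataclasses.asdict(getattr(cfg, name))
        out[name] = {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in block.items()
        }
    out["seed"] = cfg.seed
    return out


def load_config(path: str) -> RunConfig:
    with open(path) as fh:
        if path.endswith(".json"):
            payload = json.load(fh)
        else:
            payload = yaml.safe_load(fh)
    return config_from_dict(payload or {})


def save_config(cfg: RunConfig, path: str) -> None:
    payload = config_to_dict(cfg)
    with open(path, "w") as fh:
        if path.endswith(".json"):
            json.dump(payload, fh, indent=1)
        else:
            yaml.safe_dump(payload, fh, sort_keys=False)
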