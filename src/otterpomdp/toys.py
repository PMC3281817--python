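"""Small hand-parameterized POMDPs with known structure, for solver checks."""

from __future__ import annotations

import numpy as np

from .pomdp import PomdpModel

__all__ = ["make_toy_pomdp"]


def make_toy_pomdp(kind: str, gamma: float = 0.95) -> PomdpModel:
    """Build a named toy model.

    * ``two_state_perfect`` — 2 states/actions/observations, identity
      observations: reduces to an MDP.
    * ``two_state_noisy`` — same dynamics but O = 0.5 everywhere, so
      observations carry no information.
    * ``three_state_window`` — a low/middle/high chain where only the
      middle state is ambiguously observed unless a third (monitoring)
      action is taken; mimics the detection-window structure.
    """
    if kind == "two_state_perfect":
        T = np.array([
            [[0.9, 0.1], [0.2, 0.8]],  # action 0: stay-biased
            [[0.5, 0.5], [0.5, 0.5]],  # action 1: shuffle
        ])
        R = np.array([[10.0, 0.0], [0.0, 5.0]])  # R[s, a]
        O = np.zeros((2, 2, 2))
        O[:, 0, 0] = 1.0
        O[:, 1, 1] = 1.0
        return PomdpModel(
            state_intervals=[(0.0, 1.0), (1.0, 2.0)],
            T=T, R=R, O=O, gamma=gamma, b0=np.array([0.5, 0.5]),
            actions=(0, 1), observations=("o0", "o1"),
            state_names=["low", "high"],
        )
    if kind == "two_state_noisy":
        T = np.array([
            [[0.9, 0.1], [0.2, 0.8]],
            [[0.5, 0.5], [0.5, 0.5]],
        ])
        R = np.array([[10.0, 0.0], [0.0, 5.0]])
        O = np.full((2, 2, 2), 0.5)
        return PomdpModel(
            state_intervals=[(0.0, 1.0), (1.0, 2.0)],
            T=T, R=R, O=O, gamma=gamma, b0=np.array([0.5, 0.5]),
            actions=(0, 1), observations=("o0", "o1"),
            state_names=["low", "high"],
        )
    if kind == "three_state_window":
        # actions: 0 = manage-down, 1 = manage-up, 2 = monitor (no dynamics)
        T = np.array([
            [[1.0, 0.0, 0.0], [0.7, 0.3, 0.0], [0.0, 0.7, 0.3]],
            [[0.3, 0.7, 0.0], [0.0, 0.3, 0.7], [0.0, 0.0, 1.0]],
            [[0.8, 0.2, 0.0], [0.1, 0.8, 0.1], [0.0, 0.2, 0.8]],
        ])
        R = np.array([[0.0, 0.0, -1.0], [10.0, 10.0, 9.0], [0.0, 0.0, -1.0]])
        O = np.zeros((3, 3, 2))
        for a in range(3):
            O[a, 0] = [1.0, 0.0]
            O[a, 2] = [0.0, 1.0]
            p = 0.95 if a == 2 else 0.5
            O[a, 1] = [p, 1.0 - p]
        return PomdpModel(
            state_intervals=[(0.0, 1.0), (1.0, 2.0), (2.0, 3.0)],
            T=T, R=R, O=O, gamma=gamma, b0=np.full(3, 1.0 / 3),
            actions=(0, 1, 2), observations=("small", "large"),
            state_names=["low", "mid", "high"],
        )
    raise ValueError(f"unknown toy kind '{kind}'")
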