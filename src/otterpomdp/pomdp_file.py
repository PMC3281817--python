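"""Read and write POMDPs in the Cassandra ``.pomdp`` text format.

The format is the interchange surface of the classic ``pomdp-solve``
family: a preamble (``discount:``, ``values:``, ``states:``, ``actions:``,
``observations:``) followed by ``T:``, ``O:`` and ``R:`` entries, either as
single probabilities or as row/matrix blocks (``uniform`` and ``identity``
keywords supported for matrices).  Alpha-vector solutions use the
companion ``.alpha`` format: an action line followed by a coefficient
line, blank-line separated.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .pomdp import PomdpModel
from .population import Action

__all__ = ["write_pomdp", "read_pomdp", "write_alpha", "read_alpha", "PomdpParseError"]


class PomdpParseError(ValueError):
    def __init__(self, message: str, line_no: Optional[int] = None):
        prefix = f"line {line_no}: " if line_no is not None else ""
        super().__init__(prefix + message)
        self.line_no = line_no


def write_pomdp(model: PomdpModel, path: str) -> None:
    """Serialize a model; ``read_pomdp`` round-trips it to 1e-12."""
    S, A, Z = model.n_states, model.n_actions, model.n_observations
    action_names = [Action(a).name.lower() for a in range(A)] if A == len(Action) else [
        f"a{a}" for a in range(A)
    ]
    lines = [
        f"discount: {model.gamma:.17g}",
        "values: reward",
        "states: " + " ".join(model.state_names),
        "actions: " + " ".join(action_names),
        "observations: " + " ".join(model.observations),
        "",
        "start: " + " ".join(f"{p:.17g}" for p in model.b0),
        "",
    ]
    for a in range(A):
        lines.append(f"T: {action_names[a]}")
        for s in range(S):
            lines.append(" ".join(f"{p:.17g}" for p in model.T[a, s]))
        lines.append("")
    for a in range(A):
        lines.append(f"O: {action_names[a]}")
        for s in range(S):
            lines.append(" ".join(f"{p:.17g}" for p in model.O[a, s]))
        lines.append("")
    for a in range(A):
        for s in range(S):
            lines.append(f"R: {action_names[a]} : {model.state_names[s]} : * : * {model.R[s, a]:.17g}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _name_or_index(token: str, names: list[str], what: str, line_no: int) -> list[int]:
    if token == "*":
        return list(range(len(names)))
    if token in names:
        return [names.index(token)]
    try:
        idx = int(token)
    except ValueError:
        raise PomdpParseError(f"unknown {what} '{token}'", line_no)
    if not 0 <= idx < len(names):
        raise PomdpParseError(f"{what} index {idx} out of range", line_no)
    return [idx]


def read_pomdp(path: str) -> PomdpModel:
    """Parse a Cassandra-format POMDP file into a :class:`PomdpModel`."""
    with open(path) as fh:
        raw = fh.readlines()

    gamma = None
    states: list[str] = []
    actions: list[str] = []
    observations: list[str] = []
    b0 = None
    T = O = R = None

    def n_list(tokens_field: str, prefix: str, line_no: int) -> list[str]:
        toks = tokens_field.split()
        if len(toks) == 1 and toks[0].isdigit():
            return [f"{prefix}{i}" for i in range(int(toks[0]))]
        return toks

    def ensure_tensors(line_no: int):
        nonlocal T, O, R, b0
        if T is None:
            if not (states and actions and observations):
                raise PomdpParseError(
                    "states, actions and observations must precede T/O/R blocks",
                    line_no,
                )
            S, A, Z = len(states), len(actions), len(observations)
            T = np.zeros((A, S, S))
            O = np.zeros((A, S, Z))
            R = np.zeros((S, A))
            if b0 is None:
                b0 = np.full(S, 1.0 / S)

    def parse_matrix_block(i: int, rows: int, cols: int) -> tuple[np.ndarray, int]:
        """Matrix starting at line i: 'uniform', 'identity', or rows of numbers."""
        j = i
        while j < len(raw) and not raw[j].strip():
            j += 1
        if j >= len(raw):
            raise PomdpParseError("unexpected end of file in matrix block", j)
        tok = raw[j].strip()
        if tok == "uniform":
            return np.full((rows, cols), 1.0 / cols), j + 1
        if tok == "identity":
            if rows != cols:
                raise PomdpParseError("identity matrix must be square", j + 1)
            return np.eye(rows), j + 1
        mat = np.zeros((rows, cols))
        for k in range(rows):
            if j + k >= len(raw):
                raise PomdpParseError("matrix block truncated", j + k)
            vals = raw[j + k].split()
            if len(vals) != cols:
                raise PomdpParseError(
                    f"expected {cols} values, got {len(vals)}", j + k + 1
                )
            try:
                mat[k] = [float(v) for v in vals]
            except ValueError:
                raise PomdpParseError("non-numeric matrix entry", j + k + 1)
        return mat, j + rows

    i = 0
    while i < len(raw):
        line_no = i + 1
        line = raw[i].split("#", 1)[0].strip()
        if not line:
            i += 1
            continue
        if line.startswith("discount:"):
            gamma = float(line.split(":", 1)[1])
            i += 1
        elif line.startswith("values:"):
            i += 1
        elif line.startswith("states:"):
            states = n_list(line.split(":", 1)[1], "s", line_no)
            i += 1
        elif line.startswith("actions:"):
            actions = n_list(line.split(":", 1)[1], "a", line_no)
            i += 1
        elif line.startswith("observations:"):
            observations = n_list(line.split(":", 1)[1], "o", line_no)
            i += 1
        elif line.startswith("start:"):
            ensure_tensors(line_no)
            vals = line.split(":", 1)[1].split()
            if len(vals) != len(states):
                raise PomdpParseError("start belief has wrong length", line_no)
            b0 = np.array([float(v) for v in vals])
            i += 1
        elif line.startswith("T:"):
            ensure_tensors(line_no)
            parts = [p.strip() for p in line[2:].split(":")]
            a_idx = _name_or_index(parts[0], actions, "action", line_no)
            if len(parts) == 1:  # T: a  + matrix block
                mat, nxt = parse_matrix_block(i + 1, len(states), len(states))
                for a in a_idx:
                    T[a] = mat
                i = nxt
            elif len(parts) == 2:  # T: a : s  + row
                s_idx = _name_or_index(parts[1], states, "state", line_no)
                row, nxt = parse_matrix_block(i + 1, 1, len(states))
                for a in a_idx:
                    for s in s_idx:
                        T[a, s] = row[0]
                i = nxt
            elif len(parts) == 3:
                tail = parts[2].split()
                s_idx = _name_or_index(parts[1], states, "state", line_no)
                if len(tail) == 2:  # T: a : s : s' p
                    sp_idx = _name_or_index(tail[0], states, "state", line_no)
                    p = float(tail[1])
                    for a in a_idx:
                        for s in s_idx:
                            for sp in sp_idx:
                                T[a, s, sp] = p
                    i += 1
                else:
                    raise PomdpParseError("malformed T entry", line_no)
            else:
                raise PomdpParseError("malformed T entry", line_no)
        elif line.startswith("O:"):
            ensure_tensors(line_no)
            parts = [p.strip() for p in line[2:].split(":")]
            a_idx = _name_or_index(parts[0], actions, "action", line_no)
            if len(parts) == 1:
                mat, nxt = parse_matrix_block(i + 1, len(states), len(observations))
                for a in a_idx:
                    O[a] = mat
                i = nxt
            elif len(parts) == 2:
                s_idx = _name_or_index(parts[1], states, "state", line_no)
                row, nxt = parse_matrix_block(i + 1, 1, len(observations))
                for a in a_idx:
                    for s in s_idx:
                        O[a, s] = row[0]
                i = nxt
            elif len(parts) == 3:
                tail = parts[2].split()
                s_idx = _name_or_index(parts[1], states, "state", line_no)
                if len(tail) == 2:
                    o_idx = _name_or_index(tail[0], observations, "observation", line_no)
                    p = float(tail[1])
                    for a in a_idx:
                        for s in s_idx:
                            for o in o_idx:
                                O[a, s, o] = p
                    i += 1
                else:
                    raise PomdpParseError("malformed O entry", line_no)
            else:
                raise PomdpParseError("malformed O entry", line_no)
        elif line.startswith("R:"):
            ensure_tensors(line_no)
            parts = [p.strip() for p in line[2:].split(":")]
            # supported: R: a : s : * : * value   (state-action rewards)
            if len(parts) != 4:
                raise PomdpParseError(
                    "only 'R: a : s : * : * value' reward entries are supported",
                    line_no,
                )
            a_idx = _name_or_index(parts[0], actions, "action", line_no)
            s_idx = _name_or_index(parts[1], states, "state", line_no)
            tail = parts[3].split()
            if len(tail) != 2 or tail[0] != "*" or parts[2] != "*":
                raise PomdpParseError(
                    "only 'R: a : s : * : * value' reward entries are supported",
                    line_no,
                )
            val = float(tail[1])
            for a in a_idx:
                for s in s_idx:
                    R[s, a] = val
            i += 1
        else:
            raise PomdpParseError(f"unrecognized directive '{line}'", line_no)

    if gamma is None:
        raise PomdpParseError("missing discount")
    if T is None:
        raise PomdpParseError("file defines no T/O/R blocks")
    return PomdpModel(
        state_intervals=[(float(k), float(k) + 1.0) for k in range(len(states))],
        T=T,
        R=R,
        O=O,
        gamma=gamma,
        b0=b0,
        observations=tuple(observations),
        state_names=list(states),
    )


def write_alpha(vectors, path: str) -> None:
    """Write an alpha-vector set in the pomdp-solve ``.alpha`` format."""
    blocks = []
    for v in vectors:
        blocks.append(
            f"{int(v.action)}\n" + " ".join(f"{c:.17g}" for c in v.coefficients)
        )
    with open(path, "w") as fh:
        fh.write("\n\n".join(blocks) + "\n")


def read_alpha(path: str):
    """Read a ``.alpha`` file; returns a list of (action, coefficients)."""
    with open(path) as fh:
        chunks = [c for c in fh.read().strip().split("\n\n") if c.strip()]
    out = []
    for c in chunks:
        rows = c.strip().splitlines()
        if len(rows) != 2:
            raise PomdpParseError("each alpha block needs an action and a row")
        out.append((int(rows[0]), np.array([float(t) for t in rows[1].split()])))
    return out
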