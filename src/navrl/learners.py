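"""The five valuation models and the softmax choice rule.

Model-free family (temporal-difference learning on state-action values):

* ``TD0`` — the prediction error delta = r + Q(s', a') - Q(s, a) updates only
  the just-taken pair: Q(s, a) += alpha * delta (on-policy / SARSA target,
  undiscounted; the bootstrap term is 0 when s' is the goal).
* ``TDLAMBDA`` — an eligibility trace e(s, a) spreads delta backwards along
  the visited path: per step every trace entry decays by lambda, the current
  pair gains +1, and every pair receives Q += alpha * delta * e.
* ``TD1`` — no forgetting: once visited, a pair's trace is set to 1 and held
  there for the rest of the trial, so every visited pair receives the same
  update regardless of visitation frequency. (A literal lambda=1 accumulating
  trace is available behind ``td1_accumulating``.)

Model-based (``MB``): values come from a value-iteration sweep over the room
graph with discount gamma = 0.8, terminating at the goal; they equal
reward * gamma**d(s') where d is the shortest-path distance of the landing
room from the goal. The table is precomputed, identical for all navigators,
and never updated.

Hybrid: effective values (1 - omega) * Q_MF + omega * Q_MB fed to the
softmax; the TD component is TD(lambda), so the model has four free
parameters (alpha, theta, lambda, omega).

Choices are softmax over the available actions with inverse temperature
theta: p(a) ∝ exp(theta * Q(s, a)).
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Optional

import numpy as np

from .gridworld import (
    N_ACTIONS,
    Action,
    GridSpec,
    RoomState,
    StepRecord,
    TaskConfig,
    distance_map,
)

__all__ = [
    "ModelKind",
    "ModelParams",
    "MBValues",
    "PARAM_BOUNDS",
    "softmax_probs",
    "zeros_q",
    "zeros_trace",
    "td_update",
    "compute_mb_values",
    "hybrid_q",
]


class ModelKind(str, Enum):
    TD0 = "td0"
    TD1 = "td1"
    TDLAMBDA = "tdlambda"
    MB = "mb"
    HYBRID = "hybrid"

    @classmethod
    def coerce(cls, value) -> "ModelKind":
        if isinstance(value, cls):
            return value
        return cls(str(value).lower())


# bounds of the free parameters
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "alpha": (0.0, 1.0),
    "theta": (1.0, 15.0),
    "lam": (0.0, 1.0),
    "omega": (0.0, 1.0),
}

# free parameters per model, in optimizer order
FREE_PARAMS: dict[ModelKind, tuple[str, ...]] = {
    ModelKind.TD0: ("alpha", "theta"),
    ModelKind.TD1: ("alpha", "theta"),
    ModelKind.TDLAMBDA: ("alpha", "theta", "lam"),
    ModelKind.MB: ("theta",),
    ModelKind.HYBRID: ("alpha", "theta", "lam", "omega"),
}


@dataclass(frozen=True)
class ModelParams:
    """A model kind plus its bounded parameters.

    Parameters irrelevant to ``model_kind`` are carried but ignored by every
    operation (e.g. ``lam`` for TD0).
    """

    model_kind: ModelKind
    alpha: float = 0.5
    theta: float = 5.0
    lam: float = 0.0
    omega: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "model_kind", ModelKind.coerce(self.model_kind))
        for name in FREE_PARAMS[self.model_kind]:
            lo, hi = PARAM_BOUNDS[name]
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside bounds [{lo}, {hi}]")

    @property
    def k(self) -> int:
        """Free-parameter count: 2 (TD0/TD1), 3 (TD(lambda)), 1 (MB), 4 (hybrid)."""
        return len(FREE_PARAMS[self.model_kind])

    @property
    def free_names(self) -> tuple[str, ...]:
        return FREE_PARAMS[self.model_kind]

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self.free_names], dtype=float)

    @classmethod
    def from_vector(cls, model_kind: ModelKind, x: np.ndarray) -> "ModelParams":
        model_kind = ModelKind.coerce(model_kind)
        names = FREE_PARAMS[model_kind]
        if len(x) != len(names):
            raise ValueError(f"{model_kind.value} expects {len(names)} parameters, got {len(x)}")
        return cls(model_kind, **dict(zip(names, map(float, x))))

    def bounds(self) -> list[tuple[float, float]]:
        return [PARAM_BOUNDS[n] for n in self.free_names]


def softmax_probs(q_row: Mapping[Action, float], theta: float) -> dict[Action, float]:
    """Softmax choice probabilities over the available actions.

    Max-shifted for numerical stability; the result is invariant to adding a
    constant to every value.
    """
    if not q_row:
        raise ValueError("empty action set (every room has at least two doors)")
    actions = list(q_row.keys())
    x = theta * np.asarray([q_row[a] for a in actions], dtype=float)
    x -= x.max()
    ex = np.exp(x)
    p = ex / ex.sum()
    return {a: float(pi) for a, pi in zip(actions, p)}


def zeros_q(task: TaskConfig) -> np.ndarray:
    """Fresh model-free table: one zero-initialized (state, action) map per goal."""
    return np.zeros((task.n_goals, task.grid.n_states, N_ACTIONS), dtype=float)


def zeros_trace(grid: GridSpec) -> np.ndarray:
    """Eligibility trace, reset to zero at the start of every trial."""
    return np.zeros((grid.n_states, N_ACTIONS), dtype=float)


TERMINAL = None  # sentinel for "next state is the goal": bootstrap term is 0


def td_update(
    params: ModelParams,
    q: np.ndarray,
    trace: np.ndarray,
    goal_index: int,
    step: StepRecord,
    next_action: Optional[Action],
    grid: GridSpec,
    td1_accumulating: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one TD update in place; returns (q, trace).

    ``next_action`` is the action actually taken from ``step.next_state``, or
    ``TERMINAL`` (None) when the next state is the goal, in which case the
    bootstrap term is 0. delta = r + Q(s', a') - Q(s, a).
    """
    kind = params.model_kind
    if kind == ModelKind.MB:
        return q, trace  # model-based values are frozen
    s = grid.index(step.state)
    a = int(step.action)
    if next_action is TERMINAL:
        if step.reward <= 0:
            raise ValueError("TERMINAL update with zero reward: trial does not end at goal")
        boot = 0.0
    else:
        boot = q[goal_index, grid.index(step.next_state), int(next_action)]
    delta = step.reward + boot - q[goal_index, s, a]
    if kind == ModelKind.TD0:
        q[goal_index, s, a] += params.alpha * delta
    elif kind in (ModelKind.TDLAMBDA, ModelKind.HYBRID):
        trace *= params.lam
        trace[s, a] += 1.0
        q[goal_index] += params.alpha * delta * trace
    elif kind == ModelKind.TD1:
        if td1_accumulating:
            trace[s, a] += 1.0
        else:
            trace[s, a] = 1.0
        q[goal_index] += params.alpha * delta * trace
    else:  # pragma: no cover
        raise ValueError(f"unknown model kind {kind}")
    return q, trace


@dataclass(frozen=True)
class MBValues:
    """Precomputed model-based (cognitive-map) values.

    ``values[g, s, a]`` is the worth of taking action ``a`` from room ``s``
    when seeking goal ``g``; entries for illegal actions are 0 and never read.
    Identical for every navigator and stationary.
    """

    values: np.ndarray  # (n_goals, n_states, 4)
    gamma: float = 0.8
    tol: float = 1e-4

    def as_frame(self, task: TaskConfig):
        """Long-format table (goal_id, row, col, action, value) for inspection."""
        import pandas as pd

        rows = []
        for g, (gid, _) in enumerate(task.goals):
            for s in task.grid.states():
                si = task.grid.index(s)
                from .gridworld import available_actions

                for a in available_actions(task.grid, s):
                    rows.append(
                        {
                            "goal_id": gid,
                            "row": s.row,
                            "col": s.col,
                            "action": a.name.lower(),
                            "value": self.values[g, si, int(a)],
                        }
                    )
        return pd.DataFrame(rows)


def compute_mb_values(
    task: TaskConfig, gamma: float = 0.8, tol: float = 1e-4
) -> MBValues:
    """Value-iteration sweep terminating at each goal.

    Iterates Q(s, a) <- r(s, a) + gamma * V(s') with V(goal) = 0 (terminal)
    and V(s) = max_a Q(s, a) until the largest absolute change falls below
    ``tol``. On this deterministic grid the converged value of an action
    landing in room s' at distance d from the goal is
    reward_magnitude * gamma**d (goal itself: d = 0).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if not 0.0 <= gamma < 1.0:
        raise ValueError("gamma must be in [0, 1)")
    grid = task.grid
    nxt, legal = grid.transition_arrays()
    values = np.zeros((task.n_goals, grid.n_states, N_ACTIONS), dtype=float)
    for g, (_, goal_room) in enumerate(task.goals):
        gi = grid.index(goal_room)
        q = np.zeros((grid.n_states, N_ACTIONS), dtype=float)
        while True:
            v = np.where(legal.any(axis=1), np.max(np.where(legal > 0, q, -np.inf), axis=1), 0.0)
            v[gi] = 0.0  # terminal: the episode ends on entering the goal
            landing = np.where(legal > 0, nxt, 0)
            r = np.where(landing == gi, task.reward_magnitude, 0.0)
            q_new = np.where(legal > 0, r + gamma * v[landing], 0.0)
            if np.max(np.abs(q_new - q)) < tol:
                q = q_new
                break
            q = q_new
        values[g] = q
    return MBValues(values=values, gamma=gamma, tol=tol)


def hybrid_q(q_mf: np.ndarray, q_mb: np.ndarray, omega: float) -> np.ndarray:
    """Entrywise mix (1 - omega) * Q_MF + omega * Q_MB."""
    if not 0.0 <= omega <= 1.0:
        raise ValueError("omega must be in [0, 1]")
    q_mf = np.asarray(q_mf, dtype=float)
    q_mb = np.asarray(q_mb, dtype=float)
    if q_mf.shape != q_mb.shape:
        raise ValueError(f"table shape mismatch: {q_mf.shape} vs {q_mb.shape}")
    return (1.0 - omega) * q_mf + omega * q_mb
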