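"""Room-grid navigation task: rooms, legal moves, goals, phase protocols.

The environment is an ``n_rows x n_cols`` grid of rooms. From each room the
navigator can move through a door to the adjacent room in one of four
directions; rooms on the boundary lack the corresponding doors. The state
space is the set of rooms (orientation within a room is not modelled), and
transitions are deterministic.

A study session consists of a *Fixed* phase (repeated trials from one start
room, goals visited in a fixed cyclic order) followed by a *Random* phase
(uniformly random non-goal start rooms, goal order block-randomized so each
goal occurs once per consecutive block of three trials).

Coordinate convention: rooms are (row, col), 0-based, row 0 at the top;
"up" decreases the row index, "left" decreases the column index.
"""
from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, NamedTuple, Sequence

import numpy as np

__all__ = [
    "Action",
    "RoomState",
    "GridSpec",
    "TaskConfig",
    "StepRecord",
    "Trial",
    "ParticipantData",
    "available_actions",
    "step",
    "shortest_path_rooms",
    "default_task",
]


class Action(IntEnum):
    """The four door directions; values index the kernel arrays."""

    UP = 0
    DOWN = 1
    LEFT = 2
    RIGHT = 3

    @property
    def delta(self) -> tuple[int, int]:
        return _DELTAS[self]

    @property
    def opposite(self) -> "Action":
        return _OPPOSITE[self]

    @classmethod
    def from_name(cls, name: str) -> "Action":
        try:
            return cls[name.strip().upper()]
        except KeyError:
            raise ValueError(f"unknown action name: {name!r}") from None


_DELTAS: dict[Action, tuple[int, int]] = {
    Action.UP: (-1, 0),
    Action.DOWN: (1, 0),
    Action.LEFT: (0, -1),
    Action.RIGHT: (0, 1),
}
_OPPOSITE: dict[Action, Action] = {
    Action.UP: Action.DOWN,
    Action.DOWN: Action.UP,
    Action.LEFT: Action.RIGHT,
    Action.RIGHT: Action.LEFT,
}

N_ACTIONS = 4


class RoomState(NamedTuple):
    """A room, addressed by 0-based (row, col)."""

    row: int
    col: int


@dataclass(frozen=True)
class GridSpec:
    """Dimensions of the room grid (default: the 6x6 = 36-room layout)."""

    n_rows: int = 6
    n_cols: int = 6

    def __post_init__(self) -> None:
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValueError("grid must be at least 2x2")

    @property
    def n_states(self) -> int:
        return self.n_rows * self.n_cols

    def contains(self, state: RoomState) -> bool:
        return 0 <= state.row < self.n_rows and 0 <= state.col < self.n_cols

    def require(self, state: RoomState) -> None:
        if not self.contains(state):
            raise ValueError(f"room {tuple(state)} outside {self.n_rows}x{self.n_cols} grid")

    def index(self, state: RoomState) -> int:
        """Flat state index used by the numerical kernels."""
        self.require(state)
        return state.row * self.n_cols + state.col

    def state(self, index: int) -> RoomState:
        if not 0 <= index < self.n_states:
            raise ValueError(f"state index {index} out of range")
        return RoomState(index // self.n_cols, index % self.n_cols)

    def states(self) -> Iterable[RoomState]:
        for r in range(self.n_rows):
            for c in range(self.n_cols):
                yield RoomState(r, c)

    def transition_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(next_state, legal) arrays of shape (n_states, 4).

        ``next_state[s, a]`` is the flat index of the room reached by taking
        action ``a`` from room ``s`` (or -1 at a boundary wall); ``legal`` is
        the corresponding 0/1 mask.
        """
        nxt = np.full((self.n_states, N_ACTIONS), -1, dtype=np.int64)
        legal = np.zeros((self.n_states, N_ACTIONS), dtype=np.uint8)
        for s in self.states():
            si = self.index(s)
            for a in Action:
                dr, dc = a.delta
                t = RoomState(s.row + dr, s.col + dc)
                if self.contains(t):
                    nxt[si, a] = self.index(t)
                    legal[si, a] = 1
        return nxt, legal


def available_actions(grid: GridSpec, state: RoomState) -> set[Action]:
    """Directions with a door from ``state``: 2 (corner), 3 (edge) or 4 (interior)."""
    grid.require(state)
    out = set()
    for a in Action:
        dr, dc = a.delta
        if grid.contains(RoomState(state.row + dr, state.col + dc)):
            out.add(a)
    return out


def step(grid: GridSpec, state: RoomState, action: Action) -> RoomState:
    """Deterministic transition: the adjacent room through the chosen door."""
    grid.require(state)
    dr, dc = action.delta
    target = RoomState(state.row + dr, state.col + dc)
    if not grid.contains(target):
        raise ValueError(f"illegal action {action.name} from room {tuple(state)} (boundary wall)")
    return target


def shortest_path_rooms(grid: GridSpec, origin: RoomState, target: RoomState) -> int:
    """Minimal number of room transitions between two rooms (BFS on the room graph).

    On the open grid this equals the Manhattan distance, but the BFS keeps the
    definition tied to the actual door graph.
    """
    grid.require(origin)
    grid.require(target)
    if origin == target:
        return 0
    seen = {origin}
    frontier: deque[tuple[RoomState, int]] = deque([(origin, 0)])
    while frontier:
        room, d = frontier.popleft()
        for a in available_actions(grid, room):
            nxt = step(grid, room, a)
            if nxt == target:
                return d + 1
            if nxt not in seen:
                seen.add(nxt)
                frontier.append((nxt, d + 1))
    raise RuntimeError("grid graph is connected; unreachable")  # pragma: no cover


def distance_map(grid: GridSpec, target: RoomState) -> np.ndarray:
    """BFS distance from every room to ``target``, as a flat (n_states,) array."""
    grid.require(target)
    nxt, legal = grid.transition_arrays()
    dist = np.full(grid.n_states, -1, dtype=np.int64)
    ti = grid.index(target)
    dist[ti] = 0
    frontier = deque([ti])
    while frontier:
        s = frontier.popleft()
        for a in range(N_ACTIONS):
            if legal[s, a]:
                t = nxt[s, a]
                if dist[t] < 0:
                    dist[t] = dist[s] + 1
                    frontier.append(t)
    return dist


@dataclass(frozen=True)
class TaskConfig:
    """Full task geometry and protocol lengths.

    goals: ordered (goal_id, room) pairs — the three hidden goal objects.
    Only the current trial's goal yields reward; the other goal rooms are
    ordinary rooms during that trial.
    """

    grid: GridSpec
    goals: tuple[tuple[str, RoomState], ...]
    fixed_start: RoomState
    n_fixed_trials: int = 9
    n_random_trials: int = 72
    reward_magnitude: float = 1.0

    def __post_init__(self) -> None:
        rooms = [g[1] for g in self.goals]
        ids = [g[0] for g in self.goals]
        if len(set(ids)) != len(ids):
            raise ValueError("goal ids must be distinct")
        if len(set(rooms)) != len(rooms):
            raise ValueError("goal rooms must be pairwise distinct")
        for room in rooms:
            self.grid.require(room)
        self.grid.require(self.fixed_start)
        if self.fixed_start in rooms:
            raise ValueError("fixed start must not be a goal room")
        if self.n_fixed_trials % len(self.goals) != 0:
            raise ValueError("n_fixed_trials must be divisible by the number of goals")
        if self.n_random_trials % len(self.goals) != 0:
            raise ValueError("n_random_trials must be divisible by the number of goals")
        if self.reward_magnitude < 0:
            raise ValueError("reward_magnitude must be nonnegative")

    @property
    def goal_ids(self) -> tuple[str, ...]:
        return tuple(g[0] for g in self.goals)

    @property
    def n_goals(self) -> int:
        return len(self.goals)

    def goal_room(self, goal_id: str) -> RoomState:
        for gid, room in self.goals:
            if gid == goal_id:
                return room
        raise KeyError(f"unknown goal id: {goal_id!r}")

    def goal_index(self, goal_id: str) -> int:
        for i, (gid, _) in enumerate(self.goals):
            if gid == goal_id:
                return i
        raise KeyError(f"unknown goal id: {goal_id!r}")

    def to_dict(self) -> dict:
        return {
            "grid": {"n_rows": self.grid.n_rows, "n_cols": self.grid.n_cols},
            "goals": [{"id": gid, "row": r.row, "col": r.col} for gid, r in self.goals],
            "fixed_start": {"row": self.fixed_start.row, "col": self.fixed_start.col},
            "n_fixed_trials": self.n_fixed_trials,
            "n_random_trials": self.n_random_trials,
            "reward_magnitude": self.reward_magnitude,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TaskConfig":
        grid = GridSpec(d["grid"]["n_rows"], d["grid"]["n_cols"])
        goals = tuple(
            (g["id"], RoomState(g["row"], g["col"])) for g in d["goals"]
        )
        return cls(
            grid=grid,
            goals=goals,
            fixed_start=RoomState(d["fixed_start"]["row"], d["fixed_start"]["col"]),
            n_fixed_trials=int(d["n_fixed_trials"]),
            n_random_trials=int(d["n_random_trials"]),
            reward_magnitude=float(d.get("reward_magnitude", 1.0)),
        )


def default_task() -> TaskConfig:
    """The default study geometry: 6x6 grid, start in a corner, three goals.

    The exact goal rooms are not observable from the analyses (which depend
    only on path lengths), so defaults keep the goals off the start room and
    well separated; all geometry is configurable.
    """
    return TaskConfig(
        grid=GridSpec(6, 6),
        goals=(
            ("G1", RoomState(1, 4)),
            ("G2", RoomState(4, 1)),
            ("G3", RoomState(4, 4)),
        ),
        fixed_start=RoomState(0, 0),
    )


@dataclass(frozen=True)
class StepRecord:
    """One room transition: (state, action, next_state, reward)."""

    state: RoomState
    action: Action
    next_state: RoomState
    reward: float


@dataclass
class Trial:
    """One goal-seeking episode.

    If not truncated, the final step enters the goal room, and the goal room
    appears as a ``next_state`` only at that final step.
    """

    phase: str  # "fixed" | "random"
    trial_index: int
    goal_id: str
    start: RoomState
    steps: list[StepRecord] = field(default_factory=list)
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.phase not in ("fixed", "random"):
            raise ValueError(f"phase must be 'fixed' or 'random', got {self.phase!r}")

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    def validate(self, task: TaskConfig) -> None:
        grid = task.grid
        goal = task.goal_room(self.goal_id)
        if not self.steps:
            raise ValueError(f"trial {self.trial_index}: no steps")
        if self.steps[0].state != self.start:
            raise ValueError(f"trial {self.trial_index}: first step does not begin at start")
        for i, s in enumerate(self.steps):
            expected = step(grid, s.state, s.action)
            if s.next_state != expected:
                raise ValueError(
                    f"trial {self.trial_index} step {i}: next_state {tuple(s.next_state)} "
                    f"is not the result of {s.action.name} at {tuple(s.state)}"
                )
            if i + 1 < len(self.steps) and self.steps[i + 1].state != s.next_state:
                raise ValueError(f"trial {self.trial_index} step {i}: steps do not chain")
            at_goal = s.next_state == goal
            if at_goal != (s.reward > 0):
                raise ValueError(
                    f"trial {self.trial_index} step {i}: reward inconsistent with goal entry"
                )
            if at_goal and i != len(self.steps) - 1:
                raise ValueError(
                    f"trial {self.trial_index}: goal room entered before the final step"
                )
        if not self.truncated and self.steps[-1].next_state != goal:
            raise ValueError(f"trial {self.trial_index}: non-truncated trial does not end at goal")
        if self.truncated and self.steps[-1].next_state == goal:
            raise ValueError(f"trial {self.trial_index}: truncated trial ends at goal")


@dataclass
class ParticipantData:
    """All trials for one navigator, Fixed phase first, then Random."""

    participant_id: str
    trials: list[Trial]

    def phase_trials(self, phase: str) -> list[Trial]:
        if phase == "both":
            return list(self.trials)
        return [t for t in self.trials if t.phase == phase]

    def validate(self, task: TaskConfig) -> None:
        seen_random = False
        for t in self.trials:
            if t.phase == "random":
                seen_random = True
            elif seen_random:
                raise ValueError(
                    f"participant {self.participant_id}: fixed trial after random trials"
                )
            t.validate(task)


def build_trial(
    task: TaskConfig,
    phase: str,
    trial_index: int,
    goal_id: str,
    start: RoomState,
    actions: Sequence[Action],
    truncated: bool = False,
) -> Trial:
    """Construct and validate a trial from a start room and an action sequence."""
    grid = task.grid
    goal = task.goal_room(goal_id)
    steps = []
    room = start
    for a in actions:
        nxt = step(grid, room, a)
        reward = task.reward_magnitude if nxt == goal else 0.0
        steps.append(StepRecord(room, a, nxt, reward))
        room = nxt
    trial = Trial(phase, trial_index, goal_id, start, steps, truncated=truncated)
    trial.validate(task)
    return trial
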