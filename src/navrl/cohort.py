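"""Synthetic cohorts: seeded softmax RL agents on the Fixed/Random protocols.

Generative agents run the *same* per-step learning and choice code as the
likelihood replay (one implementation of the update rules), so the fitted
model class contains the generating process exactly — the prerequisite for
parameter- and model-recovery studies.

A cohort draws per-agent parameters from configurable marginals. The
dependence between the model-based weight omega and the inverse temperature
theta within each phase is induced through a Gaussian copula: a latent
bivariate normal is mapped through the marginal quantile functions, with the
latent correlation chosen to hit a target Spearman rank correlation
(rho_latent = 2 sin(pi * rho_s / 6)). Other parameters are independent.

The default cohort emulates the study's qualitative regime: omega
stochastically larger in the Random phase than in the Fixed phase, theta
stochastically larger in the Fixed phase, and omega–theta rank correlations
of +0.25 (Fixed) and -0.35 (Random).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import _core
from .fitting import _KIND_CODE
from .gridworld import (
    Action,
    ParticipantData,
    RoomState,
    StepRecord,
    TaskConfig,
    Trial,
    default_task,
)
from .learners import MBValues, ModelKind, PARAM_BOUNDS, compute_mb_values

__all__ = [
    "AgentSpec",
    "ParamDist",
    "CohortSpec",
    "make_goal_order",
    "sample_start",
    "simulate_agent",
    "simulate_cohort",
    "default_cohort",
    "recovery_cohort",
]

_MAX_SEED = 2**31 - 1


@dataclass(frozen=True)
class AgentSpec:
    """One generative agent: model kind plus per-phase parameters.

    theta and omega may differ between phases (they switch at the phase
    boundary); alpha and lam are shared. ``max_steps_per_trial`` caps a
    trial's length — a capped trial is flagged truncated, not an error.
    """

    agent_id: str
    model_kind: ModelKind = ModelKind.HYBRID
    alpha: float = 0.5
    theta_fixed: float = 5.0
    theta_random: float = 5.0
    lam: float = 0.0
    omega_fixed: float = 0.0
    omega_random: float = 0.0
    max_steps_per_trial: int = 2000

    def __post_init__(self) -> None:
        object.__setattr__(self, "model_kind", ModelKind.coerce(self.model_kind))
        for name, v in [
            ("alpha", self.alpha),
            ("theta", self.theta_fixed),
            ("theta", self.theta_random),
            ("lam", self.lam),
            ("omega", self.omega_fixed),
            ("omega", self.omega_random),
        ]:
            lo, hi = PARAM_BOUNDS[name]
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside bounds [{lo}, {hi}]")
        if self.max_steps_per_trial < 1:
            raise ValueError("max_steps_per_trial must be positive")


def make_goal_order(phase: str, n_trials: int, goal_ids: tuple[str, ...], seed: int) -> list[str]:
    """Goal sequence for a phase.

    Fixed: the goal list cycled in order, identical for every agent.
    Random: an independent seeded permutation of the goals within each
    consecutive block of len(goal_ids) trials.
    """
    k = len(goal_ids)
    if phase == "fixed":
        return [goal_ids[i % k] for i in range(n_trials)]
    if phase == "random":
        if n_trials % k != 0:
            raise ValueError(f"random-phase n_trials={n_trials} not divisible by {k} goals")
        rng = np.random.default_rng(seed)
        order: list[str] = []
        for _ in range(n_trials // k):
            order.extend(goal_ids[i] for i in rng.permutation(k))
        return order
    raise ValueError(f"phase must be 'fixed' or 'random', got {phase!r}")


def sample_start(task: TaskConfig, phase: str, rng: np.random.Generator) -> RoomState:
    """Trial start room: the fixed start, or a uniform non-goal room (Random)."""
    if phase == "fixed":
        return task.fixed_start
    if phase != "random":
        raise ValueError(f"phase must be 'fixed' or 'random', got {phase!r}")
    goal_rooms = {room for _, room in task.goals}
    candidates = [s for s in task.grid.states() if s not in goal_rooms]
    return candidates[int(rng.integers(len(candidates)))]


def _session_plan(
    task: TaskConfig, seed: int
) -> tuple[list[str], list[str], list[RoomState]]:
    """(phases, goal ids, start rooms) for a full 9 + 72 trial session."""
    rng = np.random.default_rng(seed)
    order_seed = int(rng.integers(_MAX_SEED))
    goal_f = make_goal_order("fixed", task.n_fixed_trials, task.goal_ids, order_seed)
    goal_r = make_goal_order("random", task.n_random_trials, task.goal_ids, order_seed)
    phases = ["fixed"] * task.n_fixed_trials + ["random"] * task.n_random_trials
    goals = goal_f + goal_r
    starts = [
        sample_start(task, ph, rng)
        for ph in phases
    ]
    return phases, goals, starts


def simulate_agent(
    agent: AgentSpec,
    task: TaskConfig,
    seed: int,
    mb: Optional[MBValues] = None,
) -> ParticipantData:
    """Run one agent through the full Fixed+Random session.

    Deterministic in (agent, task, seed): the same inputs give bit-identical
    trajectories. Choices are softmax over the agent's effective Q; Q_MF is
    carried across trials and phases; theta/omega switch at the phase
    boundary.
    """
    mb = mb if mb is not None else compute_mb_values(task)
    nxt, legal = task.grid.transition_arrays()
    phases, goals, starts = _session_plan(task, seed)
    n_trials = len(goals)
    cap = agent.max_steps_per_trial

    goal_arr = np.array([task.goal_index(g) for g in goals], dtype=np.int64)
    goal_state_arr = np.array(
        [task.grid.index(task.goal_room(g)) for g in goals], dtype=np.int64
    )
    start_arr = np.array([task.grid.index(s) for s in starts], dtype=np.int64)
    theta_arr = np.array(
        [agent.theta_fixed if p == "fixed" else agent.theta_random for p in phases]
    )
    omega_arr = np.array(
        [agent.omega_fixed if p == "fixed" else agent.omega_random for p in phases]
    )

    out_s = np.zeros((n_trials, cap), dtype=np.int64)
    out_a = np.zeros((n_trials, cap), dtype=np.int64)
    out_ns = np.zeros((n_trials, cap), dtype=np.int64)
    out_r = np.zeros((n_trials, cap), dtype=np.float64)
    out_len = np.zeros(n_trials, dtype=np.int64)
    out_trunc = np.zeros(n_trials, dtype=np.int64)

    sim_seed = int(np.random.default_rng(seed).integers(_MAX_SEED))
    _core.simulate_trials(
        _KIND_CODE[agent.model_kind],
        float(agent.alpha),
        theta_arr,
        float(agent.lam),
        omega_arr,
        False,
        mb.values,
        legal,
        nxt,
        goal_arr,
        start_arr,
        goal_state_arr,
        float(task.reward_magnitude),
        cap,
        sim_seed,
        out_s,
        out_a,
        out_ns,
        out_r,
        out_len,
        out_trunc,
    )

    trials: list[Trial] = []
    fixed_i = 0
    random_i = 0
    for i in range(n_trials):
        L = int(out_len[i])
        steps = [
            StepRecord(
                state=task.grid.state(int(out_s[i, t])),
                action=Action(int(out_a[i, t])),
                next_state=task.grid.state(int(out_ns[i, t])),
                reward=float(out_r[i, t]),
            )
            for t in range(L)
        ]
        if phases[i] == "fixed":
            idx = fixed_i
            fixed_i += 1
        else:
            idx = random_i
            random_i += 1
        trials.append(
            Trial(
                phase=phases[i],
                trial_index=idx,
                goal_id=goals[i],
                start=starts[i],
                steps=steps,
                truncated=bool(out_trunc[i]),
            )
        )
    return ParticipantData(participant_id=agent.agent_id, trials=trials)


@dataclass(frozen=True)
class ParamDist:
    """A marginal distribution: uniform on [low, high] or truncated normal."""

    kind: str  # "uniform" | "truncnorm"
    low: float
    high: float
    mean: Optional[float] = None
    sd: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "truncnorm"):
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        if self.kind == "truncnorm" and (self.mean is None or self.sd is None):
            raise ValueError("truncnorm requires mean and sd")
        if self.high < self.low:
            raise ValueError("high must not be below low (equal = point mass)")
        if self.kind == "truncnorm" and self.high == self.low:
            raise ValueError("point mass must use kind='uniform' with low == high")

    def ppf(self, u: np.ndarray) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        if self.kind == "uniform":
            return self.low + (self.high - self.low) * u
        a = (self.low - self.mean) / self.sd
        b = (self.high - self.mean) / self.sd
        return sps.truncnorm.ppf(u, a, b, loc=self.mean, scale=self.sd)

    def to_dict(self) -> dict:
        d = {"kind": self.kind, "low": self.low, "high": self.high}
        if self.kind == "truncnorm":
            d.update(mean=self.mean, sd=self.sd)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ParamDist":
        return cls(**d)


@dataclass(frozen=True)
class CohortSpec:
    """Generative distributions for a cohort plus target omega–theta coupling.

    ``rho_fixed`` / ``rho_random`` are target Spearman rank correlations
    between omega and theta within each phase, induced via a Gaussian copula.
    """

    n_agents: int
    task: TaskConfig
    model_kind: ModelKind = ModelKind.HYBRID
    alpha_dist: ParamDist = field(default_factory=lambda: ParamDist("uniform", 0.2, 0.8))
    lam_dist: ParamDist = field(default_factory=lambda: ParamDist("uniform", 0.0, 1.0))
    theta_fixed_dist: ParamDist = field(
        default_factory=lambda: ParamDist("truncnorm", 1.0, 15.0, mean=10.0, sd=2.0)
    )
    theta_random_dist: ParamDist = field(
        default_factory=lambda: ParamDist("truncnorm", 1.0, 15.0, mean=8.0, sd=1.0)
    )
    omega_fixed_dist: ParamDist = field(
        default_factory=lambda: ParamDist("truncnorm", 0.0, 1.0, mean=0.35, sd=0.25)
    )
    omega_random_dist: ParamDist = field(
        default_factory=lambda: ParamDist("truncnorm", 0.0, 1.0, mean=0.6, sd=0.3)
    )
    rho_fixed: float = 0.25
    rho_random: float = -0.35
    seed: int = 0
    max_steps_per_trial: int = 2000
    # draw one (omega, theta) per agent and use it in both phases
    phase_constant: bool = False

    def __post_init__(self) -> None:
        if self.n_agents < 2:
            raise ValueError("n_agents must be >= 2")
        for rho in (self.rho_fixed, self.rho_random):
            if not -1.0 < rho < 1.0:
                raise ValueError(f"target correlation {rho} must lie in (-1, 1)")


def _latent_corr(rho_spearman: float) -> float:
    """Gaussian-copula latent correlation achieving a Spearman target."""
    r = 2.0 * math.sin(math.pi * rho_spearman / 6.0)
    if not -1.0 < r < 1.0:
        raise ValueError(f"target rank correlation {rho_spearman} infeasible for a Gaussian copula")
    return r


def sample_parameters(spec: CohortSpec) -> pd.DataFrame:
    """Draw the per-agent parameter table (without simulating trajectories)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_agents
    rf = _latent_corr(spec.rho_fixed)
    rr = _latent_corr(spec.rho_random)
    cov_f = np.array([[1.0, rf], [rf, 1.0]])
    cov_r = np.array([[1.0, rr], [rr, 1.0]])
    zf = rng.multivariate_normal(np.zeros(2), cov_f, size=n)  # (omega_f, theta_f)
    zr = rng.multivariate_normal(np.zeros(2), cov_r, size=n)  # (omega_r, theta_r)
    if spec.phase_constant:
        zr = zf
    u = sps.norm.cdf(np.column_stack([zf, zr]))
    df = pd.DataFrame(
        {
            "agent_id": [f"A{i:04d}" for i in range(n)],
            "alpha": spec.alpha_dist.ppf(rng.random(n)),
            "theta_fixed": spec.theta_fixed_dist.ppf(u[:, 1]),
            "theta_random": spec.theta_random_dist.ppf(u[:, 3]),
            "lam": spec.lam_dist.ppf(rng.random(n)),
            "omega_fixed": spec.omega_fixed_dist.ppf(u[:, 0]),
            "omega_random": spec.omega_random_dist.ppf(u[:, 2]),
        }
    )
    df["seed"] = rng.integers(_MAX_SEED, size=n)
    return df


def simulate_cohort(
    spec: CohortSpec, mb: Optional[MBValues] = None
) -> tuple[list[ParticipantData], pd.DataFrame]:
    """Sample a cohort and simulate every agent; returns (data, true parameters)."""
    mb = mb if mb is not None else compute_mb_values(spec.task)
    params = sample_parameters(spec)
    cohort: list[ParticipantData] = []
    for row in params.itertuples(index=False):
        agent = AgentSpec(
            agent_id=row.agent_id,
            model_kind=spec.model_kind,
            alpha=float(row.alpha),
            theta_fixed=float(row.theta_fixed),
            theta_random=float(row.theta_random),
            lam=float(row.lam),
            omega_fixed=float(row.omega_fixed),
            omega_random=float(row.omega_random),
            max_steps_per_trial=spec.max_steps_per_trial,
        )
        cohort.append(simulate_agent(agent, spec.task, int(row.seed), mb=mb))
    return cohort, params


def default_cohort(seed: int, n_agents: int = 50, task: Optional[TaskConfig] = None) -> CohortSpec:
    """The default study-emulating cohort (hybrid agents; see module docstring)."""
    return CohortSpec(n_agents=n_agents, task=task or default_task(), seed=seed)


def recovery_cohort(
    seed: int,
    n_agents: int = 50,
    task: Optional[TaskConfig] = None,
    model_kind: ModelKind = ModelKind.HYBRID,
    theta_low: float = 3.0,
    theta_high: float = 10.0,
) -> CohortSpec:
    """A cohort for parameter/model recovery: identifiable, phase-constant regime.

    theta ~ U(theta_low, theta_high) and omega ~ U(0, 1), identical in both
    phases (zero omega–theta coupling); alpha ~ U(0.2, 0.8) keeps the
    model-free table informative (at alpha near 0 it stays flat and omega is
    structurally unidentifiable).
    """
    th = ParamDist("uniform", theta_low, theta_high)
    om = ParamDist("uniform", 0.0, 1.0)
    spec = CohortSpec(
        n_agents=n_agents,
        task=task or default_task(),
        model_kind=model_kind,
        theta_fixed_dist=th,
        theta_random_dist=th,
        omega_fixed_dist=om,
        omega_random_dist=om,
        rho_fixed=0.0,
        rho_random=0.0,
        seed=seed,
        phase_constant=True,
    )
    return spec
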