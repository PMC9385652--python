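"""Choice-likelihood replay, bounded MLE, BIC, and model comparison.

The likelihood of a navigator's data under a model is built by deterministic
replay: Q_MF starts at zero at the beginning of the experiment and is
carried across trials and phases; eligibility traces reset every trial; at
each room the probability of the recorded choice under the softmax of the
model's effective Q is accumulated, and the learning update then runs.

Phase handling: ``phase="fixed"`` scores Fixed-phase choices only;
``phase="random"`` first replays the Fixed phase under the candidate
parameters without scoring (warm start; ``cold_start=True`` instead resets
Q to zero at the phase boundary) and then scores Random-phase choices;
``phase="both"`` scores everything.

Model comparison uses BIC = k * ln(n) + 2 * NLL with natural log and, by
default, n = number of trials in the fitted phase.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import _core
from .gridworld import Action, ParticipantData, TaskConfig, Trial
from .learners import (
    TERMINAL,
    FREE_PARAMS,
    PARAM_BOUNDS,
    MBValues,
    ModelKind,
    ModelParams,
    compute_mb_values,
    softmax_probs,
    td_update,
    zeros_q,
    zeros_trace,
)

__all__ = [
    "FitResult",
    "trajectory_nll",
    "fit_mle",
    "bic",
    "compare_models",
    "fits_to_frame",
]

_KIND_CODE = {
    ModelKind.TD0: _core.KIND_TD0,
    ModelKind.TD1: _core.KIND_TD1,
    ModelKind.TDLAMBDA: _core.KIND_TDLAMBDA,
    ModelKind.MB: _core.KIND_MB,
    ModelKind.HYBRID: _core.KIND_HYBRID,
}

PHASES = ("fixed", "random", "both")


def _select_trials(data: ParticipantData, phase: str, cold_start: bool) -> list[tuple[Trial, bool]]:
    """Trials to replay, paired with whether their choices are scored."""
    if phase not in PHASES:
        raise ValueError(f"phase must be one of {PHASES}, got {phase!r}")
    out: list[tuple[Trial, bool]] = []
    for t in data.trials:
        if phase == "fixed":
            if t.phase == "fixed":
                out.append((t, True))
        elif phase == "random":
            if t.phase == "fixed":
                if not cold_start:
                    out.append((t, False))  # warm start: replay without scoring
            else:
                out.append((t, True))
        else:
            out.append((t, True))
    return out


@dataclass
class _Encoded:
    s: np.ndarray
    a: np.ndarray
    ns: np.ndarray
    r: np.ndarray
    g: np.ndarray
    trial_first: np.ndarray
    terminal: np.ndarray
    count: np.ndarray
    n_trials_scored: int
    n_choices_scored: int


def _encode(
    data: ParticipantData,
    task: TaskConfig,
    phase: str,
    include_truncated: bool,
    cold_start: bool,
) -> _Encoded:
    grid = task.grid
    rows: list[tuple[int, int, int, float, int, int, int, int]] = []
    n_trials_scored = 0
    for trial, scored in _select_trials(data, phase, cold_start):
        counted = scored and (include_truncated or not trial.truncated)
        if counted:
            n_trials_scored += 1
        g = task.goal_index(trial.goal_id)
        goal_state = grid.index(task.goal_room(trial.goal_id))
        for i, st in enumerate(trial.steps):
            s = grid.index(st.state)
            ns = grid.index(st.next_state)
            rows.append(
                (
                    s,
                    int(st.action),
                    ns,
                    float(st.reward),
                    g,
                    1 if i == 0 else 0,
                    1 if ns == goal_state else 0,
                    1 if counted else 0,
                )
            )
    if not rows:
        raise ValueError(f"no trials to replay for phase {phase!r}")
    enc = _Encoded(
        s=np.array([r[0] for r in rows], dtype=np.int64),
        a=np.array([r[1] for r in rows], dtype=np.int64),
        ns=np.array([r[2] for r in rows], dtype=np.int64),
        r=np.array([r[3] for r in rows], dtype=np.float64),
        g=np.array([r[4] for r in rows], dtype=np.int64),
        trial_first=np.array([r[5] for r in rows], dtype=np.uint8),
        terminal=np.array([r[6] for r in rows], dtype=np.uint8),
        count=np.array([r[7] for r in rows], dtype=np.uint8),
        n_trials_scored=n_trials_scored,
        n_choices_scored=int(sum(r[7] for r in rows)),
    )
    return enc


class _ReplayContext:
    """Pre-encoded arrays + precomputed MB table for repeated NLL evaluation."""

    def __init__(
        self,
        data: ParticipantData,
        task: TaskConfig,
        phase: str,
        include_truncated: bool = False,
        cold_start: bool = False,
        mb: Optional[MBValues] = None,
    ):
        self.task = task
        self.enc = _encode(data, task, phase, include_truncated, cold_start)
        self.mb = mb if mb is not None else compute_mb_values(task)
        _, self.legal = task.grid.transition_arrays()

    def nll(self, params: ModelParams, td1_accumulating: bool = False) -> float:
        e = self.enc
        return float(
            _core.replay_nll(
                _KIND_CODE[params.model_kind],
                float(params.alpha),
                float(params.theta),
                float(params.lam),
                float(params.omega),
                bool(td1_accumulating),
                self.mb.values,
                self.legal,
                e.s,
                e.a,
                e.ns,
                e.r,
                e.g,
                e.trial_first,
                e.terminal,
                e.count,
                self.task.n_goals,
                self.task.grid.n_states,
            )
        )


def trajectory_nll(
    data: ParticipantData,
    phase: str,
    params: ModelParams,
    task: TaskConfig,
    *,
    include_truncated: bool = False,
    cold_start: bool = False,
    td1_accumulating: bool = False,
    mb: Optional[MBValues] = None,
    engine: str = "numba",
) -> float:
    """Negative log-likelihood of the observed choices under ``params``.

    ``engine="python"`` runs a pure-Python reference replay built from the
    public `learners` operations; it is bit-compatible with the compiled
    kernel and exists as a cross-check and for step-level debugging.
    """
    if engine == "numba":
        ctx = _ReplayContext(data, task, phase, include_truncated, cold_start, mb)
        return ctx.nll(params, td1_accumulating)
    if engine != "python":
        raise ValueError(f"unknown engine {engine!r}")
    return _python_nll(data, phase, params, task, include_truncated, cold_start, td1_accumulating, mb)


def _effective_row(
    params: ModelParams, q: np.ndarray, mb: MBValues, task: TaskConfig, g: int, state
) -> dict[Action, float]:
    from .gridworld import available_actions

    grid = task.grid
    s = grid.index(state)
    row = {}
    for a in available_actions(grid, state):
        if params.model_kind == ModelKind.MB:
            v = mb.values[g, s, int(a)]
        elif params.model_kind == ModelKind.HYBRID:
            v = (1 - params.omega) * q[g, s, int(a)] + params.omega * mb.values[g, s, int(a)]
        else:
            v = q[g, s, int(a)]
        row[a] = float(v)
    return row


def _python_nll(
    data: ParticipantData,
    phase: str,
    params: ModelParams,
    task: TaskConfig,
    include_truncated: bool,
    cold_start: bool,
    td1_accumulating: bool,
    mb: Optional[MBValues],
) -> float:
    mb = mb if mb is not None else compute_mb_values(task)
    q = zeros_q(task)
    nll = 0.0
    for trial, scored in _select_trials(data, phase, cold_start):
        counted = scored and (include_truncated or not trial.truncated)
        trace = zeros_trace(task.grid)
        g = task.goal_index(trial.goal_id)
        goal_room = task.goal_room(trial.goal_id)
        if counted:
            p = softmax_probs(_effective_row(params, q, mb, task, g, trial.steps[0].state), params.theta)
            nll -= math.log(p[trial.steps[0].action])
        for i, st in enumerate(trial.steps):
            if st.next_state == goal_room:
                td_update(params, q, trace, g, st, TERMINAL, task.grid, td1_accumulating)
            elif i + 1 < len(trial.steps):
                a_next = trial.steps[i + 1].action
                if counted:
                    p = softmax_probs(
                        _effective_row(params, q, mb, task, g, st.next_state), params.theta
                    )
                    nll -= math.log(p[a_next])
                td_update(params, q, trace, g, st, a_next, task.grid, td1_accumulating)
            # else: truncated final step, no successor action, no update
    return nll


def bic(nll: float, k: int, n: int) -> float:
    """Bayesian Information Criterion, natural logarithm: k * ln(n) + 2 * NLL."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if k < 0:
        raise ValueError("k must be >= 0")
    return k * math.log(n) + 2.0 * float(nll)


@dataclass
class FitResult:
    """Outcome of one bounded maximum-likelihood fit."""

    participant_id: str
    phase: str
    model_kind: ModelKind
    params_hat: ModelParams
    nll: float
    k: int
    n: int
    bic: float
    n_restarts: int
    seed: int
    best_restart_index: int

    def to_row(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "phase": self.phase,
            "model": self.model_kind.value,
            "alpha": self.params_hat.alpha if "alpha" in self.params_hat.free_names else np.nan,
            "theta": self.params_hat.theta,
            "lam": self.params_hat.lam if "lam" in self.params_hat.free_names else np.nan,
            "omega": self.params_hat.omega if "omega" in self.params_hat.free_names else np.nan,
            "nll": self.nll,
            "k": self.k,
            "n": self.n,
            "bic": self.bic,
            "n_restarts": self.n_restarts,
            "seed": self.seed,
            "best_restart_index": self.best_restart_index,
        }


def fits_to_frame(fits: Iterable[FitResult]) -> pd.DataFrame:
    return pd.DataFrame([f.to_row() for f in fits])


def fit_mle(
    data: ParticipantData,
    phase: str,
    model_kind: ModelKind,
    task: TaskConfig,
    n_restarts: int = 10,
    seed: int = 0,
    *,
    include_truncated: bool = False,
    cold_start: bool = False,
    td1_accumulating: bool = False,
    bic_n_mode: str = "trials",
    mb: Optional[MBValues] = None,
) -> FitResult:
    """Bounded MLE by L-BFGS-B from seeded uniform-random restarts.

    Returns the restart achieving the lowest NLL. ``bic_n_mode`` selects the
    BIC sample-size term: "trials" (default; the number of scored trials) or
    "choices" (the number of scored step choices).
    """
    model_kind = ModelKind.coerce(model_kind)
    ctx = _ReplayContext(data, task, phase, include_truncated, cold_start, mb)
    if ctx.enc.n_trials_scored < 1:
        raise ValueError(f"no scored trials in phase {phase!r}")
    names = FREE_PARAMS[model_kind]
    bounds = [PARAM_BOUNDS[n] for n in names]
    rng = np.random.default_rng(seed)

    def objective(x: np.ndarray) -> float:
        val = ctx.nll(ModelParams.from_vector(model_kind, x), td1_accumulating)
        # TD(lambda) at alpha, lam near 1 can diverge; keep the surface finite
        return val if np.isfinite(val) else 1e12

    best = None
    best_idx = -1
    failures = []
    for i in range(n_restarts):
        x0 = np.array([rng.uniform(lo, hi) for lo, hi in bounds])
        res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds)
        if not np.isfinite(res.fun) or res.fun >= 1e11:
            failures.append((i, res.message))
            continue
        if best is None or res.fun < best.fun:
            best = res
            best_idx = i
    if best is None:
        raise RuntimeError(f"all {n_restarts} restarts failed: {failures}")
    params_hat = ModelParams.from_vector(model_kind, np.clip(best.x, [b[0] for b in bounds], [b[1] for b in bounds]))
    if bic_n_mode == "trials":
        n = ctx.enc.n_trials_scored
    elif bic_n_mode == "choices":
        n = ctx.enc.n_choices_scored
    else:
        raise ValueError(f"bic_n_mode must be 'trials' or 'choices', got {bic_n_mode!r}")
    k = len(names)
    return FitResult(
        participant_id=data.participant_id,
        phase=phase,
        model_kind=model_kind,
        params_hat=params_hat,
        nll=float(best.fun),
        k=k,
        n=n,
        bic=bic(best.fun, k, n),
        n_restarts=n_restarts,
        seed=seed,
        best_restart_index=best_idx,
    )


_MODEL_K = {kind: len(names) for kind, names in FREE_PARAMS.items()}


def _winner(row: pd.Series) -> str:
    """Minimum-BIC model; ties (to 1e-9) broken toward fewer parameters, then name."""
    m = row.min()
    cands = [c for c in row.index if row[c] <= m + 1e-9]
    return sorted(cands, key=lambda c: (_MODEL_K[ModelKind(c)], c))[0]


def compare_models(fits: Sequence[FitResult] | pd.DataFrame, phase: str) -> dict:
    """Per-model BIC summary, per-participant winners, and pairwise differences.

    Requires one fit per participant x model in ``phase``; raises listing any
    gaps. Returns {"summary", "winners", "pairwise_mean_bic_diff", "bic_wide"}.
    """
    df = fits if isinstance(fits, pd.DataFrame) else fits_to_frame(fits)
    df = df[df["phase"] == phase]
    if df.empty:
        raise ValueError(f"no fits for phase {phase!r}")
    wide = df.pivot_table(index="participant_id", columns="model", values="bic")
    if wide.isna().any().any():
        gaps = [
            (pid, model)
            for pid in wide.index
            for model in wide.columns
            if pd.isna(wide.loc[pid, model])
        ]
        raise ValueError(f"missing participant x model fits: {gaps}")
    winners = wide.apply(_winner, axis=1)
    summary = pd.DataFrame(
        {
            "mean_bic": wide.mean(),
            "sd_bic": wide.std(ddof=1) if len(wide) > 1 else np.nan,
            "n_wins": winners.value_counts().reindex(wide.columns, fill_value=0),
        }
    )
    models = list(wide.columns)
    pair = pd.DataFrame(
        [[(wide[m1] - wide[m2]).mean() for m2 in models] for m1 in models],
        index=models,
        columns=models,
    )
    return {
        "summary": summary,
        "winners": winners,
        "pairwise_mean_bic_diff": pair,
        "bic_wide": wide,
    }
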