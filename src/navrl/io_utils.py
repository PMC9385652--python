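"""File formats: trajectory CSV, task JSON, fits CSV, report JSON.

All writers produce deterministic output (fixed column order, 12
significant digits for floating quantities, UTF-8), so identical in-memory
objects always serialize byte-identically.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .gridworld import (
    Action,
    ParticipantData,
    RoomState,
    StepRecord,
    TaskConfig,
    Trial,
)

__all__ = [
    "TRAJECTORY_COLUMNS",
    "write_trajectories",
    "read_trajectories",
    "write_task",
    "read_task",
    "write_fits",
    "read_fits",
    "write_true_params",
    "write_report",
]

TRAJECTORY_COLUMNS = [
    "participant_id",
    "phase",
    "trial_index",
    "goal_id",
    "step_index",
    "row",
    "col",
    "action",
    "next_row",
    "next_col",
    "reward",
    "truncated",
]


def _fmt(x: float) -> str:
    return format(float(x), ".12g")


def write_trajectories(cohort: Sequence[ParticipantData], path: str | Path) -> None:
    """One CSV row per step, participants in order, fixed trials first."""
    lines = [",".join(TRAJECTORY_COLUMNS)]
    for p in cohort:
        for t in p.trials:
            for i, st in enumerate(t.steps):
                lines.append(
                    ",".join(
                        [
                            str(p.participant_id),
                            t.phase,
                            str(t.trial_index),
                            str(t.goal_id),
                            str(i),
                            str(st.state.row),
                            str(st.state.col),
                            st.action.name.lower(),
                            str(st.next_state.row),
                            str(st.next_state.col),
                            _fmt(st.reward),
                            "1" if t.truncated else "0",
                        ]
                    )
                )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_trajectories(path: str | Path, task: TaskConfig | None = None) -> list[ParticipantData]:
    """Parse and validate a trajectory CSV.

    Validation (chaining, adjacency, goal termination, phase ordering) cites
    the offending file row. If ``task`` is omitted the default 6x6 task is
    assumed for bounds/goal checks.
    """
    from .gridworld import default_task

    task = task or default_task()
    grid = task.grid
    df = pd.read_csv(path)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    cohort: list[ParticipantData] = []
    # +2: header line and 1-based numbering, for error messages
    df["csv_row"] = np.arange(2, len(df) + 2)
    for pid, pdf in df.groupby("participant_id", sort=False):
        trials: list[Trial] = []
        for (phase, tidx), tdf in pdf.groupby(["phase", "trial_index"], sort=False):
            tdf = tdf.sort_values("step_index")
            steps = []
            for rec in tdf.itertuples(index=False):
                state = RoomState(int(rec.row), int(rec.col))
                nxt = RoomState(int(rec.next_row), int(rec.next_col))
                if not grid.contains(state) or not grid.contains(nxt):
                    raise ValueError(f"{path} row {rec.csv_row}: room outside the grid")
                try:
                    action = Action.from_name(str(rec.action))
                except ValueError as e:
                    raise ValueError(f"{path} row {rec.csv_row}: {e}") from None
                steps.append(StepRecord(state, action, nxt, float(rec.reward)))
            first = tdf.iloc[0]
            trial = Trial(
                phase=str(phase),
                trial_index=int(tidx),
                goal_id=str(first["goal_id"]),
                start=steps[0].state,
                steps=steps,
                truncated=bool(int(first["truncated"])),
            )
            try:
                trial.validate(task)
            except ValueError as e:
                rows = f"rows {int(tdf['csv_row'].iloc[0])}-{int(tdf['csv_row'].iloc[-1])}"
                raise ValueError(f"{path} {rows}: {e}") from None
            trials.append(trial)
        data = ParticipantData(participant_id=str(pid), trials=trials)
        data.validate(task)
        cohort.append(data)
    return cohort


def write_task(task: TaskConfig, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(task.to_dict(), indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def read_task(path: str | Path) -> TaskConfig:
    return TaskConfig.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


FITS_COLUMNS = [
    "participant_id",
    "phase",
    "model",
    "alpha",
    "theta",
    "lam",
    "omega",
    "nll",
    "k",
    "n",
    "bic",
    "n_restarts",
    "seed",
    "best_restart_index",
]


def write_fits(fits_df: pd.DataFrame, path: str | Path) -> None:
    """Deterministic fits CSV (12 significant digits on likelihood quantities)."""
    df = fits_df[FITS_COLUMNS].copy()
    lines = [",".join(FITS_COLUMNS)]
    for rec in df.itertuples(index=False):
        vals = []
        for col, v in zip(FITS_COLUMNS, rec):
            if isinstance(v, float) and not pd.isna(v):
                vals.append(_fmt(v))
            elif pd.isna(v):
                vals.append("")
            else:
                vals.append(str(v))
        lines.append(",".join(vals))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_fits(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in FITS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


TRUE_PARAM_COLUMNS = [
    "agent_id",
    "alpha",
    "theta_fixed",
    "theta_random",
    "lam",
    "omega_fixed",
    "omega_random",
    "seed",
]


def write_true_params(params: pd.DataFrame, path: str | Path) -> None:
    df = params[TRUE_PARAM_COLUMNS]
    lines = [",".join(TRUE_PARAM_COLUMNS)]
    for rec in df.itertuples(index=False):
        vals = [
            _fmt(v) if isinstance(v, float) else str(v)
            for v in rec
        ]
        lines.append(",".join(vals))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    return obj


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(_jsonify(report), indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
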