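"""Wayfinding metrics and the study-level statistical analyses.

Covers: excessive distance (the wayfinding-efficiency index), paired t tests
with Cohen's d, one-way repeated-measures ANOVA over model BICs, Pearson
correlations, the comparison of two dependent non-overlapping correlations
(Pearson–Filon family), the sensitivity power analysis for a correlation,
and parameter/model recovery summaries for validating the fitting pipeline.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .gridworld import GridSpec, ParticipantData, Trial, shortest_path_rooms

__all__ = [
    "EDRecord",
    "excessive_distance",
    "ed_table",
    "paired_t",
    "rm_anova_oneway",
    "pearson_r",
    "compare_dependent_correlations",
    "min_detectable_r",
    "RecoveryReport",
    "recovery_report",
]


@dataclass(frozen=True)
class EDRecord:
    """Per-trial excessive distance: ed = (actual - optimal) / optimal."""

    participant_id: str
    phase: str
    trial_index: int
    actual: int
    optimal: int
    ed: float


def excessive_distance(trial: Trial, grid: GridSpec) -> float:
    """(actual traversed rooms - optimal rooms) / optimal rooms.

    0 indicates perfect wayfinding (the shortest path was taken); 1 means the
    traversed path was 100% longer than optimal. Truncated trials have no
    defined ED and raise.
    """
    if trial.truncated:
        raise ValueError(f"trial {trial.trial_index}: ED undefined for a truncated trial")
    goal = trial.steps[-1].next_state
    optimal = shortest_path_rooms(grid, trial.start, goal)
    if optimal < 1:
        raise ValueError(f"trial {trial.trial_index}: start equals goal (optimal distance 0)")
    return (trial.n_steps - optimal) / optimal


def ed_table(
    cohort: Sequence[ParticipantData],
    grid: GridSpec,
    truncated: str = "exclude",
) -> pd.DataFrame:
    """Per-trial ED records for a cohort.

    ``truncated``: "exclude" drops capped trials (default); "nan" keeps them
    with ed = NaN.
    """
    if truncated not in ("exclude", "nan"):
        raise ValueError("truncated must be 'exclude' or 'nan'")
    rows = []
    for p in cohort:
        for t in p.trials:
            if t.truncated:
                if truncated == "exclude":
                    continue
                rec = EDRecord(p.participant_id, t.phase, t.trial_index, t.n_steps, -1, float("nan"))
            else:
                goal = t.steps[-1].next_state
                opt = shortest_path_rooms(grid, t.start, goal)
                rec = EDRecord(
                    p.participant_id, t.phase, t.trial_index, t.n_steps, opt, (t.n_steps - opt) / opt
                )
            rows.append(rec.__dict__)
    return pd.DataFrame(rows)


def mean_ed_by_phase(ed: pd.DataFrame) -> pd.DataFrame:
    """Participant x phase mean ED (wide: columns 'fixed', 'random')."""
    return ed.pivot_table(index="participant_id", columns="phase", values="ed", aggfunc="mean")


def paired_t(x: np.ndarray, y: np.ndarray) -> tuple[float, int, float, float]:
    """Paired t test; returns (t, df, p, Cohen's d) with d = mean(diff)/sd(diff)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3 pairs")
    diff = x - y
    sd = diff.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of differences")
    res = sps.ttest_rel(x, y)
    d = diff.mean() / sd
    return float(res.statistic), n - 1, float(res.pvalue), float(d)


def rm_anova_oneway(values: np.ndarray | pd.DataFrame) -> dict:
    """One-way repeated-measures ANOVA on a participants x conditions table.

    Classical sums-of-squares decomposition: SS_total = SS_subject +
    SS_condition + SS_error, F = MS_condition / MS_error with df =
    (k-1, (k-1)(N-1)). Reports eta_sq = SS_condition / SS_total (the
    classical eta^2 for this design) and partial eta^2 =
    SS_condition / (SS_condition + SS_error).
    """
    arr = values.to_numpy(dtype=float) if isinstance(values, pd.DataFrame) else np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValueError("values must be a 2-D participants x conditions table")
    if np.isnan(arr).any():
        raise ValueError("missing cells in the repeated-measures table")
    n, k = arr.shape
    if k < 2 or n < 3:
        raise ValueError("need >= 2 conditions and >= 3 participants")
    grand = arr.mean()
    ss_total = ((arr - grand) ** 2).sum()
    ss_subj = k * ((arr.mean(axis=1) - grand) ** 2).sum()
    ss_cond = n * ((arr.mean(axis=0) - grand) ** 2).sum()
    ss_err = ss_total - ss_subj - ss_cond
    df1 = k - 1
    df2 = (k - 1) * (n - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    if ms_err == 0:
        f = math.inf if ms_cond > 0 else 0.0
        p = 0.0 if ms_cond > 0 else 1.0
    else:
        f = ms_cond / ms_err
        p = float(sps.f.sf(f, df1, df2))
    eta = ss_cond / ss_total if ss_total > 0 else 0.0
    eta_p = ss_cond / (ss_cond + ss_err) if (ss_cond + ss_err) > 0 else 0.0
    return {
        "F": float(f),
        "df1": df1,
        "df2": df2,
        "p": p,
        "eta_sq": float(eta),
        "partial_eta_sq": float(eta_p),
        "ss_condition": float(ss_cond),
        "ss_subject": float(ss_subj),
        "ss_error": float(ss_err),
    }


def pearson_r(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided t-based p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 4:
        raise ValueError("x and y must be equal-length vectors of length >= 4")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input has no defined correlation")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def _pf_k(r12: float, r34: float, r13: float, r14: float, r23: float, r24: float) -> float:
    """Pearson–Filon covariance term for two dependent non-overlapping correlations."""
    return (
        (r13 - r12 * r23) * (r24 - r23 * r34)
        + (r14 - r13 * r34) * (r23 - r13 * r12)
        + (r13 - r14 * r34) * (r24 - r14 * r12)
        + (r14 - r12 * r24) * (r23 - r24 * r34)
    )


def compare_dependent_correlations(
    r12: float,
    r34: float,
    r13: float,
    r14: float,
    r23: float,
    r24: float,
    n: int,
    method: str = "zpf",
) -> tuple[float, float]:
    """Test r12 = r34 for two dependent correlations sharing no variable.

    Variables 1,2 form the first correlation and 3,4 the second; the four
    cross-correlations complete the 4x4 matrix, which must be positive
    semidefinite. ``method="zpf"`` (default) is the Fisher-z stabilized
    Pearson–Filon statistic; ``method="pf"`` is the raw Pearson–Filon test.
    Returns (z, two-sided p).
    """
    if n < 10:
        raise ValueError("need n >= 10")
    for r in (r12, r34):
        if not -1.0 < r < 1.0:
            raise ValueError("compared correlations must lie strictly in (-1, 1)")
    R = np.array(
        [
            [1.0, r12, r13, r14],
            [r12, 1.0, r23, r24],
            [r13, r23, 1.0, r34],
            [r14, r24, r34, 1.0],
        ]
    )
    if np.linalg.eigvalsh(R).min() < -1e-8:
        raise ValueError("correlation matrix is not positive semidefinite")
    k = _pf_k(r12, r34, r13, r14, r23, r24)
    if method == "pf":
        denom = (1 - r12**2) ** 2 + (1 - r34**2) ** 2 - k
        z = math.sqrt(n) * (r12 - r34) / math.sqrt(denom)
    elif method == "zpf":
        z12 = math.atanh(r12)
        z34 = math.atanh(r34)
        denom = 1.0 - k / (2.0 * (1 - r12**2) * (1 - r34**2))
        z = math.sqrt((n - 3) / 2.0) * (z12 - z34) / math.sqrt(denom)
    else:
        raise ValueError(f"method must be 'zpf' or 'pf', got {method!r}")
    p = 2.0 * float(sps.norm.sf(abs(z)))
    return float(z), p


def min_detectable_r(n: int, alpha: float = 0.05, power: float = 0.8) -> float:
    """Smallest correlation detectable at two-sided ``alpha`` with given power.

    Fisher-z sensitivity analysis: tanh((z_{1-alpha/2} + z_{power}) / sqrt(n-3)).
    """
    if n < 4:
        raise ValueError("need n >= 4")
    za = sps.norm.ppf(1.0 - alpha / 2.0)
    zb = sps.norm.ppf(power)
    return float(np.tanh((za + zb) / math.sqrt(n - 3)))


@dataclass
class RecoveryReport:
    """Parameter- and model-recovery summary for a simulated cohort."""

    parameter_stats: pd.DataFrame  # index: parameter; cols: r, bias, rmse, n
    confusion: Optional[pd.DataFrame] = None  # generating model x selected model

    def to_dict(self) -> dict:
        out = {"parameters": self.parameter_stats.to_dict(orient="index")}
        if self.confusion is not None:
            out["confusion"] = {
                str(g): {str(m): int(v) for m, v in row.items()}
                for g, row in self.confusion.to_dict(orient="index").items()
            }
        return out


def recovery_report(
    true_params: pd.DataFrame,
    fitted: pd.DataFrame,
    param_cols: Sequence[tuple[str, str]] = (),
    winners: Optional[pd.DataFrame] = None,
) -> RecoveryReport:
    """Compare fitted parameters (and BIC winners) against generating truth.

    ``true_params`` must have an ``agent_id`` column; ``fitted`` a
    ``participant_id`` column. ``param_cols`` lists (true_column,
    fitted_column) pairs to score; each gets Pearson r(true, fitted), bias
    (mean fitted - true), and RMSE. ``winners`` optionally carries columns
    (participant_id, generating_model, selected_model) for a model-recovery
    confusion matrix.
    """
    merged = true_params.merge(
        fitted,
        left_on="agent_id",
        right_on="participant_id",
        how="inner",
        suffixes=("_true", "_fit"),
    )
    if len(merged) != len(true_params):
        missing = set(true_params["agent_id"]) - set(fitted["participant_id"])
        raise ValueError(f"agent ids missing from fits: {sorted(missing)}")
    rows = {}
    for true_col, fit_col in param_cols:
        tc = true_col if true_col in merged.columns else f"{true_col}_true"
        fc = fit_col if fit_col in merged.columns else f"{fit_col}_fit"
        t = merged[tc].to_numpy(dtype=float)
        f = merged[fc].to_numpy(dtype=float)
        err = f - t
        r = pearson_r(t, f)[0] if t.std() > 0 and f.std() > 0 else float("nan")
        rows[true_col] = {
            "r": r,
            "bias": float(err.mean()),
            "rmse": float(np.sqrt((err**2).mean())),
            "n": len(merged),
        }
    stats = pd.DataFrame.from_dict(rows, orient="index")
    confusion = None
    if winners is not None:
        confusion = pd.crosstab(winners["generating_model"], winners["selected_model"])
    return RecoveryReport(parameter_stats=stats, confusion=confusion)


def study_report(
    fits_df: pd.DataFrame,
    ed_wide: Optional[pd.DataFrame] = None,
    true_params: Optional[pd.DataFrame] = None,
) -> dict:
    """Assemble the full individual-differences analysis for a fitted cohort.

    Expects the long fits table (one row per participant x phase x model).
    Produces, per phase, the BIC model-comparison summary; from the hybrid
    fits, the omega/theta phase contrasts (paired t), the 4x4 correlation
    matrix of (omega_fixed, omega_random, theta_fixed, theta_random), the
    dependent-correlation comparison of the within-phase omega–theta
    correlations, and (if ``ed_wide`` from `mean_ed_by_phase` is given) the
    omega–ED correlations. If ``true_params`` is given, a parameter-recovery
    block is appended.
    """
    from .fitting import compare_models  # deferred: fitting does not import stats

    report: dict = {"model_comparison": {}}
    for phase in ("fixed", "random"):
        if (fits_df["phase"] == phase).any():
            cmp = compare_models(fits_df, phase)
            report["model_comparison"][phase] = {
                "summary": cmp["summary"].to_dict(orient="index"),
                "n_wins": cmp["summary"]["n_wins"].to_dict(),
            }

    hyb = fits_df[fits_df["model"] == "hybrid"]
    if {"fixed", "random"} <= set(hyb["phase"]):
        wide = hyb.pivot_table(index="participant_id", columns="phase", values=["omega", "theta"])
        wide.columns = [f"{p}_{ph}" for p, ph in wide.columns]
        wide = wide.dropna()
        n = len(wide)
        if n >= 4:
            om_f = wide["omega_fixed"].to_numpy()
            om_r = wide["omega_random"].to_numpy()
            th_f = wide["theta_fixed"].to_numpy()
            th_r = wide["theta_random"].to_numpy()
            t_om = paired_t(om_f, om_r)
            t_th = paired_t(th_f, th_r)
            report["phase_contrasts"] = {
                "omega_fixed_minus_random": dict(zip(("t", "df", "p", "cohens_d"), t_om)),
                "theta_fixed_minus_random": dict(zip(("t", "df", "p", "cohens_d"), t_th)),
            }
            cols = {
                "omega_fixed": om_f,
                "omega_random": om_r,
                "theta_fixed": th_f,
                "theta_random": th_r,
            }
            names = list(cols)
            corr = {
                a: {b: pearson_r(cols[a], cols[b])[0] if a != b else 1.0 for b in names}
                for a in names
            }
            report["omega_theta_correlations"] = corr
            r12 = corr["omega_fixed"]["theta_fixed"]
            r34 = corr["omega_random"]["theta_random"]
            z, p = compare_dependent_correlations(
                r12,
                r34,
                corr["omega_fixed"]["omega_random"],
                corr["omega_fixed"]["theta_random"],
                corr["theta_fixed"]["omega_random"],
                corr["theta_fixed"]["theta_random"],
                n,
            )
            report["omega_theta_phase_comparison"] = {
                "r_fixed": r12,
                "r_random": r34,
                "z": z,
                "p": p,
                "n": n,
            }
            if ed_wide is not None:
                ed = ed_wide.reindex(wide.index)
                block = {}
                for phase in ("fixed", "random"):
                    if phase in ed.columns and ed[phase].notna().all():
                        r, pv = pearson_r(cols[f"omega_{phase}"], ed[phase].to_numpy())
                        block[phase] = {"r": r, "p": pv, "n": n}
                report["omega_ed_correlations"] = block
            if true_params is not None:
                rec = recovery_report(
                    true_params,
                    wide.reset_index(),
                    param_cols=[
                        ("omega_fixed", "omega_fixed"),
                        ("omega_random", "omega_random"),
                        ("theta_fixed", "theta_fixed"),
                        ("theta_random", "theta_random"),
                    ],
                )
                report["recovery"] = rec.to_dict()
    return report
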