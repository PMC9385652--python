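"""Wayfinding metrics and the statistical toolbox."""
import math

import numpy as np
import pandas as pd
import pytest

from navrl.gridworld import Action, RoomState, build_trial
from navrl.stats import (
    compare_dependent_correlations,
    ed_table,
    excessive_distance,
    mean_ed_by_phase,
    min_detectable_r,
    paired_t,
    pearson_r,
    recovery_report,
    rm_anova_oneway,
)


def _detour_trial(task, n_detours):
    """(2,0) -> G3=(4,4): optimal 6 steps, plus n_detours back-and-forth pairs."""
    actions = [Action.DOWN, Action.UP] * n_detours
    actions += [Action.DOWN, Action.DOWN] + [Action.RIGHT] * 4
    return build_trial(task, "random", 0, "G3", RoomState(2, 0), actions)


class TestExcessiveDistance:
    def test_optimal_path_scores_zero(self, task):
        assert excessive_distance(_detour_trial(task, 0), task.grid) == pytest.approx(0.0)

    def test_double_distance_scores_one(self, task):
        assert excessive_distance(_detour_trial(task, 3), task.grid) == pytest.approx(1.0)

    def test_fractional_overshoot(self, task):
        # 1 detour pair: 8 steps vs optimal 6 -> ED = 2/6
        assert excessive_distance(_detour_trial(task, 1), task.grid) == pytest.approx(2 / 6)

    def test_scale_consistency(self, task):
        """Doubling both actual and optimal path lengths leaves ED unchanged."""
        short = build_trial(
            task,
            "random",
            0,
            "G3",
            RoomState(4, 2),
            [Action.DOWN, Action.UP, Action.RIGHT, Action.RIGHT],  # 4 vs optimal 2
        )
        lng = build_trial(
            task,
            "random",
            0,
            "G3",
            RoomState(4, 0),
            [Action.DOWN, Action.UP] * 2 + [Action.RIGHT] * 4,  # 8 vs optimal 4
        )
        assert excessive_distance(short, task.grid) == pytest.approx(
            excessive_distance(lng, task.grid)
        )

    def test_truncated_trial_rejected(self, task):
        t = build_trial(task, "random", 0, "G3", RoomState(2, 0), [Action.DOWN], truncated=True)
        with pytest.raises(ValueError, match="truncated"):
            excessive_distance(t, task.grid)

    def test_ed_table_excludes_truncated_by_default(self, task):
        ok = _detour_trial(task, 0)
        bad = build_trial(task, "random", 1, "G3", RoomState(2, 0), [Action.DOWN], truncated=True)
        from navrl.gridworld import ParticipantData

        data = ParticipantData("p", [ok, bad])
        df = ed_table([data], task.grid)
        assert len(df) == 1
        df2 = ed_table([data], task.grid, truncated="nan")
        assert len(df2) == 2 and df2["ed"].isna().sum() == 1


class TestPairedT:
    def test_identical_vectors_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            paired_t(np.ones(5), np.ones(5))

    def test_df_is_n_minus_one(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=114), rng.normal(size=114)
        _, df, _, _ = paired_t(x, y)
        assert df == 113

    def test_hand_example(self):
        """x=(1,2,3), y=(0,2,2): diff=(1,0,1), mean=2/3, sd=1/sqrt(3)."""
        t, df, p, d = paired_t(np.array([1.0, 2, 3]), np.array([0.0, 2, 2]))
        sd = math.sqrt(((1 - 2 / 3) ** 2 + (0 - 2 / 3) ** 2 + (1 - 2 / 3) ** 2) / 2)
        t_hand = (2 / 3) / (sd / math.sqrt(3))
        assert t == pytest.approx(t_hand, rel=1e-12)
        assert d == pytest.approx((2 / 3) / sd, rel=1e-12)
        assert df == 2

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(1)
        x = rng.normal(size=40)
        y = x + rng.normal(0.3, 1.0, size=40)
        t, df, p, d = paired_t(x, y)
        res = pg.ttest(x, y, paired=True)
        assert t == pytest.approx(res["T"].iloc[0], rel=1e-9)
        assert p == pytest.approx(res["p_val"].iloc[0], rel=1e-9)


class TestRMAnova:
    def test_degrees_of_freedom(self):
        rng = np.random.default_rng(2)
        res = rm_anova_oneway(rng.normal(size=(114, 3)))
        assert (res["df1"], res["df2"]) == (2, 226)

    def test_identical_conditions_give_zero_f(self):
        rng = np.random.default_rng(3)
        col = rng.normal(size=10)
        res = rm_anova_oneway(np.column_stack([col, col, col]))
        assert res["F"] == pytest.approx(0.0)
        assert res["ss_condition"] == pytest.approx(0.0)

    def test_hand_sums_of_squares(self):
        """4 subjects x 3 conditions, decomposition worked by hand."""
        table = np.array(
            [
                [1.0, 2.0, 3.0],
                [2.0, 2.0, 4.0],
                [3.0, 4.0, 5.0],
                [4.0, 4.0, 6.0],
            ]
        )
        grand = table.mean()
        ss_cond = 4 * sum((table.mean(axis=0) - grand) ** 2)
        ss_subj = 3 * sum((table.mean(axis=1) - grand) ** 2)
        ss_tot = ((table - grand) ** 2).sum()
        ss_err = ss_tot - ss_cond - ss_subj
        f_hand = (ss_cond / 2) / (ss_err / 6)
        res = rm_anova_oneway(table)
        assert res["F"] == pytest.approx(f_hand, rel=1e-12)
        assert res["eta_sq"] == pytest.approx(ss_cond / ss_tot, rel=1e-12)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        wide = rng.normal(size=(20, 3)) + np.array([0.0, 0.3, 0.6])
        res = rm_anova_oneway(wide)
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(20), 3),
                "cond": np.tile(np.arange(3), 20),
                "y": wide.ravel(),
            }
        )
        aov = pg.rm_anova(data=long, dv="y", within="cond", subject="subject", detailed=True)
        assert res["F"] == pytest.approx(aov["F"].iloc[0], rel=1e-9)
        assert res["p"] == pytest.approx(aov["p_unc"].iloc[0], rel=1e-9)

    def test_f_equals_t_squared_for_two_conditions(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=30)
        y = x + rng.normal(0.2, 0.8, size=30)
        res = rm_anova_oneway(np.column_stack([x, y]))
        t, _, p_t, _ = paired_t(x, y)
        assert res["F"] == pytest.approx(t**2, abs=1e-9)
        assert res["p"] == pytest.approx(p_t, abs=1e-12)

    def test_missing_cells_rejected(self):
        bad = np.array([[1.0, 2.0], [np.nan, 3.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="missing"):
            rm_anova_oneway(bad)


class TestPearson:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2, 3, 4, 5])
        assert pearson_r(x, x)[0] == pytest.approx(1.0)
        assert pearson_r(x, -x)[0] == pytest.approx(-1.0)

    def test_hand_example(self):
        x = np.array([1.0, 2, 3, 4])
        y = np.array([2.0, 1, 4, 3])
        num = ((x - x.mean()) * (y - y.mean())).sum()
        den = math.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        assert pearson_r(x, y)[0] == pytest.approx(num / den, rel=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_r(np.ones(5), np.arange(5.0))


class TestDependentCorrelations:
    # the published 4x4 matrix used as the worked example
    CROSS = dict(r13=0.53, r14=-0.27, r23=0.31, r24=-0.20)

    def test_equal_correlations_give_zero(self):
        z, p = compare_dependent_correlations(0.3, 0.3, 0.4, 0.1, 0.1, 0.4, 100)
        assert z == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_zpf_frozen_value(self):
        """Independent evaluation of the Fisher-z Pearson-Filon formula."""
        z, p = compare_dependent_correlations(0.25, -0.35, n=114, **self.CROSS)
        assert z == pytest.approx(4.407138093997829, abs=1e-9)
        assert p < 1e-4

    def test_pf_frozen_value(self):
        z, _ = compare_dependent_correlations(0.25, -0.35, n=114, method="pf", **self.CROSS)
        assert z == pytest.approx(4.754090315108861, abs=1e-9)

    def test_z_grows_with_n(self):
        zs = [
            abs(compare_dependent_correlations(0.25, -0.35, n=n, **self.CROSS)[0])
            for n in (30, 60, 120, 240)
        ]
        assert all(a < b for a, b in zip(zs, zs[1:]))

    def test_non_psd_matrix_rejected(self):
        with pytest.raises(ValueError, match="positive semidefinite"):
            compare_dependent_correlations(0.9, -0.9, 0.9, 0.9, 0.9, 0.9, 100)


class TestMinDetectableR:
    def test_published_sample_size(self):
        assert round(min_detectable_r(114), 2) == 0.26

    def test_small_sample_hand_value(self):
        # tanh((1.959964 + 0.841621)/sqrt(27))
        assert min_detectable_r(30) == pytest.approx(math.tanh(2.8015855 / math.sqrt(27)), abs=1e-4)

    def test_vanishes_for_large_n(self):
        assert min_detectable_r(10_000_000) < 0.001
        with pytest.raises(ValueError):
            min_detectable_r(3)


class TestRecoveryReport:
    def test_oracle_fits_recover_exactly(self):
        truth = pd.DataFrame(
            {"agent_id": ["a", "b", "c", "d"], "omega_random": [0.1, 0.4, 0.6, 0.9]}
        )
        fitted = pd.DataFrame(
            {"participant_id": ["a", "b", "c", "d"], "omega": [0.1, 0.4, 0.6, 0.9]}
        )
        rep = recovery_report(truth, fitted, param_cols=[("omega_random", "omega")])
        row = rep.parameter_stats.loc["omega_random"]
        assert row["r"] == pytest.approx(1.0)
        assert row["bias"] == pytest.approx(0.0, abs=1e-12)
        assert row["rmse"] == pytest.approx(0.0, abs=1e-12)

    def test_missing_agent_rejected(self):
        truth = pd.DataFrame({"agent_id": ["a", "b"], "omega_random": [0.1, 0.9]})
        fitted = pd.DataFrame({"participant_id": ["a"], "omega": [0.2]})
        with pytest.raises(ValueError, match="missing"):
            recovery_report(truth, fitted, param_cols=[("omega_random", "omega")])

    def test_confusion_matrix_counts(self):
        winners = pd.DataFrame(
            {
                "participant_id": list("abcd"),
                "generating_model": ["td0", "td0", "mb", "mb"],
                "selected_model": ["td0", "mb", "mb", "mb"],
            }
        )
        truth = pd.DataFrame({"agent_id": list("abcd"), "x": [1.0, 2, 3, 4]})
        fitted = pd.DataFrame({"participant_id": list("abcd"), "x": [1.0, 2, 3, 4]})
        rep = recovery_report(truth, fitted, winners=winners)
        assert rep.confusion.loc["td0", "td0"] == 1
        assert rep.confusion.loc["mb", "mb"] == 2
        assert rep.confusion.sum(axis=1).tolist() == [2, 2]
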