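import math

import numpy as np
import pandas as pd
import pytest

from imt.stats import (
    bonferroni_threshold,
    correlation_battery,
    cronbach_alpha,
    dependent_corr_diff,
    paired_ttest,
    partial_corr,
    rm_anova,
    tukey_posthoc,
)


def make_long(values: dict, groups: dict) -> pd.DataFrame:
    """values: subject -> {(control, valence): y}; groups: subject -> label."""
    rows = []
    for sid, cells in values.items():
        for (c, v), y in cells.items():
            rows.append(
                {"subject_id": sid, "group": groups[sid], "control": c, "valence": v, "y": y}
            )
    return pd.DataFrame(rows)


def random_long(n, rng, groups=("HC", "MDD", "ANX")):
    rows = []
    for i in range(n):
        for c in ("extrinsic", "intrinsic"):
            for v in ("win", "loss"):
                rows.append(
                    {
                        "subject_id": f"S{i}",
                        "group": groups[i % len(groups)] if groups else None,
                        "control": c,
                        "valence": v,
                        "y": rng.standard_normal(),
                    }
                )
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_balanced_toy_matches_hand_ss_partition(self):
        """4 subjects, 2 groups, one 2-level within factor: every F matches an
        explicit sums-of-squares partition computed in the test."""
        # subjects s1,s2 in group A; s3,s4 in group B; factor control e/i
        y = {
            ("s1", "e"): 4.0, ("s1", "i"): 2.0,
            ("s2", "e"): 6.0, ("s2", "i"): 2.0,
            ("s3", "e"): 5.0, ("s3", "i"): 5.0,
            ("s4", "e"): 7.0, ("s4", "i"): 5.0,
        }
        grp = {"s1": "A", "s2": "A", "s3": "B", "s4": "B"}
        rows = [
            {"subject_id": s, "group": grp[s], "control": c, "valence": "win", "y": v}
            for (s, c), v in y.items()
        ]
        # duplicate valence level so the 2x2 crossing is complete but inert
        rows += [dict(r, valence="loss") for r in rows]
        table = pd.DataFrame(rows)
        res = rm_anova(table, "y", within=["control", "valence"], between="group")
        res = res.set_index("effect")

        # hand partition (balanced, so all SS types coincide)
        subj_means = {s: (y[(s, "e")] + y[(s, "i")]) / 2 for s in grp}
        grand = np.mean(list(subj_means.values()))
        ga = np.mean([subj_means["s1"], subj_means["s2"]])
        gb = np.mean([subj_means["s3"], subj_means["s4"]])
        ss_group = 2 * 2 * ((ga - grand) ** 2 + (gb - grand) ** 2)
        ss_subj = 2 * sum((subj_means[s] - (ga if grp[s] == "A" else gb)) ** 2 for s in grp)
        ms_group = ss_group / 1
        ms_subj_err = ss_subj / 2
        F_group = ms_group / ms_subj_err
        assert res.loc["group", "F"] == pytest.approx(F_group, abs=1e-9)
        assert res.loc["group", "df1"] == 1 and res.loc["group", "df2"] == 2

        # within effect via contrast d = e - i
        d = {s: y[(s, "e")] - y[(s, "i")] for s in grp}
        da = np.mean([d["s1"], d["s2"]])
        db = np.mean([d["s3"], d["s4"]])
        dbar = (da + db) / 2
        ss_err = sum((d[s] - (da if grp[s] == "A" else db)) ** 2 for s in grp)
        F_control = (4 * dbar**2 / 2) / (ss_err / 2 / 2)  # scale-free ratio
        assert res.loc["control", "F"] == pytest.approx(F_control, abs=1e-9)
        F_interaction = (da - db) ** 2 / (ss_err / 2)
        assert res.loc["group:control", "F"] == pytest.approx(F_interaction, abs=1e-9)

    def test_within_only_matches_statsmodels_anovarm(self):
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(0)
        df = random_long(14, rng)
        mine = rm_anova(df, "y", within=["control", "valence"]).set_index("effect")
        ref = AnovaRM(df, "y", "subject_id", within=["control", "valence"]).fit().anova_table
        for effect in ["control", "valence", "control:valence"]:
            assert mine.loc[effect, "F"] == pytest.approx(ref.loc[effect, "F Value"], abs=1e-9)
            assert mine.loc[effect, "p"] == pytest.approx(ref.loc[effect, "Pr > F"], abs=1e-9)

    def test_error_dfs_match_design_sizes(self):
        rng = np.random.default_rng(1)
        df = random_long(181, rng)  # 3 groups
        res = rm_anova(df, "y", within=["control", "valence"], between="group")
        assert (res["df2"] == 178).all()
        df2 = random_long(258, rng)
        res2 = rm_anova(df2, "y", within=["control", "valence"])
        assert (res2["df2"] == 257).all()

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        df = random_long(20, rng)
        a = rm_anova(df, "y", within=["control", "valence"], between="group")
        df["y"] = 3.7 * df["y"] - 11.0
        b = rm_anova(df, "y", within=["control", "valence"], between="group")
        assert np.allclose(a["F"], b["F"], atol=1e-9)
        assert ((a["p"] >= 0) & (a["p"] <= 1)).all()

    def test_missing_cell_names_subject(self):
        rng = np.random.default_rng(3)
        df = random_long(6, rng)
        df = df[~((df.subject_id == "S2") & (df.control == "intrinsic") & (df.valence == "loss"))]
        with pytest.raises(ValueError, match="S2"):
            rm_anova(df, "y", within=["control", "valence"], between="group")

    def test_small_group_rejected(self):
        rng = np.random.default_rng(4)
        df = random_long(4, rng, groups=("A", "A", "A", "B"))
        with pytest.raises(ValueError, match="2 subjects"):
            rm_anova(df, "y", within=["control"], between="group")


class TestTukey:
    def test_identical_groups_p_near_one(self):
        # identical group means with within-group spread
        df = pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(12)],
                "group": ["A", "B", "C"] * 4,
                "y": [1.0, 1.0, 1.0, 2.0, 2.0, 2.0, 3.0, 3.0, 3.0, 4.0, 4.0, 4.0],
            }
        )
        res = tukey_posthoc(df, "y", "group")
        assert (res["p_adj"] > 0.999).all()

    def test_shifted_group_significant(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(30)],
                "group": ["A", "B", "C"] * 10,
                "y": rng.standard_normal(30),
            }
        )
        df.loc[df.group == "C", "y"] += 10.0
        res = tukey_posthoc(df, "y", "group").set_index("contrast")
        assert res.loc["A - C", "p_adj"] < 1e-6
        assert res.loc["B - C", "p_adj"] < 1e-6
        assert res.loc["A - B", "p_adj"] > 0.05

    def test_matches_statsmodels_tukeyhsd(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(2)
        y = rng.standard_normal(15) + np.repeat([0.0, 0.5, 1.0], 5)
        g = np.repeat(["a", "b", "c"], 5)
        df = pd.DataFrame({"subject_id": [f"S{i}" for i in range(15)], "group": g, "y": y})
        mine = tukey_posthoc(df, "y", "group")
        ref = pairwise_tukeyhsd(y, g)
        assert np.allclose(np.sort(mine["p_adj"]), np.sort(ref.pvalues), atol=1e-6)

    def test_single_level_rejected(self):
        df = pd.DataFrame({"subject_id": ["a", "b"], "group": ["A", "A"], "y": [1.0, 2.0]})
        with pytest.raises(ValueError):
            tukey_posthoc(df, "y", "group")


class TestPartialCorr:
    def test_no_covariates_equals_pearson(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal(30), rng.standard_normal(30)
        res = partial_corr(x, y)
        from scipy.stats import pearsonr

        r_ref, p_ref = pearsonr(x, y)
        assert res["r"] == pytest.approx(r_ref, abs=1e-12)
        assert res["p"] == pytest.approx(p_ref, abs=1e-10)

    def test_identity_gives_r_one(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(25)
        z = rng.standard_normal(25)
        res = partial_corr(x, x.copy(), z)
        assert res["r"] == pytest.approx(1.0, abs=1e-12)

    def test_matches_residualization_oracle(self):
        """Two-stage residualization computed with an independent code path
        (explicit normal-equation solve) agrees to 1e-12."""
        rng = np.random.default_rng(2)
        n = 20
        Z = rng.standard_normal((n, 3))
        x = Z @ [0.5, -0.2, 0.1] + rng.standard_normal(n)
        y = Z @ [-0.3, 0.4, 0.2] + 0.5 * x + rng.standard_normal(n)
        res = partial_corr(x, y, Z)
        Za = np.column_stack([np.ones(n), Z])
        rx = x - Za @ np.linalg.solve(Za.T @ Za, Za.T @ x)
        ry = y - Za @ np.linalg.solve(Za.T @ Za, Za.T @ y)
        r_oracle = (rx @ ry) / math.sqrt((rx @ rx) * (ry @ ry))
        assert res["r"] == pytest.approx(r_oracle, abs=1e-12)
        assert res["df"] == n - 2 - 3

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        n = 40
        df = pd.DataFrame(
            {
                "x": rng.standard_normal(n),
                "y": rng.standard_normal(n),
                "c1": rng.standard_normal(n),
                "c2": rng.standard_normal(n),
            }
        )
        mine = partial_corr(df["x"], df["y"], df[["c1", "c2"]])
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
        assert mine["r"] == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert mine["p"] == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-9)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            partial_corr(np.ones(10), np.arange(10.0))


class TestDependentCorrDiff:
    def test_equal_correlations_give_zero(self):
        res = dependent_corr_diff(0.4, 0.4, 0.3, 100)
        assert res["Z"] == 0.0
        assert res["p"] == pytest.approx(0.5)

    def test_antisymmetry(self):
        a = dependent_corr_diff(0.5, 0.2, 0.3, 100)
        b = dependent_corr_diff(0.2, 0.5, 0.3, 100)
        assert a["Z"] == pytest.approx(-b["Z"], abs=1e-12)

    def test_matches_published_formula_reimplementation(self):
        r_xy, r_xz, r_yz, n = 0.5, 0.2, 0.3, 100
        res = dependent_corr_diff(r_xy, r_xz, r_yz, n)
        # independent re-derivation of the Meng-Rosenthal-Rubin statistic
        rbar2 = (r_xy**2 + r_xz**2) / 2
        f = min((1 - r_yz) / (2 * (1 - rbar2)), 1.0)
        h = (1 - f * rbar2) / (1 - rbar2)
        z = (np.arctanh(r_xy) - np.arctanh(r_xz)) * math.sqrt(
            (n - 3) / (2 * (1 - r_yz) * h)
        )
        assert res["Z"] == pytest.approx(z, abs=1e-9)

    def test_one_vs_two_sided(self):
        one = dependent_corr_diff(0.5, 0.2, 0.3, 100)
        two = dependent_corr_diff(0.5, 0.2, 0.3, 100, two_sided=True)
        assert two["p"] == pytest.approx(min(2 * one["p"], 1.0))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            dependent_corr_diff(1.0, 0.2, 0.3, 100)
        with pytest.raises(ValueError):
            dependent_corr_diff(0.5, 0.2, 0.3, 3)


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha,n,expected", [(0.05, 4, 0.0125), (0.05, 1, 0.05), (0.05, 10, 0.005)]
    )
    def test_examples(self, alpha, n, expected):
        assert bonferroni_threshold(alpha, n) == pytest.approx(expected)

    def test_validation(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.0, 4)
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


class TestCronbach:
    def test_identical_items_alpha_one(self):
        col = np.random.default_rng(0).standard_normal(10)
        M = np.column_stack([col] * 4)
        assert cronbach_alpha(M) == pytest.approx(1.0)

    def test_independent_items_alpha_near_zero(self):
        rng = np.random.default_rng(1)
        M = rng.standard_normal((5000, 4))
        assert abs(cronbach_alpha(M)) < 0.1

    def test_toy_matches_hand_variance_ratio(self):
        M = np.array(
            [
                [2.0, 3.0, 3.0, 4.0],
                [4.0, 4.0, 5.0, 5.0],
                [1.0, 2.0, 2.0, 3.0],
                [3.0, 3.0, 4.0, 4.0],
                [5.0, 5.0, 5.0, 6.0],
                [2.0, 2.0, 3.0, 3.0],
            ]
        )
        k = 4
        hand = k / (k - 1) * (1 - M.var(axis=0, ddof=1).sum() / M.sum(axis=1).var(ddof=1))
        assert cronbach_alpha(M) == pytest.approx(hand, abs=1e-12)
        pingouin = pytest.importorskip("pingouin")
        ref = pingouin.cronbach_alpha(pd.DataFrame(M))[0]
        assert cronbach_alpha(M) == pytest.approx(ref, abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            cronbach_alpha(np.ones((5, 3)))


class TestPairedTtest:
    def test_identical_sessions(self):
        x = np.arange(10.0)
        res = paired_ttest(x, x.copy())
        assert res == {"t": 0.0, "df": 9, "p": 1.0}

    def test_constant_shift_infinite_t(self):
        x = np.arange(10.0)
        res = paired_ttest(x, x + 2.0)
        assert math.isinf(res["t"]) and res["t"] > 0
        assert res["p"] == 0.0

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(5)
        a = rng.standard_normal(10)
        b = a + 0.3 + 0.5 * rng.standard_normal(10)
        res = paired_ttest(a, b)
        d = b - a
        t_hand = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        from scipy.stats import t as t_dist

        p_hand = 2 * t_dist.sf(abs(t_hand), len(d) - 1)
        assert res["t"] == pytest.approx(t_hand, abs=1e-12)
        assert res["p"] == pytest.approx(p_hand, abs=1e-12)


class TestCorrelationBattery:
    def test_structure_and_bonferroni_flags(self):
        rng = np.random.default_rng(6)
        n = 40
        subjects = pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(n)],
                "group": ["HC"] * n,
                "age": rng.uniform(18, 65, n),
                "sex": rng.choice(["F", "M"], n),
                "medication": rng.choice([True, False], n),
                "teps_anticipatory": rng.normal(45, 7, n),
            }
        )
        est = pd.DataFrame(
            [
                {"subject_id": f"S{i}", "condition": cond, "bias": rng.normal()}
                for i in range(n)
                for cond in ("extrinsic-win", "extrinsic-loss", "intrinsic-win", "intrinsic-loss")
            ]
        )
        res = correlation_battery(est, subjects, "bias", ["teps_anticipatory"])
        assert len(res) == 4
        assert np.allclose(res["bonferroni_alpha"], 0.0125)
        assert (res["bonferroni_pass"] == (res["p"] < 0.0125)).all()
        assert ((res["p"] >= 0) & (res["p"] <= 1)).all()
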