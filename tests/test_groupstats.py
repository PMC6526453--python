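"""Group-level statistics against hand-computed and independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pendiff import (
    DataError, correlations, drift_sign_convert, mixed_anova,
    pairwise_bonferroni, table2_summary, ttest_between,
)


def _values(data):
    """data: {(subject, group): (value_cond1, value_cond2)}"""
    rows = []
    for (subject, group), (v1, v2) in data.items():
        rows.append({"subject": subject, "group": group, "condition": "c1", "value": v1})
        rows.append({"subject": subject, "group": group, "condition": "c2", "value": v2})
    return pd.DataFrame(rows)


FIXTURE = _values({
    ("s1", "A"): (1, 3), ("s2", "A"): (3, 4),
    ("s3", "B"): (2, 6), ("s4", "B"): (4, 8),
})


def brute_force_mixed_ss(df):
    """Independent sums-of-squares decomposition by explicit enumeration."""
    y = df["value"].to_numpy(float)
    grand = y.mean()
    subjects = sorted(df["subject"].unique())
    conds = sorted(df["condition"].unique())
    groups = {s: df[df["subject"] == s]["group"].iloc[0] for s in subjects}
    glabels = sorted(set(groups.values()))
    cell = lambda g, c: df[(df["group"] == g) & (df["condition"] == c)]["value"].mean()
    gmean = lambda g: df[df["group"] == g]["value"].mean()
    cmean = lambda c: df[df["condition"] == c]["value"].mean()
    smean = lambda s: df[df["subject"] == s]["value"].mean()

    ss_group = sum(
        len(conds) * sum(1 for s in subjects if groups[s] == g) * (gmean(g) - grand) ** 2
        for g in glabels
    )
    ss_subj = sum(
        len(conds) * (smean(s) - gmean(groups[s])) ** 2 for s in subjects
    )
    ss_cond = sum(len(subjects) * (cmean(c) - grand) ** 2 for c in conds)
    ss_inter = sum(
        sum(1 for s in subjects if groups[s] == g)
        * (cell(g, c) - gmean(g) - cmean(c) + grand) ** 2
        for g, c in itertools.product(glabels, conds)
    )
    ss_total = ((y - grand) ** 2).sum()
    ss_err = ss_total - ss_group - ss_subj - ss_cond - ss_inter
    return ss_group, ss_subj, ss_cond, ss_inter, ss_err


class TestMixedAnova:
    def test_hand_computed_fixture(self):
        res = {r.effect: r for r in mixed_anova(FIXTURE)}
        assert res["group"].value == pytest.approx(3.24, abs=1e-10)
        assert res["condition"].value == pytest.approx(121.0, abs=1e-10)
        assert res["group x condition"].value == pytest.approx(25.0, abs=1e-10)
        assert res["group"].df == (1.0, 2.0)
        assert res["condition"].df == (1.0, 2.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("n_per_group", [2, 3, 4])
    def test_matches_brute_force_decomposition(self, seed, n_per_group):
        rng = np.random.default_rng(seed)
        data = {}
        for g in ("A", "B"):
            for i in range(n_per_group):
                data[(f"{g}{i}", g)] = tuple(rng.normal(size=2))
        df = _values(data)
        ssg, sss, ssc, ssi, sse = brute_force_mixed_ss(df)
        res = {r.effect: r for r in mixed_anova(df)}
        n_subj = 2 * n_per_group
        assert res["group"].value == pytest.approx((ssg / 1) / (sss / (n_subj - 2)), abs=1e-10)
        assert res["condition"].value == pytest.approx((ssc / 1) / (sse / (n_subj - 2)), abs=1e-10)
        assert res["group x condition"].value == pytest.approx(
            (ssi / 1) / (sse / (n_subj - 2)), abs=1e-10
        )

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(42)
        data = {(f"{g}{i}", g): tuple(rng.normal(size=2))
                for g in ("A", "B") for i in range(5)}
        df = _values(data)
        ours = {r.effect: r for r in mixed_anova(df)}
        theirs = pg.mixed_anova(
            data=df, dv="value", within="condition", between="group", subject="subject"
        ).set_index("Source")
        assert ours["group"].value == pytest.approx(theirs.loc["group", "F"], rel=1e-8)
        assert ours["condition"].value == pytest.approx(
            theirs.loc["condition", "F"], rel=1e-8
        )
        assert ours["group x condition"].value == pytest.approx(
            theirs.loc["Interaction", "F"], rel=1e-8
        )

    def test_constant_data_gives_zero_F(self):
        df = _values({("s1", "A"): (2, 2), ("s2", "A"): (2, 2),
                      ("s3", "B"): (2, 2), ("s4", "B"): (2, 2)})
        for r in mixed_anova(df):
            assert r.value == 0.0

    def test_condition_relabeling_leaves_group_effect(self):
        swapped = FIXTURE.copy()
        swapped["condition"] = swapped["condition"].map({"c1": "c2", "c2": "c1"})
        f1 = {r.effect: r.value for r in mixed_anova(FIXTURE)}
        f2 = {r.effect: r.value for r in mixed_anova(swapped)}
        assert f1["group"] == pytest.approx(f2["group"], abs=1e-12)

    def test_missing_cell_rejected(self):
        df = FIXTURE.iloc[:-1]
        with pytest.raises(DataError):
            mixed_anova(df)


class TestTTests:
    def test_known_value(self):
        res = ttest_between([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
        assert res.value == pytest.approx(-3.6742346, abs=1e-6)
        assert res.df == (4.0,)

    def test_matches_scipy(self, rng):
        from scipy.stats import ttest_ind

        x = rng.normal(size=12)
        g = ["a"] * 5 + ["b"] * 7
        res = ttest_between(x, g)
        ref = ttest_ind(x[:5], x[5:], equal_var=True)
        assert res.value == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p_raw == pytest.approx(ref.pvalue, rel=1e-10)

    def test_sign_flips_with_group_order(self):
        a = ttest_between([1, 2, 3, 7, 8, 9], ["a"] * 3 + ["b"] * 3)
        b = ttest_between([7, 8, 9, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert a.value == pytest.approx(-b.value)

    def test_equal_means_zero(self):
        res = ttest_between([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert res.value == 0.0 and res.eta_squared == 0.0

    def test_zero_variance_rejected(self):
        with pytest.raises(DataError):
            ttest_between([1, 1, 1, 1], ["a", "a", "b", "b"])


class TestPairwise:
    def test_family_of_one_unadjusted(self):
        res = pairwise_bonferroni(FIXTURE, [{"kind": "between", "condition": "c1"}])
        assert res[0].p_adjusted == pytest.approx(res[0].p_raw)

    def test_adjustment_caps_at_one(self):
        fam = [{"kind": "between", "condition": "c1"}] * 4
        res = pairwise_bonferroni(FIXTURE, fam)
        for r in res:
            assert r.p_adjusted == pytest.approx(min(1.0, r.p_raw * 4))
            assert r.p_adjusted <= 1.0

    def test_within_group_paired(self):
        res = pairwise_bonferroni(FIXTURE, [{"kind": "within", "group": "A"}])
        # group A differences c1-c2: (-2, -1): mean -1.5, sd 1/sqrt(2)
        assert res[0].value == pytest.approx(-3.0, abs=1e-10)
        assert res[0].df == (1.0,)


class TestDriftSignConversion:
    def test_nonword_flipped_word_unchanged(self):
        df = pd.DataFrame({"v_word": [1.472], "v_nonword": [-1.944]})
        out = drift_sign_convert(df)
        assert out["v_nonword"].iloc[0] == pytest.approx(1.944)
        assert out["v_word"].iloc[0] == pytest.approx(1.472)

    def test_involution(self):
        df = pd.DataFrame({"v_word": [1.0], "v_nonword": [-2.0]})
        twice = drift_sign_convert(drift_sign_convert(df))
        pd.testing.assert_frame_equal(twice, df)


class TestCorrelations:
    def test_uncorrelated_covariate_leaves_r(self):
        rng = np.random.default_rng(5)
        n = 400
        x = rng.normal(size=n)
        y = 0.6 * x + 0.8 * rng.normal(size=n)
        g = ["a", "b"] * (n // 2)  # balanced, independent of x and y
        res = correlations(x, y, g)
        assert res.r_partial == pytest.approx(res.r_bivariate, abs=0.02)

    def test_matches_pingouin_partial(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(17)
        n = 40
        g = np.array([0] * 20 + [1] * 20)
        x = rng.normal(size=n) + 0.8 * g
        y = 0.5 * x + rng.normal(size=n) + 0.5 * g
        res = correlations(x, y, ["a" if v == 0 else "b" for v in g])
        df = pd.DataFrame({"x": x, "y": y, "g": g})
        ref = pg.partial_corr(data=df, x="x", y="y", covar="g")
        assert res.r_partial == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DataError):
            correlations([1, 1, 1, 1], [1, 2, 3, 4], ["a", "a", "b", "b"])
        with pytest.raises(DataError):
            correlations([1, 2, 3], [1, 2, 3], ["a", "a", "b"])


class TestTable2Summary:
    def test_single_participant_cells(self):
        trials = pd.DataFrame(
            {
                "participant_id": ["P1"] * 2,
                "condition": ["word", "word"],
                "is_reference": [False, False],
                "response": ["word", "nonword"],
                "rt_s": [0.6, 1.0],
            }
        )
        out = table2_summary(trials, {"P1": "younger"})
        row = out[(out["group"] == "younger") & (out["condition"] == "word")].iloc[0]
        assert row["accuracy"] == pytest.approx(0.5)
        assert row["rt_correct_s"] == pytest.approx(0.6)
        assert row["rt_error_s"] == pytest.approx(1.0)

    def test_zero_error_participant_excluded_from_error_cell(self):
        trials = pd.DataFrame(
            {
                "participant_id": ["P1", "P1", "P2", "P2"],
                "condition": ["word"] * 4,
                "is_reference": [False] * 4,
                "response": ["word", "word", "word", "nonword"],
                "rt_s": [0.5, 0.7, 0.6, 1.2],
            }
        )
        out = table2_summary(trials, {"P1": "g", "P2": "g"})
        row = out.iloc[0]
        # only P2 contributes an error RT
        assert row["rt_error_s"] == pytest.approx(1.2)
        assert 0.0 <= row["accuracy"] <= 1.0

    def test_missing_group_label_rejected(self):
        trials = pd.DataFrame(
            {
                "participant_id": ["P1"],
                "condition": ["word"],
                "is_reference": [False],
                "response": ["word"],
                "rt_s": [0.5],
            }
        )
        with pytest.raises(DataError):
            table2_summary(trials, {"other": "g"})
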