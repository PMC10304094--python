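"""Grade-group comparison: screening tests, Welch ANOVA, Games-Howell,
compact letter display, descriptives."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fnti.compare import (
    GroupDataError,
    boxplot_data,
    compact_letters,
    compare_groups,
    describe_groups,
    games_howell,
    levene,
    shapiro_wilk,
    welch_anova,
)
from fnti.synthetic import DEFAULT_GRADE_PARAMS, SyntheticCohortConfig, generate_cohort

STUDY_PARAMS = DEFAULT_GRADE_PARAMS


def simulated_groups(rng, params=STUDY_PARAMS):
    return {g: rng.normal(m, s, n) for g, (m, s, n) in params.items()}


class TestShapiroWilk:
    def test_constant_sample_rejected(self):
        with pytest.raises(GroupDataError):
            shapiro_wilk([2.0] * 10)

    def test_out_of_range_n_rejected(self):
        with pytest.raises(GroupDataError):
            shapiro_wilk([1.0, 2.0])

    def test_bimodal_sample_detected(self):
        rng = np.random.default_rng(8)
        x = np.concatenate([rng.normal(0, 0.1, 25), rng.normal(5, 0.1, 25)])
        _, p = shapiro_wilk(x)
        assert p < 0.01

    def test_calibration_on_normal_samples(self):
        rng = np.random.default_rng(19)
        rejections = sum(
            shapiro_wilk(rng.normal(0.809, 0.024, 19))[1] < 0.05 for _ in range(1000)
        )
        assert abs(rejections / 1000 - 0.05) <= 0.02


class TestLevene:
    def test_identical_value_sets(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        res = levene({"a": vals, "b": vals})
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert (res.df1, res.df2) == (1, 6)

    def test_power_against_unequal_spread(self):
        rng = np.random.default_rng(24)
        hits = sum(
            levene({"lo": rng.normal(0, 0.02, 24), "hi": rng.normal(0, 0.07, 24)}).p_value < 0.05
            for _ in range(500)
        )
        assert hits / 500 >= 0.90

    def test_type_one_calibration(self):
        rng = np.random.default_rng(25)
        hits = sum(
            levene({"a": rng.normal(0, 1, 24), "b": rng.normal(0, 1, 24)}).p_value < 0.05
            for _ in range(1000)
        )
        assert abs(hits / 1000 - 0.05) <= 0.02

    def test_median_centred_variant(self):
        rng = np.random.default_rng(26)
        g = {"a": rng.normal(0, 1, 30), "b": rng.normal(0, 3, 30)}
        classic = levene(g, center="mean")
        bf = levene(g, center="median")
        assert classic.p_value < 0.05 and bf.p_value < 0.05
        assert classic.statistic != bf.statistic


class TestWelchAnova:
    def test_identical_sample_means_give_zero_f(self):
        base = np.array([-1.0, 0.0, 1.0])
        res = welch_anova({"a": 5 + base, "b": 5 + 2 * base, "c": 5 + 0.5 * base})
        assert res.f_stat == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_two_groups_equal_welch_t_squared(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 20), rng.normal(0.5, 2, 15)
        res = welch_anova({"a": a, "b": b})
        t = stats.ttest_ind(a, b, equal_var=False)
        assert res.f_stat == pytest.approx(t.statistic**2, rel=1e-9)
        assert res.p_value == pytest.approx(t.pvalue, rel=1e-9)

    def test_study_design_effect_is_enormous(self):
        rng = np.random.default_rng(3)
        res = welch_anova(simulated_groups(rng))
        assert res.df1 == 4
        assert res.p_value < 1e-6

    def test_reduces_to_classic_anova_when_homoscedastic(self):
        rng = np.random.default_rng(4)
        groups = {g: rng.normal(mu, 1.0, 80) for g, mu in zip("abcd", [0, 0.2, 0.4, 0.6])}
        welch = welch_anova(groups)
        classic_f = stats.f_oneway(*groups.values()).statistic
        assert welch.f_stat == pytest.approx(classic_f, rel=0.02)

    def test_zero_variance_group_named(self):
        with pytest.raises(GroupDataError, match="b"):
            welch_anova({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})

    def test_matches_pingouin_cross_check(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        groups = simulated_groups(rng)
        long = pd.DataFrame(
            {
                "g": np.concatenate([[g] * len(v) for g, v in groups.items()]),
                "v": np.concatenate(list(groups.values())),
            }
        )
        ref = pg.welch_anova(long, "v", "g")
        res = welch_anova(groups)
        assert res.f_stat == pytest.approx(ref["F"][0], rel=1e-9)
        assert res.df2 == pytest.approx(ref["ddof2"][0], rel=1e-9)
        assert res.p_value == pytest.approx(ref["p_unc"][0], rel=1e-9)


class TestGamesHowell:
    def test_two_groups_equal_welch_t(self):
        """Studentized range with k=2 at |t|*sqrt(2) is the two-sided t p."""
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 20), rng.normal(0.7, 2, 15)
        gh = games_howell({"a": a, "b": b})
        t = stats.ttest_ind(a, b, equal_var=False)
        assert gh["p_adj"][0] == pytest.approx(t.pvalue, abs=1e-6)

    def test_identical_groups_not_significant(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        gh = games_howell({"a": vals, "b": vals, "c": vals})
        assert np.allclose(gh["p_adj"], 1.0)
        assert not gh["significant"].any()

    def test_strong_contrasts_detected_in_study_design(self):
        """The printed group moments put A-C, A-D, A-E and B-D far apart;
        those contrasts should be flagged in essentially every replicate."""
        rng = np.random.default_rng(2024)
        strong = {("A", "C"), ("A", "D"), ("A", "E"), ("B", "D")}
        reps, hits = 200, 0
        for _ in range(reps):
            gh = games_howell(simulated_groups(rng))
            sig = {
                (r.group_i, r.group_j) for r in gh.itertuples() if r.significant
            }
            if strong <= sig:
                hits += 1
        assert hits / reps >= 0.95

    def test_p_monotone_in_mean_separation(self):
        rng = np.random.default_rng(7)
        base = rng.normal(0, 1, 25)
        other = rng.normal(0, 1.5, 30)
        ps = [
            games_howell({"a": base, "b": other + shift})["p_adj"][0]
            for shift in np.linspace(0.0, 2.0, 9)
        ]
        assert all(p2 <= p1 + 1e-12 for p1, p2 in zip(ps, ps[1:]))

    def test_matches_pingouin_cross_check(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        groups = simulated_groups(rng)
        long = pd.DataFrame(
            {
                "g": np.concatenate([[g] * len(v) for g, v in groups.items()]),
                "v": np.concatenate(list(groups.values())),
            }
        )
        ref = pg.pairwise_gameshowell(long, "v", "g").set_index(["A", "B"])
        gh = games_howell(groups).set_index(["group_i", "group_j"])
        for pair in gh.index:
            assert gh.loc[pair, "p_adj"] == pytest.approx(ref.loc[pair, "pval"], abs=1e-9)
            assert gh.loc[pair, "df"] == pytest.approx(ref.loc[pair, "df"], rel=1e-9)


class TestCompactLetters:
    MEANS = {"A": 0.809, "B": 0.835, "C": 0.868, "D": 0.903, "E": 0.923}

    def test_published_superscript_pattern(self):
        sig = {("A", "C"), ("A", "D"), ("A", "E"), ("B", "D"), ("B", "E"), ("C", "E")}
        letters = compact_letters(self.MEANS, sig)
        assert letters == {"A": "a", "B": "ab", "C": "bc", "D": "cd", "E": "d"}

    def test_no_significant_pairs_share_one_letter(self):
        assert set(compact_letters(self.MEANS, set()).values()) == {"a"}

    def test_all_pairs_distinct_letters(self):
        means = {"x": 1.0, "y": 2.0, "z": 3.0}
        sig = {("x", "y"), ("x", "z"), ("y", "z")}
        assert compact_letters(means, sig) == {"x": "a", "y": "b", "z": "c"}

    def test_biconditional_on_random_patterns(self):
        """Two groups share a letter iff their pair is not significant —
        checked over 1000 random (possibly non-transitive) patterns."""
        rng = np.random.default_rng(1000)
        for _ in range(1000):
            k = rng.integers(2, 7)
            names = [f"g{i}" for i in range(k)]
            means = {g: float(rng.normal()) for g in names}
            sig = {
                frozenset(p)
                for p in itertools.combinations(names, 2)
                if rng.random() < 0.4
            }
            letters = compact_letters(means, sig)
            for gi, gj in itertools.combinations(names, 2):
                share = bool(set(letters[gi]) & set(letters[gj]))
                assert share == (frozenset((gi, gj)) not in sig), (letters, sig)

    def test_unknown_group_in_pattern_rejected(self):
        with pytest.raises(GroupDataError):
            compact_letters({"a": 1.0, "b": 2.0}, {("a", "zzz")})


class TestDescribeGroups:
    def test_hand_computed_ci(self):
        desc = describe_groups({"g": [1.0, 2.0, 3.0], "h": [4.0, 5.0, 6.0]})
        row = desc.loc["g"]
        assert row["mean"] == pytest.approx(2.0)
        assert row["sd"] == pytest.approx(1.0)
        assert row["ci_lower"] == pytest.approx(2 - 2.484, abs=1e-3)
        assert row["ci_upper"] == pytest.approx(2 + 2.484, abs=1e-3)
        assert (row["min"], row["max"]) == (1.0, 3.0)

    def test_constant_group_collapses_ci(self):
        desc = describe_groups({"g": [5.0, 5.0, 5.0], "h": [1.0, 2.0, 3.0]})
        row = desc.loc["g"]
        assert row["sd"] == 0 and row["ci_lower"] == row["ci_upper"] == 5.0

    def test_generator_mean_recovered_at_large_n(self):
        cfg = SyntheticCohortConfig(
            grade_params={"A": (0.809, 0.024, 10_000)}, seed=77
        )
        vals = generate_cohort(cfg)["true_fnti"].to_numpy()
        desc = describe_groups({"A": vals, "pad": [0.0, 1.0, 2.0]})
        assert desc.loc["A", "mean"] == pytest.approx(0.809, abs=0.005)


class TestCompareGroups:
    def test_full_report_structure(self):
        truth = generate_cohort(SyntheticCohortConfig(seed=5))
        groups = {g: v["true_fnti"].to_numpy() for g, v in truth.groupby("grade")}
        rep = compare_groups(groups)
        assert len(rep.descriptives) == 5
        assert len(rep.pairwise) == 10
        assert "letters" in rep.descriptives.columns
        # letters satisfy the defining biconditional against the pairwise table
        sig = {
            frozenset((r.group_i, r.group_j)) for r in rep.pairwise.itertuples() if r.significant
        }
        letters = rep.descriptives["letters"]
        for gi, gj in itertools.combinations(letters.index, 2):
            share = bool(set(letters[gi]) & set(letters[gj]))
            assert share == (frozenset((gi, gj)) not in sig)

    def test_boxplot_export_shape(self):
        rng = np.random.default_rng(12)
        groups = {"a": rng.normal(0, 1, 40), "b": rng.normal(2, 1, 40)}
        box = boxplot_data(groups)
        assert list(box.columns) == [
            "whisker_low", "q1", "median", "q3", "whisker_high", "outliers",
        ]
        assert (box["q1"] <= box["median"]).all() and (box["median"] <= box["q3"]).all()
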