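import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from hedoseg.characterize import (
    chi_square_association,
    kruskal_wallis,
    letter_display,
    liking_with_never_tasted,
    one_way_anova,
    sdcf_pairwise,
    two_way_anova,
)


class TestLetterDisplay:
    def test_all_nonsignificant_share_one_letter(self):
        letters = letter_display(["a", "b", "c"], {})
        assert set(letters.values()) == {"a"}

    def test_all_significant_distinct_letters(self):
        p = {frozenset(pair): 0.001 for pair in itertools.combinations("abc", 2)}
        letters = letter_display(["a", "b", "c"], p)
        assert len(set(letters.values())) == 3

    @given(st.integers(min_value=0, max_value=2**15 - 1))
    def test_sharing_relation_reconstructs_significance(self, bits):
        # every 4-group significance pattern: sharing a letter iff p >= alpha
        groups = list("wxyz")
        pairs = list(itertools.combinations(groups, 2))
        p = {
            frozenset(pair): (0.001 if (bits >> i) & 1 else 0.5)
            for i, pair in enumerate(pairs)
        }
        letters = letter_display(groups, p, alpha=0.05)
        for a, b in pairs:
            share = bool(set(letters[a]) & set(letters[b]))
            assert share == (p[frozenset((a, b))] >= 0.05)


class TestOneWayAnova:
    def test_identical_groups_f_zero_shared_letter(self):
        res = one_way_anova([1, 2, 3, 1, 2, 3], list("aaabbb"))
        assert res.terms["F"].iloc[0] == 0.0
        assert set(res.letters.values()) == {"a"}

    def test_hand_computed_sums_of_squares(self):
        res = one_way_anova([0, 0, 10, 10], list("aabb"))
        assert res.terms["ss"].iloc[0] == pytest.approx(100.0)
        assert res.residual_ss == pytest.approx(0.0)

    def test_null_case_letters_shared(self, rng):
        y = np.concatenate([rng.normal(0, s, 30) for s in (1.0, 2.0, 3.0)])
        g = np.repeat(list("abc"), 30)
        res = one_way_anova(y, g)
        if res.terms["p"].iloc[0] > 0.05:
            assert set("".join(res.letters.values())) == {"a"}

    def test_matches_scipy_f_oneway(self, rng):
        y = rng.normal(50, 10, 90)
        g = rng.choice(list("abc"), 90)
        res = one_way_anova(y, g)
        F, p = stats.f_oneway(*(y[g == lvl] for lvl in "abc"))
        assert res.terms["F"].iloc[0] == pytest.approx(F)
        assert res.terms["p"].iloc[0] == pytest.approx(p)

    def test_df_bookkeeping(self, rng):
        y = rng.normal(0, 1, 47)
        g = rng.choice(list("abcd"), 47)
        assert one_way_anova(y, g).check_df()


class TestTwoWayAnova:
    def test_constant_response_all_ss_zero(self):
        a = list("xxyy") * 4
        b = list("uvuv") * 4
        res = two_way_anova([5.0] * 16, a, b)
        assert np.allclose(res.terms["ss"], 0.0)

    def test_balanced_2x2_hand_oracle(self):
        # 2 replicates per cell; classical balanced formulas
        y = np.array([1.0, 3.0, 4.0, 6.0, 5.0, 7.0, 12.0, 14.0])
        a = list("aaaabbbb")
        b = list("ccddccdd")
        res = two_way_anova(y, a, b)
        cell = np.array([[2.0, 5.0], [6.0, 13.0]])
        n_rep, grand = 2, y.mean()
        ss_a = 2 * n_rep * ((cell.mean(axis=1) - grand) ** 2).sum()
        ss_b = 2 * n_rep * ((cell.mean(axis=0) - grand) ** 2).sum()
        ss_int = n_rep * (
            (cell - cell.mean(axis=1, keepdims=True) - cell.mean(axis=0) + grand) ** 2
        ).sum()
        got = res.terms.set_index("name")["ss"]
        assert got["A"] == pytest.approx(ss_a)
        assert got["B"] == pytest.approx(ss_b)
        assert got["A:B"] == pytest.approx(ss_int)
        assert res.residual_ss == pytest.approx(8 * 0.5 * 2)  # within-cell SS

    def test_residual_df_for_cohort_shape(self, rng):
        n = 1138
        cluster = np.repeat(rng.choice(3, n, p=[0.39, 0.40, 0.21]), 4)
        conc = np.tile([38.0, 83.0, 119.0, 223.0], n)
        y = rng.normal(50, 10, 4 * n)
        res = two_way_anova(y, cluster, conc)
        assert res.residual_df == 4540
        assert res.check_df()

    def test_type3_equals_type1_on_balanced_designs(self, rng):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        for _ in range(5):
            levels_a, levels_b, reps = rng.integers(2, 4), rng.integers(2, 4), rng.integers(2, 4)
            a = np.repeat(np.arange(levels_a), levels_b * reps)
            b = np.tile(np.repeat(np.arange(levels_b), reps), levels_a)
            y = rng.normal(0, 1, levels_a * levels_b * reps)
            res = two_way_anova(y, a, b)
            df = pd.DataFrame({"y": y, "a": a, "b": b})
            t1 = sm.stats.anova_lm(smf.ols("y ~ C(a) * C(b)", df).fit(), typ=1)
            np.testing.assert_allclose(
                res.terms["ss"].to_numpy(), t1["sum_sq"].to_numpy()[:3], rtol=1e-8
            )

    def test_empty_cell_rejected_naming_cell(self):
        a = ["x", "x", "y", "y", "y"]
        b = ["u", "u", "u", "v", "v"]
        with pytest.raises(ValueError, match="empty cell"):
            two_way_anova([1.0, 2.0, 3.0, 4.0, 5.0], a, b)

    def test_letters_within_each_level_of_other_factor(self, rng):
        a = np.repeat([0, 1, 2], 40)
        b = np.tile(np.repeat([0, 1], 20), 3)
        y = rng.normal(0, 1, 120) + 10.0 * (a == 0) * (b == 0)
        res = two_way_anova(y, a, b)
        assert set(res.letters) == {0, 1}
        assert res.letters[0][0] == "a"  # boosted cell ranks first at b=0
        assert len(set(res.letters[0].values())) > 1


class TestChiSquare:
    def test_exact_independence(self):
        table = np.outer([30, 50], [20, 60, 20]) / 100.0
        table = np.round(table * 10)  # integer counts with product margins
        res = chi_square_association(pd.DataFrame(table))
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert (res.flags == "").all().all()

    def test_hand_computed_diagonal_table(self):
        res = chi_square_association(pd.DataFrame([[10, 0], [0, 10]]))
        assert res.chi2 == pytest.approx(20.0)
        assert res.df == 1
        assert res.flags.iloc[0, 0] == ">" and res.flags.iloc[1, 1] == ">"
        assert res.flags.iloc[0, 1] == "<" and res.flags.iloc[1, 0] == "<"

    def test_flag_gated_by_per_cell_significance(self):
        res = chi_square_association(pd.DataFrame([[6, 5], [5, 6]]))
        assert (res.observed > res.expected).iloc[0, 0]
        assert res.flags.iloc[0, 0] == ""

    def test_contributions_sum_to_chi2_and_match_direct_formula(self, rng):
        table = rng.integers(1, 40, size=(3, 4))
        res = chi_square_association(pd.DataFrame(table))
        O = table.astype(float)
        E = np.outer(O.sum(1), O.sum(0)) / O.sum()
        assert res.chi2 == pytest.approx(((O - E) ** 2 / E).sum())
        assert res.contributions.to_numpy().sum() == pytest.approx(res.chi2)
        np.testing.assert_allclose(res.expected.to_numpy(), E)
        chi2_scipy = stats.chi2_contingency(table, correction=False)[0]
        assert res.chi2 == pytest.approx(chi2_scipy)

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValueError):
            chi_square_association(pd.DataFrame([[1.5, 2], [3, 4]]))


class TestKruskalWallis:
    def test_identical_groups_mean_rank_center(self):
        res = kruskal_wallis([1, 2, 3] * 3, list("aaabbbccc"))
        assert np.allclose(res.mean_ranks, 5.0)  # (N+1)/2 with N=9
        assert res.H == pytest.approx(0.0)

    def test_hand_formula_two_groups(self):
        res = kruskal_wallis([1, 2, 3, 4], list("aabb"))
        assert res.H == pytest.approx(2.4)
        assert res.mean_ranks.tolist() == [1.5, 3.5]

    def test_weighted_mean_rank_invariant(self, rng):
        y = rng.normal(0, 1, 60)
        g = rng.choice(list("abc"), 60)
        res = kruskal_wallis(y, g)
        ns = pd.Series(g).value_counts()
        weighted = (res.mean_ranks * ns).sum() / ns.sum()
        assert weighted == pytest.approx((60 + 1) / 2)

    def test_matches_scipy_with_ties(self, rng):
        y = rng.integers(0, 6, 50).astype(float)
        g = rng.choice(list("abc"), 50)
        res = kruskal_wallis(y, g)
        H, p = stats.kruskal(*(y[g == lvl] for lvl in "abc"))
        assert res.H == pytest.approx(H)
        assert res.p == pytest.approx(p)

    def test_all_identical_values_warn_h_zero(self):
        res = kruskal_wallis([5, 5, 5, 5], list("aabb"))
        assert res.H == 0.0


class TestSDCF:
    def test_identical_groups_statistic_zero(self):
        res = sdcf_pairwise([1, 2, 3, 4] * 2, list("aaaabbbb"))
        row = res.pairwise.iloc[0]
        assert row["z"] == pytest.approx(0.0)
        assert row["p"] == pytest.approx(1.0, abs=1e-6)

    def test_complete_separation_smallest_attainable_p(self):
        y = [1, 2, 3, 4, 10, 11, 12, 13, 20, 21, 22, 23]
        g = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        res = sdcf_pairwise(y, g)
        # all pairs maximally separated: identical minimal asymptotic p
        assert res.pairwise["p"].nunique() == 1
        # monotone with effect size: shrink one gap, its p must not decrease
        y2 = [1, 2, 3, 4, 2, 3, 4, 5, 20, 21, 22, 23]
        res2 = sdcf_pairwise(y2, g)
        p_ab_sep = res.pairwise.set_index(["group1", "group2"]).loc[("a", "b"), "p"]
        p_ab_close = res2.pairwise.set_index(["group1", "group2"]).loc[("a", "b"), "p"]
        assert p_ab_close > p_ab_sep

    def test_symmetric_in_pair_order(self, rng):
        y = rng.normal(0, 1, 30)
        g = rng.choice(list("abc"), 30)
        res1 = sdcf_pairwise(y, g)
        idx = rng.permutation(30)
        res2 = sdcf_pairwise(y[idx], g[idx])
        m1 = {frozenset((r.group1, r.group2)): r.p for r in res1.pairwise.itertuples()}
        m2 = {frozenset((r.group1, r.group2)): r.p for r in res2.pairwise.itertuples()}
        for key in m1:
            assert m1[key] == pytest.approx(m2[key])

    def test_invariant_under_monotone_transform(self, rng):
        y = rng.normal(0, 1, 24)
        g = rng.choice(list("abc"), 24)
        res1 = sdcf_pairwise(y, g)
        res2 = sdcf_pairwise(np.exp(3 * y), g)
        np.testing.assert_allclose(
            res1.pairwise["p"].to_numpy(), res2.pairwise["p"].to_numpy()
        )

    def test_against_permutation_oracle_3x5(self, rng):
        # asymptotic p within small-n slack of the seeded max-q
        # permutation distribution
        y = np.array([3.1, 4.2, 5.0, 6.3, 7.1, 5.5, 6.8, 7.7, 8.9, 9.4,
                      8.1, 9.2, 10.3, 11.0, 12.4])
        g = ["a"] * 5 + ["b"] * 5 + ["c"] * 5
        asym = sdcf_pairwise(y, g, method="asymptotic")
        perm = sdcf_pairwise(y, g, method="permutation", n_perm=4000, seed=0)
        for pa, pp in zip(asym.pairwise["p"], perm.pairwise["p"]):
            assert abs(pa - pp) < 0.10

    def test_small_group_pair_skipped(self):
        res = sdcf_pairwise([1.0, 2.0, 3.0, 4.0, 5.0], ["a", "a", "b", "b", "c"])
        pairs = set(map(frozenset, zip(res.pairwise["group1"], res.pairwise["group2"])))
        assert pairs == {frozenset(("a", "b"))}


class TestNeverTasted:
    def test_single_never_tasted_percentage(self):
        df = pd.DataFrame(
            {"item": ["chicory"] * 10,
             "response": [5, 6, 7, 4, 8, 6, 5, 7, 6, "never_tasted"]}
        )
        out = liking_with_never_tasted(df)
        assert out.loc[0, "n"] == 9
        assert out.loc[0, "pct_never_tasted"] == pytest.approx(10.0)
        assert out.loc[0, "mean"] == pytest.approx(54 / 9)

    def test_all_never_tasted(self):
        df = pd.DataFrame({"item": ["x", "x"], "response": ["never_tasted"] * 2})
        out = liking_with_never_tasted(df)
        assert np.isnan(out.loc[0, "mean"])
        assert out.loc[0, "pct_never_tasted"] == 100.0

    def test_mixed_items_table_shape(self):
        df = pd.DataFrame(
            {"item": ["a", "a", "b", "b"], "response": [9, "never_tasted", 1, 3]}
        )
        out = liking_with_never_tasted(df)
        assert list(out["item"]) == ["a", "b"]
        assert out.loc[1, "mean"] == pytest.approx(2.0)
        assert out.loc[0, "pct_never_tasted"] == pytest.approx(50.0)
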