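"""Percent differences, t-tests, two-way ANOVA, LSD letters and indices."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ricephys import (
    InputDataError,
    TraitTable,
    anova_two_way,
    compare_cultivars,
    harvest_index,
    lsd_groups,
    organ_partition,
    percent_difference,
    productive_tiller_pct,
    t_test_two_sample,
)
from ricephys.synth import NoiseModel, gen_trial_table
from ricephys.traits import round_half_up


class TestPercentDifference:
    @pytest.mark.parametrize(
        "test,ref,expected",
        [
            (105.91, 92.33, 14.71),   # Vcmax, milk stage
            (191.66, 177.15, 8.19),   # Jmax, milk stage
            (25.58, 21.31, 20.04),    # leaf Pn, panicle differentiation 2012
            (9.82, 9.09, 8.03),       # grain yield 2013 (t/ha)
        ],
    )
    def test_printed_trial_cells(self, test, ref, expected):
        assert round_half_up(percent_difference(test, ref)) == pytest.approx(expected)

    def test_identity_is_zero(self):
        assert percent_difference(3.7, 3.7) == 0.0

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_difference(1.0, 0.0)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(a=st.floats(0.1, 1e3), b=st.floats(0.1, 1e3))
    def test_reciprocity(self, a, b):
        d_ab = percent_difference(a, b)
        d_ba = percent_difference(b, a)
        assert (1 + d_ab / 100.0) * (1 + d_ba / 100.0) == pytest.approx(1.0, abs=1e-12)

    def test_round_half_up_ties(self):
        assert round_half_up(0.125) == 0.13
        assert round_half_up(-0.125) == -0.13
        assert round_half_up(8.0308) == 8.03


class TestTTest:
    def test_identical_samples(self):
        t, df, p = t_test_two_sample([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_pooled_hand_value(self):
        # means differ by 1, pooled se = 1 -> t = -1, df = 8
        t, df, p = t_test_two_sample([1, 2, 3, 4, 5], [2, 3, 4, 5, 6], "pooled")
        assert t == pytest.approx(-1.0, abs=1e-12)
        assert df == 8

    def test_welch_with_constant_sample(self):
        t, df, p = t_test_two_sample([5.0, 5.0, 5.0], [1.0, 2.0, 3.0], "welch")
        assert np.isfinite(t) and 0 < p < 1
        # Welch-Satterthwaite collapses to the non-constant sample's df
        assert df == pytest.approx(2.0, abs=1e-9)

    def test_small_sample_rejected(self):
        with pytest.raises(InputDataError):
            t_test_two_sample([1.0], [1.0, 2.0])


def _balanced_table(values_by_cell, n_reps=None, trait="y"):
    rows = []
    for (cv, yr), vals in values_by_cell.items():
        for i, v in enumerate(vals):
            rows.append(
                {"cultivar": cv, "year": yr, "replicate": i + 1, "trait": trait,
                 "value": v, "unit": ""}
            )
    return TraitTable(pd.DataFrame(rows))


class TestAnova:
    def test_zero_effects_degenerate(self):
        table = _balanced_table(
            {(c, y): [7.0, 7.0] for c in "AB" for y in (2013, 2014)}
        )
        out = anova_two_way(table, "y")
        assert out.loc["A", "ss"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc["B", "ss"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc["A×B", "ss"] == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(out.loc["A", "F"])

    def test_textbook_two_by_two(self):
        # cells: A1B1={10,10}, A1B2={20,20}, A2B1={30,30}, A2B2={40,40}
        table = _balanced_table(
            {("a1", 1): [10, 10], ("a1", 2): [20, 20],
             ("a2", 1): [30, 30], ("a2", 2): [40, 40]}
        )
        out = anova_two_way(table, "y")
        # grand mean 25; A deviations ±10 -> SS_A = 4*2*100... per-cell r=2:
        # SS_A = nb*r*sum((15-25)^2+(35-25)^2) = 2*2*200 = 800
        assert out.loc["A", "ss"] == pytest.approx(800.0, abs=1e-9)
        assert out.loc["B", "ss"] == pytest.approx(200.0, abs=1e-9)
        assert out.loc["A×B", "ss"] == pytest.approx(0.0, abs=1e-9)
        assert out.loc["error", "ss"] == pytest.approx(0.0, abs=1e-9)
        assert out.loc["A", "df"] == 1 and out.loc["error", "df"] == 4

    def test_partition_identity_random_tables(self, rng):
        for _ in range(25):
            vals = {
                (c, y): rng.normal(10, 2, size=3)
                for c in ("t", "r")
                for y in (2013, 2014, 2015)
            }
            out = anova_two_way(_balanced_table(vals), "y")
            parts = out.loc[["A", "B", "A×B", "error"], "ss"].sum()
            assert parts == pytest.approx(out.loc["total", "ss"], abs=1e-9)

    def test_matches_statsmodels_oracle(self, rng):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        vals = {
            (c, y): rng.normal(10, 2, size=4)
            for c in ("t", "r")
            for y in (2013, 2014, 2015)
        }
        table = _balanced_table(vals)
        ours = anova_two_way(table, "y")
        df = table.df.copy()
        fit = ols("value ~ C(cultivar) * C(year)", data=df).fit()
        ref = sm.stats.anova_lm(fit, typ=2)
        assert ours.loc["A", "ss"] == pytest.approx(ref.loc["C(cultivar)", "sum_sq"], rel=1e-9)
        assert ours.loc["B", "ss"] == pytest.approx(ref.loc["C(year)", "sum_sq"], rel=1e-9)
        assert ours.loc["A×B", "ss"] == pytest.approx(
            ref.loc["C(cultivar):C(year)", "sum_sq"], rel=1e-9
        )
        assert ours.loc["A", "p"] == pytest.approx(ref.loc["C(cultivar)", "PR(>F)"], rel=1e-9)

    def test_f_equals_squared_t_for_two_levels(self, rng):
        # single B level: one-way layout, F_A == t^2 (pooled)
        vals = {("t", 2013): rng.normal(10, 1, 6), ("r", 2013): rng.normal(11, 1, 6)}
        table = _balanced_table(vals)
        sub = table.df
        a = sub[sub.cultivar == "t"]["value"].to_numpy()
        b = sub[sub.cultivar == "r"]["value"].to_numpy()
        t, df, p = t_test_two_sample(a, b)
        out = anova_two_way(table, "y")
        assert out.loc["A", "F"] == pytest.approx(t**2, rel=1e-9)

    def test_unbalanced_rejected(self):
        table = _balanced_table(
            {("a", 1): [1, 2, 3], ("a", 2): [1, 2], ("b", 1): [1, 2], ("b", 2): [1, 2]}
        )
        with pytest.raises(InputDataError, match="nbalanced"):
            anova_two_way(table, "y")


class TestLsdGroups:
    def test_two_separated_means(self):
        # df large, ms_error/n chosen so LSD ~ 1.96
        letters = lsd_groups([10.0, 5.0], ms_error=5.0, df_error=1000, n_per_cell=10)
        assert letters == ["a", "b"]

    def test_all_close_means_share_letter(self):
        letters = lsd_groups([10.0, 9.9, 9.8], ms_error=5.0, df_error=1000, n_per_cell=10)
        assert letters == ["a", "a", "a"]

    def test_two_pairs(self):
        # LSD = t(0.975,1000)*sqrt(2*5/10) = 1.962
        letters = lsd_groups([10.0, 9.5, 7.0, 6.8], ms_error=5.0, df_error=1000, n_per_cell=10)
        assert letters == ["a", "a", "b", "b"]

    def test_overlapping_chain(self):
        letters = lsd_groups([10.0, 8.5, 7.0], ms_error=5.0, df_error=1000, n_per_cell=10)
        assert letters == ["a", "ab", "b"]

    def test_input_order_preserved(self):
        letters = lsd_groups([6.8, 10.0, 7.0, 9.5], ms_error=5.0, df_error=1000, n_per_cell=10)
        assert letters == ["b", "a", "b", "a"]

    def test_bad_df_rejected(self):
        with pytest.raises(InputDataError):
            lsd_groups([1.0, 2.0], 1.0, 0, 3)


class TestAgronomicIndices:
    def test_harvest_index(self):
        assert harvest_index(50.0, 100.0) == 0.5
        assert harvest_index(0.0, 100.0) == 0.0
        flag = []
        assert harvest_index(60.0, 50.0, flag=flag) == pytest.approx(1.2)
        assert flag == ["harvest_index>1"]
        with pytest.raises(ValueError):
            harvest_index(10.0, 0.0)

    def test_organ_partition(self):
        assert organ_partition(10, 10, 10, 10) == (25.0, 25.0, 25.0, 25.0)
        assert organ_partition(1, 0, 0, 0) == (100.0, 0.0, 0.0, 0.0)
        assert organ_partition(3, 2, 4, 1) == pytest.approx((30.0, 20.0, 40.0, 10.0))
        assert sum(organ_partition(3.1, 2.2, 4.7, 1.3)) == 100.0
        with pytest.raises(ValueError):
            organ_partition(0, 0, 0, 0)

    def test_productive_tillers(self):
        assert productive_tiller_pct(10, 20) == 50.0
        assert productive_tiller_pct(0, 20) == 0.0
        assert productive_tiller_pct(13, 16) == pytest.approx(81.25)
        flag = []
        productive_tiller_pct(22, 20, flag=flag)
        assert flag == ["productive_tillers>100%"]


class TestCompareCultivars:
    def test_known_means_reproduce_difference(self):
        # leaf Pn cell: 25.58 vs 21.31 -> +20.04%
        table = _balanced_table(
            {("test", 2012): [25.58] * 3, ("reference", 2012): [21.31] * 3},
            trait="pn",
        )
        res = compare_cultivars(table, "pn", 2012, "test", "reference")
        assert round_half_up(res.percent_diff) == pytest.approx(20.04)

    def test_equal_means(self):
        rng = np.random.default_rng(5)
        noise = rng.normal(0, 0.1, 6)
        table = _balanced_table(
            {("test", 2013): 20 + noise[:3], ("reference", 2013): 20 + noise[:3]},
            trait="pn",
        )
        res = compare_cultivars(table, "pn", 2013, "test", "reference")
        assert res.percent_diff == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)
        assert res.significant_at == "ns"

    def test_single_replicate_reports_difference_without_test(self):
        table = _balanced_table(
            {("test", 2013): [9.82], ("reference", 2013): [9.09]}, trait="yield"
        )
        res = compare_cultivars(table, "yield", 2013, "test", "reference")
        assert round_half_up(res.percent_diff) == pytest.approx(8.03)
        assert res.t_statistic is None and res.p_value is None

    def test_missing_cell_rejected(self):
        table = _balanced_table({("test", 2013): [1.0, 2.0]}, trait="y")
        with pytest.raises(InputDataError):
            compare_cultivars(table, "y", 2013, "test", "reference")

    def test_generator_effect_matches_population_difference(self):
        table = gen_trial_table(
            {"yield": 9.09}, {"yield": 0.73}, n_reps=3, years=(2013,),
            noise=NoiseModel("none", 0.0, 0),
        )
        res = compare_cultivars(table, "yield", 2013, "test", "reference")
        assert round_half_up(res.percent_diff) == pytest.approx(8.03)
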