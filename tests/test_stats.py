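"""Repeated-measures ANOVA, Bayes factors and power: oracle comparisons.

`pingouin.rm_anova` and `statsmodels.stats.power.TTestPower` serve as
independent reference implementations; the hand-computed sums-of-squares
oracle is written from the textbook decomposition with explicit loops.
"""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats as sps
from statsmodels.stats.power import TTestPower

from cyclopean.stats import (
    PowerSpec,
    RepeatedMeasuresAnova,
    RepeatedMeasuresTable,
    bf01_band,
    bf01_bic,
    min_sample_size_t,
    normalize_to_baseline,
    power_one_sample_t,
    rm_anova_one_way,
    rm_anova_two_way,
)


def toy_table(rng=None, n=8, k=4, effect=None):
    rng = rng or np.random.default_rng(0)
    Y = rng.normal(size=(n, k)) + rng.normal(size=(n, 1))
    if effect is not None:
        Y = Y + np.asarray(effect)
    return RepeatedMeasuresTable(
        pd.DataFrame(Y, columns=[f"c{j}" for j in range(k)]))


def hand_sums_of_squares(Y):
    """Textbook one-way within-subject decomposition, explicit loops."""
    n, k = Y.shape
    grand = Y.mean()
    ss_cond = sum(n * (Y[:, j].mean() - grand) ** 2 for j in range(k))
    ss_subj = sum(k * (Y[i, :].mean() - grand) ** 2 for i in range(n))
    ss_tot = sum((Y[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_tot - ss_cond - ss_subj
    F = (ss_cond / (k - 1)) / (ss_err / ((n - 1) * (k - 1)))
    p = sps.f.sf(F, k - 1, (n - 1) * (k - 1))
    return F, p


class TestNormalizeToBaseline:
    def test_subtracts_each_subjects_baseline(self):
        tab = RepeatedMeasuresTable(pd.DataFrame(
            [[2.0, 5.0, 3.0], [1.0, 1.0, 1.0]], columns=["pre", "a", "b"]))
        out = normalize_to_baseline(tab, "pre")
        np.testing.assert_array_equal(out.values,
                                      [[0.0, 3.0, 1.0], [0.0, 0.0, 0.0]])

    def test_readding_baseline_recovers_table(self):
        tab = toy_table()
        out = normalize_to_baseline(tab, "c0")
        restored = out.data.add(tab.data["c0"], axis=0)
        np.testing.assert_allclose(restored.values, tab.values, atol=1e-12)

    def test_missing_baseline_rejected(self):
        with pytest.raises(ValueError):
            normalize_to_baseline(toy_table(), "nope")


class TestOneWayAnova:
    def test_identical_conditions_give_zero_f(self):
        Y = np.tile(np.array([[1.0], [2.0], [5.0]]), (1, 4))
        res = rm_anova_one_way(RepeatedMeasuresTable(
            pd.DataFrame(Y, columns=list("abcd"))))
        assert res.F == 0.0 and res.degenerate

    def test_two_conditions_equal_squared_paired_t(self):
        rng = np.random.default_rng(2)
        tab = toy_table(rng, n=12, k=2, effect=[0.0, 0.4])
        res = rm_anova_one_way(tab)
        t = sps.ttest_rel(tab.values[:, 1], tab.values[:, 0])
        assert res.F == pytest.approx(t.statistic**2, rel=1e-10)
        assert res.p == pytest.approx(t.pvalue, rel=1e-10)
        assert (res.df1, res.df2) == (1, 11)
        assert res.epsilon == 1.0

    def test_matches_hand_computed_sums_of_squares(self):
        Y = np.array([[3.0, 5.0, 4.0], [2.0, 4.0, 6.0],
                      [1.0, 3.0, 2.0], [4.0, 6.0, 5.0]])
        res = rm_anova_one_way(RepeatedMeasuresTable(
            pd.DataFrame(Y, columns=list("abc"))), correction="never")
        F, p = hand_sums_of_squares(Y)
        assert res.F == pytest.approx(F, rel=1e-12)
        assert res.p == pytest.approx(p, rel=1e-12)

    def test_agrees_with_hand_oracle_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            Y = rng.integers(0, 10, size=(5, 4)).astype(float)
            Y += rng.normal(scale=1e-6, size=Y.shape)  # break exact ties
            res = rm_anova_one_way(RepeatedMeasuresTable(
                pd.DataFrame(Y, columns=list("abcd"))), correction="never")
            F, p = hand_sums_of_squares(Y)
            assert res.F == pytest.approx(F, rel=1e-9)

    def test_matches_pingouin_including_epsilon(self):
        rng = np.random.default_rng(5)
        tab = toy_table(rng, n=9, k=4, effect=[0, 0.3, 0.1, 0.6])
        long = tab.data.reset_index(names="subj").melt(
            "subj", var_name="cond", value_name="y")
        ref = pg.rm_anova(data=long, dv="y", within="cond", subject="subj",
                          correction=True).iloc[0]
        mine = rm_anova_one_way(tab, correction="always")
        assert mine.F == pytest.approx(ref["F"], rel=1e-9)
        assert mine.epsilon == pytest.approx(ref["eps"], rel=1e-9)
        assert mine.mauchly_w == pytest.approx(ref["W_spher"], rel=1e-9)
        assert mine.p == pytest.approx(ref["p_GG_corr"], rel=1e-6)

    def test_epsilon_bounds(self):
        rng = np.random.default_rng(9)
        for seed in range(10):
            tab = toy_table(np.random.default_rng(seed), n=8, k=5)
            res = rm_anova_one_way(tab, correction="always")
            assert 1.0 / 4.0 <= res.epsilon <= 1.0


class TestTwoWayAnova:
    @staticmethod
    def crossed_table(rng, n=8, a=3, b=3, interaction=0.0):
        Y = rng.normal(size=(n, a, b)) + rng.normal(size=(n, 1, 1))
        Y[:, 0, 0] += interaction
        cols = pd.MultiIndex.from_product(
            [[f"t{i}" for i in range(a)], [f"f{j}" for j in range(b)]],
            names=["time", "freq"])
        return RepeatedMeasuresTable(pd.DataFrame(Y.reshape(n, a * b),
                                                  columns=cols))

    def test_matches_pingouin_uncorrected(self):
        rng = np.random.default_rng(1)
        tab = self.crossed_table(rng, interaction=0.8)
        res = rm_anova_two_way(tab, correction="never")
        long = tab.data.stack([0, 1], future_stack=True).rename("y").reset_index()
        long.columns = ["subj", "time", "freq", "y"]
        ref = pg.rm_anova(data=long, dv="y", within=["time", "freq"],
                          subject="subj", correction=True)
        for source, mine in zip(["time", "freq", "time * freq"],
                                ["time", "freq", "time x freq"]):
            row = ref[ref.Source == source].iloc[0]
            assert res[mine].F == pytest.approx(row["F"], rel=1e-9)
            assert res[mine].p == pytest.approx(row["p_unc"], rel=1e-6)
            assert (res[mine].df1, res[mine].df2) == (row["ddof1"], row["ddof2"])

    def test_main_effect_epsilon_matches_pingouin(self):
        rng = np.random.default_rng(4)
        tab = self.crossed_table(rng)
        res = rm_anova_two_way(tab, correction="always")
        long = tab.data.stack([0, 1], future_stack=True).rename("y").reset_index()
        long.columns = ["subj", "time", "freq", "y"]
        ref = pg.rm_anova(data=long, dv="y", within=["time", "freq"],
                          subject="subj", correction=True)
        for source in ("time", "freq"):
            row = ref[ref.Source == source].iloc[0]
            assert res[source].epsilon == pytest.approx(row["eps"], rel=1e-6)

    def test_additive_data_recovers_main_effects_without_interaction(self):
        rng = np.random.default_rng(3)
        n, a, b = 12, 3, 3
        time_eff = np.array([0.0, 1.0, 2.0])
        freq_eff = np.array([0.0, -1.0, 1.0])
        Y = (rng.normal(scale=0.5, size=(n, a, b))
             + time_eff[None, :, None] + freq_eff[None, None, :])
        cols = pd.MultiIndex.from_product(
            [list("tuv"), list("xyz")], names=["time", "freq"])
        tab = RepeatedMeasuresTable(pd.DataFrame(Y.reshape(n, a * b), columns=cols))
        res = rm_anova_two_way(tab)
        assert res["time"].p < 1e-6 and res["freq"].p < 1e-6
        assert res["time x freq"].p > 0.01

    def test_interaction_type_i_error_near_alpha(self):
        # pure subject + noise data: interaction rejections ~ alpha
        alpha, reps = 0.05, 500
        rej = 0
        for seed in range(reps):
            tab = self.crossed_table(np.random.default_rng(seed), n=10)
            if rm_anova_two_way(tab)["time x freq"].p < alpha:
                rej += 1
        lo, hi = sps.binom.interval(0.99, reps, alpha)
        assert lo <= rej <= hi

    def test_single_level_factor_reduces_to_one_way(self):
        rng = np.random.default_rng(8)
        Y = rng.normal(size=(7, 4))
        cols = pd.MultiIndex.from_product([["only"], list("abcd")],
                                          names=["time", "freq"])
        tab2 = RepeatedMeasuresTable(pd.DataFrame(Y, columns=cols))
        tab1 = RepeatedMeasuresTable(pd.DataFrame(Y, columns=list("abcd")))
        res2 = rm_anova_two_way(tab2)["freq"]
        res1 = rm_anova_one_way(tab1)
        assert res2.F == pytest.approx(res1.F, rel=1e-12)
        assert res2.p == pytest.approx(res1.p, rel=1e-12)

    def test_unbalanced_design_rejected(self):
        cols = pd.MultiIndex.from_tuples(
            [("t0", "f0"), ("t0", "f1"), ("t1", "f0")], names=["time", "freq"])
        df = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 3)),
                          columns=cols)
        with pytest.raises(ValueError):
            rm_anova_two_way(RepeatedMeasuresTable(df))


class TestBayesFactor:
    def test_equal_bics_give_unity(self):
        # identical-model comparison: null == alternative terms
        tab = toy_table()
        res = bf01_bic(tab, ("subject",), ("subject",))
        assert res.bf01 == pytest.approx(1.0)

    def test_bic_gap_algebra(self):
        assert np.exp((2 * np.log(10)) / 2) == pytest.approx(10.0)
        assert bf01_band(10.0) == "strong"
        assert bf01_band(9.99) == "substantial"
        assert bf01_band(2.0) == "anecdotal"
        assert bf01_band(250.0) == "decisive"

    def test_non_nested_models_rejected(self):
        with pytest.raises(ValueError):
            bf01_bic(toy_table(), ("subject", "condition"), ("subject",))

    def test_null_data_favor_the_null_model(self):
        # 200 null tables (10 subjects x 5 change scores): median BF01 > 1
        bfs = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            tab = toy_table(rng, n=10, k=5)
            bfs.append(bf01_bic(tab).bf01)
        assert np.median(bfs) > 1.0

    def test_strong_effect_favors_the_alternative(self):
        rng = np.random.default_rng(0)
        tab = toy_table(rng, n=10, k=4, effect=[0.0, 2.0, 4.0, 6.0])
        assert bf01_bic(tab).bf01 < 1.0


class TestPower:
    def test_null_effect_power_equals_alpha(self):
        spec = PowerSpec(0.0, 1.0, alpha=0.05, tail="one")
        assert power_one_sample_t(spec, 10) == pytest.approx(0.05, abs=1e-10)

    def test_monotone_in_n_and_effect_size(self):
        spec = PowerSpec(1.0, 2.0)
        powers = [power_one_sample_t(spec, n) for n in range(2, 40)]
        assert np.all(np.diff(powers) > 0)
        stronger = PowerSpec(1.5, 2.0)
        assert power_one_sample_t(stronger, 10) > power_one_sample_t(spec, 10)

    @pytest.mark.parametrize("tail,alt", [("one", "larger"), ("two", "two-sided")])
    def test_matches_statsmodels_ttest_power(self, tail, alt):
        spec = PowerSpec(1.39, 1.24, alpha=0.05, tail=tail)
        for n in (5, 7, 12, 30):
            ref = TTestPower().power(effect_size=1.39 / 1.24, nobs=n,
                                     alpha=0.05, alternative=alt)
            assert power_one_sample_t(spec, n) == pytest.approx(ref, abs=1e-8)

    def test_minimum_sample_size_boundary(self):
        spec = PowerSpec(1.39, 1.24)
        n = min_sample_size_t(spec)
        assert power_one_sample_t(spec, n) >= 0.80
        assert power_one_sample_t(spec, n - 1) < 0.80

    def test_overwhelming_effect_floors_at_two(self):
        assert min_sample_size_t(PowerSpec(100.0, 1.0)) == 2

    def test_null_effect_unreachable(self):
        with pytest.raises(ValueError):
            min_sample_size_t(PowerSpec(0.0, 1.0))


class TestModelResultsSurface:
    def test_one_way_summary_reports_f_and_bf(self):
        rng = np.random.default_rng(6)
        model = RepeatedMeasuresAnova(toy_table(rng).data, baseline="c0",
                                      drop_baseline=True)
        res = model.fit()
        text = res.summary()
        assert "F(" in text and "BF01" in text
        assert res.to_frame().shape[0] == 1

    def test_two_way_summary_lists_three_effects(self):
        rng = np.random.default_rng(2)
        tab = TestTwoWayAnova.crossed_table(rng)
        res = RepeatedMeasuresAnova(tab).fit()
        assert len(res.effects) == 3
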