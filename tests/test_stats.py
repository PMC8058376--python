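import numpy as np
import pytest
from scipy import stats as sps

from qeeg_mcao.errors import (DegenerateDataError, DesignError, ParameterError)
from qeeg_mcao.stats import (assign_letters, ks_normality, one_way_anova,
                             summarize_groups, t_test_two_sample, tukey_hsd,
                             two_way_anova)


class TestKsNormality:
    def test_normal_quantile_sample_accepted(self):
        # sample laid exactly on fitted-normal quantiles: D is as small as
        # an n=50 sample can make it, so the Monte-Carlo p must be large
        x = sps.norm.ppf((np.arange(1, 51) - 0.5) / 50)
        d, p = ks_normality(x, n_replicates=2000)
        assert p > 0.5

    def test_exponential_sample_rejected(self):
        rng = np.random.default_rng(4)
        x = rng.exponential(size=200)
        _, p = ks_normality(x, n_replicates=2000)
        assert p < 0.05

    def test_constant_sample_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            ks_normality(np.full(10, 3.0))

    def test_small_sample_rejected(self):
        with pytest.raises(ParameterError):
            ks_normality([1.0, 2.0, 3.0])

    def test_loose_agreement_with_table_calibration(self):
        """Cross-check: the Monte-Carlo p should land near statsmodels'
        table-based Lilliefors p on a mildly non-normal sample."""
        lilliefors = pytest.importorskip(
            "statsmodels.stats.diagnostic").lilliefors
        rng = np.random.default_rng(8)
        x = rng.gamma(4.0, size=80)
        _, p_mc = ks_normality(x)
        _, p_tab = lilliefors(x, dist="norm")
        assert abs(p_mc - min(p_tab, 1.0)) < 0.05 or (p_mc < 0.01 and p_tab < 0.01)


class TestTTest:
    def test_identical_samples(self):
        t, df, p = t_test_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p) == (0.0, 1.0)

    def test_hand_evaluated_pooled_t(self):
        # pooled s^2 = 1, t = -1/sqrt(2/3)
        t, df, p = t_test_two_sample([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-1.224744871, abs=1e-6)
        assert df == 4

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, 8), rng.normal(0.5, 1, 10)
        t1, _, p1 = t_test_two_sample(x, y)
        t2, _, p2 = t_test_two_sample(y, x)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_zero_variance_unequal_means_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            t_test_two_sample([1.0, 1.0], [2.0, 2.0])


class TestOneWayAnova:
    def test_hand_evaluated_sums_of_squares(self):
        res = one_way_anova([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        assert res.f_value == pytest.approx(3.0)
        assert (res.df_between, res.df_within) == (2, 6)

    def test_identical_groups_give_null_f(self):
        res = one_way_anova([[1, 2, 3]] * 3)
        assert res.f_value == 0.0
        assert res.p_value == 1.0

    def test_translation_invariance(self):
        groups = [[1.0, 2.5, 3.1], [2.2, 3.3, 4.0], [0.5, 1.0, 2.0]]
        shifted = [[v + 100.0 for v in g] for g in groups]
        assert one_way_anova(groups).f_value == pytest.approx(
            one_way_anova(shifted).f_value)

    def test_matches_scipy(self):
        rng = np.random.default_rng(6)
        groups = [rng.normal(m, 1, 7) for m in (0, 0.5, 1.5)]
        ours = one_way_anova(groups)
        ref = sps.f_oneway(*groups)
        assert ours.f_value == pytest.approx(ref.statistic, rel=1e-10)
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_two_groups_satisfy_f_equals_t_squared(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(0, 1, 6), rng.normal(1, 1, 6)
        t, _, p_t = t_test_two_sample(x, y)
        res = one_way_anova([x, y])
        assert res.f_value == pytest.approx(t ** 2, rel=1e-9)
        assert res.p_value == pytest.approx(p_t, rel=1e-9)

    def test_small_group_rejected(self):
        with pytest.raises(ParameterError):
            one_way_anova([[1.0], [2.0, 3.0]])


class TestTwoWayAnova:
    def test_null_effects_by_construction(self):
        # B means and interaction identical across cells: F_B = F_AxB = 0
        cells = {("a1", "b1"): [1.0, 2.0], ("a1", "b2"): [1.0, 2.0],
                 ("a2", "b1"): [4.0, 5.0], ("a2", "b2"): [4.0, 5.0]}
        res = two_way_anova(cells)
        assert res["B"].f_value == pytest.approx(0.0, abs=1e-12)
        assert res["AxB"].f_value == pytest.approx(0.0, abs=1e-12)
        assert res["A"].f_value > 1.0

    def test_matches_statsmodels_on_2x2(self):
        smf = pytest.importorskip("statsmodels.formula.api")
        anova_lm = pytest.importorskip("statsmodels.stats.anova").anova_lm
        import pandas as pd
        rng = np.random.default_rng(12)
        rows = []
        cells = {}
        for a in ("a1", "a2"):
            for b in ("b1", "b2"):
                vals = rng.normal((a == "a2") * 1.0 + (b == "b2") * 0.5, 1.0, 4)
                cells[(a, b)] = list(vals)
                rows += [{"a": a, "b": b, "y": v} for v in vals]
        ours = two_way_anova(cells)
        fit = smf.ols("y ~ C(a) * C(b)", data=pd.DataFrame(rows)).fit()
        ref = anova_lm(fit, typ=2)
        assert ours["A"].f_value == pytest.approx(ref.loc["C(a)", "F"], rel=1e-8)
        assert ours["B"].f_value == pytest.approx(ref.loc["C(b)", "F"], rel=1e-8)
        assert ours["AxB"].f_value == pytest.approx(ref.loc["C(a):C(b)", "F"], rel=1e-8)

    def test_unbalanced_design_rejected(self):
        cells = {("a1", "b1"): [1.0, 2.0], ("a1", "b2"): [1.0, 2.0, 3.0],
                 ("a2", "b1"): [4.0, 5.0], ("a2", "b2"): [4.0, 5.0]}
        with pytest.raises(DesignError):
            two_way_anova(cells)


class TestTukey:
    def test_identical_groups_nothing_significant(self):
        tk = tukey_hsd([[1.0, 2.0, 3.0]] * 3)
        assert tk.significant() == []
        assert np.all(tk.p_adj > 0.99)

    def test_only_the_far_pair_separates(self):
        base = [0.0, 0.3, -0.3, 0.0]
        a = base
        b = [v + 0.45 for v in base]
        c = [v + 0.90 for v in base]
        tk = tukey_hsd([a, b, c], labels=["a", "b", "c"])
        assert tk.significant() == [("a", "c")]

    def test_matches_scipy_tukey(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(m, 1, 6) for m in (0, 1, 3)]
        ours = tukey_hsd(groups)
        ref = sps.tukey_hsd(*groups)
        for idx, (i, j) in enumerate([(0, 1), (0, 2), (1, 2)]):
            assert ours.p_adj[idx] == pytest.approx(ref.pvalue[i, j], abs=1e-8)

    def test_adjusted_p_dominates_pairwise_t(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(m, 1, 5) for m in (0, 0.8, 1.6)]
        tk = tukey_hsd(groups)
        for (i, j), p_adj in zip([(0, 1), (0, 2), (1, 2)], tk.p_adj):
            _, _, p_raw = t_test_two_sample(groups[i], groups[j])
            assert p_adj >= p_raw - 1e-12


class TestLetters:
    @staticmethod
    def letters_for(groups, labels):
        return assign_letters(tukey_hsd(groups, labels=labels))

    def test_no_differences_single_letter(self):
        lt = self.letters_for([[1.0, 2.0, 3.0]] * 3, ["g1", "g2", "g3"])
        assert set(lt.values()) == {"a"}

    def test_all_different_distinct_letters(self):
        groups = [[0.0, 0.1, -0.1], [10.0, 10.1, 9.9], [20.0, 20.1, 19.9]]
        lt = self.letters_for(groups, ["g1", "g2", "g3"])
        assert sorted(lt.values()) == ["a", "b", "c"]

    def test_chain_yields_bridge_label(self):
        # A~B and B~C but A!=C: minimal cover on 3 nodes is a / ab / b
        base = [0.0, 0.1, -0.1, 0.05, -0.05]
        a = base
        b = [v + 0.1 for v in base]
        c = [v + 0.2 for v in base]
        tk = tukey_hsd([a, b, c], labels=["A", "B", "C"])
        assert tk.significant() == [("A", "C")]
        assert assign_letters(tk) == {"A": "a", "B": "ab", "C": "b"}


class TestSummary:
    def test_mean_and_sample_sd(self):
        gs = summarize_groups({"g1": [1.0, 2.0, 3.0], "g2": [5.0, 5.0, 5.0]})
        assert gs.mean == [2.0, 5.0]
        assert gs.sd[0] == pytest.approx(1.0)
        assert gs.sd[1] == 0.0

    def test_scaling_scales_mean_and_sd(self):
        vals = {"g1": [1.0, 2.0, 4.0], "g2": [3.0, 5.0, 6.0]}
        scaled = {k: [10 * v for v in g] for k, g in vals.items()}
        a, b = summarize_groups(vals), summarize_groups(scaled)
        assert b.mean == pytest.approx([10 * m for m in a.mean])
        assert b.sd == pytest.approx([10 * s for s in a.sd])
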