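"""ANOVA battery against hand-computed values and independent references."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sst

from murisomnia.stats import (
    anova_mixed,
    anova_one_way_within,
    anova_two_way_between,
    bonferroni_adjust,
    simple_effects,
    t_unpaired,
    tukey_hsd,
)


def two_way_table(cells: dict) -> pd.DataFrame:
    rows = []
    for (a, b), values in cells.items():
        for v in values:
            rows.append({"A": a, "B": b, "value": float(v)})
    return pd.DataFrame(rows)


class TestTwoWayBetween:
    def test_hand_computed_2x2(self):
        """Balanced 2x2 with cells {1,2},{3,4},{5,6},{7,8}: SS_A=32, SS_B=8,
        SS_AB=0, MSE=0.5 -> F_A=64 (1,4), F_B=16, F_AB=0."""
        table = two_way_table({
            ("a1", "b1"): [1, 2], ("a1", "b2"): [3, 4],
            ("a2", "b1"): [5, 6], ("a2", "b2"): [7, 8],
        })
        fa, fb, fab = anova_two_way_between(table)
        assert fa.F == pytest.approx(64.0, abs=1e-10)
        assert (fa.df_num, fa.df_den) == (1, 4)
        assert fb.F == pytest.approx(16.0, abs=1e-10)
        assert fab.F == pytest.approx(0.0, abs=1e-10)

    def test_constant_data_all_zero_f(self):
        table = two_way_table({(a, b): [5.0, 5.0] for a in "xy" for b in "uv"})
        for res in anova_two_way_between(table):
            assert res.F == pytest.approx(0.0, abs=1e-10)

    def test_empty_cell_named(self):
        table = two_way_table({("a1", "b1"): [1, 2], ("a1", "b2"): [3, 4],
                               ("a2", "b1"): [5, 6]})
        with pytest.raises(ValueError, match="a2.*b2"):
            anova_two_way_between(table)

    def test_agrees_with_statsmodels_type3(self, rng):
        """Random unbalanced tables vs statsmodels Type-III ANOVA."""
        smf = pytest.importorskip("statsmodels.formula.api")
        import statsmodels.api as sm

        for _ in range(5):
            cells = {}
            for a in ("a1", "a2", "a3"):
                for b in ("b1", "b2"):
                    n = int(rng.integers(3, 7))
                    cells[(a, b)] = rng.normal(rng.normal(0, 2), 1.0, size=n)
            table = two_way_table(cells)
            ours = anova_two_way_between(table)
            model = smf.ols(
                "value ~ C(A, Sum) * C(B, Sum)", data=table
            ).fit()
            ref = sm.stats.anova_lm(model, typ=3)
            np.testing.assert_allclose(ours[0].F, ref.loc["C(A, Sum)", "F"],
                                       rtol=1e-8)
            np.testing.assert_allclose(ours[1].F, ref.loc["C(B, Sum)", "F"],
                                       rtol=1e-8)
            np.testing.assert_allclose(
                ours[2].F, ref.loc["C(A, Sum):C(B, Sum)", "F"], rtol=1e-8
            )


def mixed_table(rng, n_per_group=(6, 6), q=2, group_shift=0.0,
                period_shift=0.0, interaction=0.0):
    rows = []
    k = 0
    for gi, n in enumerate(n_per_group):
        for _ in range(n):
            k += 1
            subj_effect = rng.normal(0, 1)
            for w in range(q):
                value = (rng.normal(0, 1) + subj_effect + gi * group_shift
                         + w * period_shift + gi * w * interaction)
                rows.append({"subject": f"s{k}", "between": f"g{gi}",
                             "within": f"t{w}", "value": value})
    return pd.DataFrame(rows)


class TestMixed:
    def test_identical_within_levels_zero_f(self, rng):
        table = mixed_table(rng)
        wide = table.pivot_table(index=["subject", "between"], columns="within",
                                 values="value").reset_index()
        wide["t1"] = wide["t0"]
        flat = wide.melt(id_vars=["subject", "between"], value_vars=["t0", "t1"],
                         var_name="within", value_name="value")
        res = anova_mixed(flat)
        within = next(r for r in res if r.effect == "within")
        assert within.F == pytest.approx(0.0, abs=1e-10)

    def test_missing_within_level_names_subject(self, rng):
        table = mixed_table(rng)
        table = table[~((table["subject"] == "s3") & (table["within"] == "t1"))]
        with pytest.raises(ValueError, match="s3"):
            anova_mixed(table)

    def test_agrees_with_pingouin_balanced(self, rng):
        pg = pytest.importorskip("pingouin")
        import warnings

        for _ in range(5):
            table = mixed_table(rng, n_per_group=(5, 5), q=3)
            ours = {r.effect: r for r in anova_mixed(table)}
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ref = pg.mixed_anova(data=table, dv="value", within="within",
                                     between="between", subject="subject")
            ref = ref.set_index("Source")
            np.testing.assert_allclose(ours["between"].F, ref.loc["between", "F"],
                                       rtol=1e-8)
            np.testing.assert_allclose(ours["within"].F, ref.loc["within", "F"],
                                       rtol=1e-8)
            np.testing.assert_allclose(ours["between x within"].F,
                                       ref.loc["Interaction", "F"], rtol=1e-8)

    def test_planted_interaction_detected(self, rng):
        """Power check: a genotype x period interaction planted well above
        the noise floor is detected in most replicates."""
        hits = 0
        for _ in range(10):
            table = mixed_table(rng, n_per_group=(8, 8), interaction=2.0)
            res = {r.effect: r for r in anova_mixed(table)}
            hits += res["between x within"].p < 0.05
        assert hits >= 8


class TestOneWayWithin:
    def _table(self, rng, n=7, q=4, shift=0.0):
        rows = []
        for s in range(n):
            base = rng.normal(0, 1)
            for lvl in range(q):
                rows.append({"subject": f"s{s}", "level": f"r{lvl}",
                             "value": base + rng.normal(0, 1) + lvl * shift})
        return pd.DataFrame(rows)

    def test_identical_levels_zero_f(self, rng):
        table = self._table(rng, q=2)
        wide = table.pivot(index="subject", columns="level", values="value")
        wide["r1"] = wide["r0"]
        flat = wide.reset_index().melt(id_vars="subject", var_name="level",
                                       value_name="value")
        assert anova_one_way_within(flat).F == pytest.approx(0.0, abs=1e-10)

    def test_agrees_with_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        for _ in range(5):
            table = self._table(rng, shift=0.5)
            ours = anova_one_way_within(table)
            ref = pg.rm_anova(data=table, dv="value", within="level",
                              subject="subject")
            np.testing.assert_allclose(ours.F, ref["F"].iloc[0], rtol=1e-8)
            assert (ours.df_num, ours.df_den) == (
                int(ref["ddof1"].iloc[0]), int(ref["ddof2"].iloc[0])
            )

    def test_region_scale_separation_significant_at_n7(self, rng):
        """Region means separated by orders of magnitude, n = 7."""
        table = self._table(rng, n=7, q=4, shift=0.0)
        table["value"] = table["value"] + table["level"].map(
            {"r0": 7600.0, "r1": 100.0, "r2": 51.0, "r3": 41.0}
        ) * (1 + 0.1 * table["value"])
        assert anova_one_way_within(table).p < 0.05

    def test_incomplete_block_rejected(self, rng):
        table = self._table(rng).iloc[:-1]
        with pytest.raises(ValueError, match="incomplete block"):
            anova_one_way_within(table)


class TestTukey:
    def test_equal_means_all_p_one(self):
        res = tukey_hsd({"a": 5.0, "b": 5.0, "c": 5.0}, {"a": 5, "b": 5, "c": 5},
                        mse=1.0, df_error=12)
        assert all(p == 1.0 and q == 0.0 for _, q, p in res)

    def test_two_groups_matches_t_test(self, rng):
        """With k=2 the studentized-range p equals the unpaired-t p."""
        x, y = rng.normal(0, 1, 8), rng.normal(1, 1, 8)
        t_res = t_unpaired(x, y)
        mse = (((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()) / t_res.df_den
        (_, q, p), = tukey_hsd({"x": x.mean(), "y": y.mean()}, {"x": 8, "y": 8},
                               mse=mse, df_error=t_res.df_den)
        assert p == pytest.approx(t_res.p, rel=1e-6)
        assert q == pytest.approx(abs(t_res.F) * np.sqrt(2), rel=1e-9)

    def test_agrees_with_scipy_oracle(self, rng):
        """Balanced groups vs scipy.stats.tukey_hsd."""
        groups = [rng.normal(m, 1, 6) for m in (0.0, 0.8, 1.6)]
        res = sst.tukey_hsd(*groups)
        mse = np.mean([g.var(ddof=1) for g in groups])
        means = {f"g{i}": g.mean() for i, g in enumerate(groups)}
        ns = {f"g{i}": 6 for i in range(3)}
        ours = tukey_hsd(means, ns, mse=mse, df_error=15)
        for (gi, gj), _, p in ours:
            i, j = int(gi[1]), int(gj[1])
            assert p == pytest.approx(res.pvalue[i, j], rel=1e-6, abs=1e-12)

    def test_nonpositive_df_rejected(self):
        with pytest.raises(ValueError):
            tukey_hsd({"a": 1.0, "b": 2.0}, {"a": 2, "b": 2}, mse=1.0, df_error=0)


class TestBonferroni:
    def test_examples_and_monotonicity(self):
        assert bonferroni_adjust([0.01]) == [0.01]
        assert bonferroni_adjust([0.02, 0.03]) == [0.04, 0.06]
        ps = [0.001, 0.2, 0.9]
        assert all(adj >= p for adj, p in zip(bonferroni_adjust(ps), ps))
        assert max(bonferroni_adjust([0.9, 0.9])) == 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([1.5])


class TestSimpleEffects:
    def test_effect_planted_at_one_level_only(self, rng):
        hits_there = hits_elsewhere = 0
        for _ in range(10):
            cells = {("a1", "b1"): rng.normal(0, 1, 6),
                     ("a2", "b1"): rng.normal(3, 1, 6),
                     ("a1", "b2"): rng.normal(0, 1, 6),
                     ("a2", "b2"): rng.normal(0, 1, 6)}
            table = two_way_table(cells)
            results = {r.effect: r for r in simple_effects(table, "A", "B")}
            hits_there += results["A at B=b1"].p < 0.05
            hits_elsewhere += results["A at B=b2"].p < 0.05
        assert hits_there >= 8
        assert hits_elsewhere <= 3

    def test_single_level_factor_rejected(self, rng):
        table = two_way_table({("a1", "b1"): rng.normal(0, 1, 4),
                               ("a1", "b2"): rng.normal(0, 1, 4)})
        with pytest.raises(ValueError, match="single level"):
            simple_effects(table, "A", "B")


class TestTTest:
    def test_identical_samples(self):
        res = t_unpaired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.F == 0.0 and res.p == 1.0

    def test_zero_variance_equal_means_p_one(self):
        res = t_unpaired([2.0, 2.0], [2.0, 2.0])
        assert res.p == 1.0

    def test_matches_scipy(self, rng):
        for _ in range(10):
            x, y = rng.normal(0, 1, 7), rng.normal(0.5, 1, 9)
            ours = t_unpaired(x, y)
            ref = sst.ttest_ind(x, y)
            assert ours.F == pytest.approx(ref.statistic, rel=1e-10)
            assert ours.p == pytest.approx(ref.pvalue, rel=1e-10)
            assert ours.df_den == 14

    def test_textbook_pair(self):
        """Means 5 vs 7, pooled sd 1, n=4 each -> t = -2/sqrt(1/2) ~ -2.828."""
        x = [4.0, 5.0, 5.0, 6.0]
        y = [6.0, 7.0, 7.0, 8.0]
        res = t_unpaired(x, y)
        sp2 = (2.0 + 2.0) / 6
        expected = (5.0 - 7.0) / np.sqrt(sp2 * 0.5)
        assert res.F == pytest.approx(expected, rel=1e-12)


class TestTypeICalibration:
    """Null rejection rates at alpha=0.05 stay within [0.03, 0.07]."""

    REPS = 1000

    def test_two_way_between_null(self):
        rng = np.random.default_rng(2001)
        rejections = np.zeros(3)
        for _ in range(self.REPS):
            cells = {(a, b): rng.normal(0, 1, 4) for a in "xy" for b in "uv"}
            res = anova_two_way_between(two_way_table(cells))
            rejections += [r.p < 0.05 for r in res]
        rates = rejections / self.REPS
        assert ((0.03 <= rates) & (rates <= 0.07)).all(), rates

    def test_mixed_null(self):
        rng = np.random.default_rng(2002)
        rejections = np.zeros(3)
        for _ in range(self.REPS):
            res = anova_mixed(mixed_table(rng, n_per_group=(5, 5)))
            rejections += [r.p < 0.05 for r in res]
        rates = rejections / self.REPS
        assert ((0.03 <= rates) & (rates <= 0.07)).all(), rates

    def test_rm_one_way_null(self):
        rng = np.random.default_rng(2003)
        count = 0
        for _ in range(self.REPS):
            rows = []
            for s in range(6):
                base = rng.normal()
                for lvl in range(3):
                    rows.append({"subject": s, "level": lvl,
                                 "value": base + rng.normal()})
            count += anova_one_way_within(pd.DataFrame(rows)).p < 0.05
        assert 0.03 <= count / self.REPS <= 0.07

    def test_t_null(self):
        rng = np.random.default_rng(2004)
        count = sum(
            t_unpaired(rng.normal(0, 1, 6), rng.normal(0, 1, 8)).p < 0.05
            for _ in range(self.REPS)
        )
        assert 0.03 <= count / self.REPS <= 0.07
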