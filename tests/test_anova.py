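"""Binned accuracy, sphericity, rm-ANOVA, post-hoc t tests and effect sizes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import make_trials
from tachometry import (
    bin_accuracy_100ms,
    bonferroni_adjust,
    cohens_d_paired,
    congruency_effect,
    gg_epsilon,
    mauchly_test,
    posthoc_paired_t,
    rm_anova_2way,
)
from tachometry.anova import BinnedAccuracyTable
from tachometry.trials import CONGRUENCIES

# printed post-hoc rows (bin_a, bin_b, t, df, p, adj p, d) from the three
# main-effect tables of the published analyses; used as arithmetic oracles
TABLE_SPATIAL = [
    (50, 150, 0.50, 9, 0.632, 1.00, 0.16),
    (50, 250, -0.18, 9, 0.858, 1.00, -0.06),
    (50, 350, -3.48, 9, 0.007, 0.10, -1.10),
    (50, 450, -9.19, 9, 0.001, 0.00, -2.91),
    (50, 550, -6.36, 9, 0.001, 0.00, -2.01),
    (150, 250, -0.35, 9, 0.737, 1.00, -0.11),
    (150, 350, -3.64, 9, 0.005, 0.08, -1.15),
    (150, 450, -8.62, 9, 0.001, 0.00, -2.73),
    (150, 550, -6.62, 9, 0.001, 0.00, -2.09),
    (250, 350, -1.70, 9, 0.124, 1.00, -0.54),
    (250, 450, -4.41, 9, 0.002, 0.03, -1.39),
    (250, 550, -4.26, 9, 0.002, 0.03, -1.35),
    (350, 450, -4.26, 9, 0.002, 0.03, -1.35),
    (350, 550, -3.47, 9, 0.007, 0.10, -1.10),
    (450, 550, -1.15, 9, 0.279, 1.00, -0.36),
]
TABLE_NUMERICAL = [
    (50, 150, 0.57, 19, 0.576, 1.00, 0.13),
    (50, 250, -1.51, 19, 0.147, 1.00, -0.34),
    (250, 350, -4.24, 19, 0.001, 0.01, -0.95),
    (350, 450, -2.81, 19, 0.011, 0.23, -0.63),
    (350, 550, -4.02, 19, 0.001, 0.01, -0.90),
    (350, 650, -3.05, 19, 0.007, 0.14, -0.68),
    (450, 550, -3.00, 19, 0.007, 0.15, -0.67),
    (450, 650, -0.93, 19, 0.365, 1.00, -0.21),
    (550, 650, 0.44, 19, 0.666, 1.00, 0.10),
]
TABLE_SIMON = [
    (250, 350, -2.55, 11, 0.027, 0.27, -0.74),
    (250, 450, -2.75, 11, 0.019, 0.19, -0.80),
    (250, 550, -3.27, 11, 0.008, 0.07, -0.94),
    (250, 650, -3.34, 11, 0.007, 0.07, -0.96),
    (350, 450, -2.09, 11, 0.061, 0.61, -0.60),
    (350, 550, -5.00, 11, 0.001, 0.00, -1.44),
    (350, 650, -3.13, 11, 0.010, 0.10, -0.90),
    (450, 550, -1.23, 11, 0.244, 1.00, -0.36),
    (450, 650, -2.54, 11, 0.028, 0.28, -0.73),
    (550, 650, -1.53, 11, 0.155, 1.00, -0.44),
]
FAMILY = {9: 15, 19: 21, 11: 10}  # df -> number of pairwise comparisons


def _random_cells(rng, n, b):
    bins = [50 + 100 * i for i in range(b)]
    cols = pd.MultiIndex.from_tuples(
        [(c, bn) for c in CONGRUENCIES for bn in bins],
        names=["congruency", "bin_center"],
    )
    cells = pd.DataFrame(rng.random((n, 2 * b)) * 0.5 + 0.4, columns=cols,
                         index=[f"P{i:02d}" for i in range(n)])
    return BinnedAccuracyTable(cells=cells, bin_width=100, lo=0, hi=1000,
                               complete_bins=bins)


class TestBinning:
    def test_half_open_edges_and_center_labels(self):
        t = make_trials([0, 99, 100], [True, True, False],
                        congruency=["congruent"] * 3)
        t.data.loc[:, "congruency"] = ["congruent", "congruent", "incongruent"]
        # add the other condition so completeness keeps bins comparable
        import pandas as pd

        extra = make_trials([0, 99, 100], [True, False, True],
                            congruency=["incongruent", "incongruent", "congruent"])
        both = type(t)(pd.concat([t.data, extra.data], ignore_index=True))
        bt = bin_accuracy_100ms(both)
        assert set(bt.complete_bins) == {50, 150}

    def test_incomplete_bin_dropped_for_everyone(self):
        rpt = [50, 150, 650, 50, 150, 50, 150, 650, 50, 150]
        cong = ["congruent", "congruent", "congruent", "incongruent", "incongruent",
                "congruent", "congruent", "congruent", "incongruent", "incongruent"]
        part = ["P01"] * 5 + ["P02"] * 5
        t = make_trials(rpt, [True] * 10, congruency=cong, participant=part)
        bt = bin_accuracy_100ms(t)
        # bin 650 has no incongruent trials for anyone -> dropped
        assert 650 not in bt.complete_bins
        assert bt.n_dropped_bins == 1

    def test_empty_table_rejected(self, small_experiment):
        analyzed, _ = small_experiment
        empty = type(analyzed)(analyzed.data.iloc[:0])
        with pytest.raises(ValueError):
            bin_accuracy_100ms(empty)


class TestSphericity:
    def test_two_levels_trivially_spherical(self):
        rng = np.random.default_rng(0)
        data = rng.random((10, 2))
        res = mauchly_test(data)
        assert res.W == 1.0 and res.p == 1.0
        assert gg_epsilon(data) == 1.0

    def test_one_level_rejected(self):
        with pytest.raises(ValueError):
            mauchly_test(np.random.default_rng(0).random((10, 1)))

    def test_epsilon_bounds_random_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            k = int(rng.integers(2, 7))
            data = rng.random((int(rng.integers(k + 2, 20)), k))
            eps = gg_epsilon(data)
            assert 1.0 / (k - 1) - 1e-12 <= eps <= 1.0 + 1e-12

    def test_epsilon_approaches_one_under_sphericity(self):
        # spherical population covariance (iid levels), large n
        rng = np.random.default_rng(2)
        data = rng.normal(size=(4000, 5))
        assert gg_epsilon(data) > 0.99

    def test_mauchly_null_p_uniform(self):
        # compound-symmetric population: sphericity holds; p ~ Uniform(0,1)
        rng = np.random.default_rng(3)
        ps = []
        for _ in range(200):
            subj = rng.normal(size=(25, 1))
            data = subj + rng.normal(size=(25, 4))
            ps.append(mauchly_test(data).p)
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01
        rate = np.mean(np.asarray(ps) < 0.05)
        assert 0.01 <= rate <= 0.11

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        data = rng.random((12, 5))
        mine = mauchly_test(data)
        ref = pg.sphericity(pd.DataFrame(data))
        assert mine.W == pytest.approx(ref.W, rel=1e-10)
        assert mine.chi2 == pytest.approx(ref.chi2, rel=1e-10)
        assert mine.p == pytest.approx(ref.pval, rel=1e-8)
        assert gg_epsilon(data) == pytest.approx(
            float(pg.epsilon(pd.DataFrame(data), correction="gg")), rel=1e-10)


class TestRmAnova:
    def test_two_level_reduction_equals_squared_paired_t(self):
        rng = np.random.default_rng(5)
        bt = _random_cells(rng, n=9, b=2)
        res = rm_anova_2way(bt)
        # congruency main effect vs paired t on condition means across bins
        a = bt.condition_matrix("congruent").mean(axis=1)
        b = bt.condition_matrix("incongruent").mean(axis=1)
        t, p = stats.ttest_rel(a, b)
        assert res.congruency.F == pytest.approx(t**2, abs=1e-8)
        assert res.congruency.p == pytest.approx(p, abs=1e-10)

    def test_additive_data_zero_interaction(self):
        n, b = 8, 5
        subj = np.linspace(0, 0.1, n)[:, None, None]
        cond = np.array([0.0, 0.08])[None, :, None]
        bins = np.linspace(0, 0.3, b)[None, None, :]
        y = 0.5 + subj + cond + bins
        cols = pd.MultiIndex.from_tuples(
            [(c, 50 + 100 * i) for c in CONGRUENCIES for i in range(b)],
            names=["congruency", "bin_center"])
        cells = pd.DataFrame(y.reshape(n, -1), columns=cols)
        bt = BinnedAccuracyTable(cells=cells, bin_width=100, lo=0, hi=1000,
                                 complete_bins=[50 + 100 * i for i in range(b)])
        res = rm_anova_2way(bt)
        assert res.ss["interaction"] == pytest.approx(0.0, abs=1e-20)

    def test_ss_conservation_and_eta_range(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            bt = _random_cells(rng, n=int(rng.integers(4, 12)),
                               b=int(rng.integers(2, 8)))
            res = rm_anova_2way(bt)
            ss = res.ss
            parts = (ss["subject"] + ss["congruency"] + ss["bin"]
                     + ss["congruency_x_subject"] + ss["bin_x_subject"]
                     + ss["interaction"] + ss["interaction_x_subject"])
            assert parts == pytest.approx(ss["total"], abs=1e-10)
            for eff in (res.congruency, res.bin, res.interaction):
                assert 0.0 <= eff.eta2_g <= 1.0
                assert 1.0 / max(eff.df1, 1) <= eff.gg_epsilon <= 1.0 or eff.df1 == 1

    def test_matches_pingouin_two_way(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        bt = _random_cells(rng, n=10, b=6)
        res = rm_anova_2way(bt)
        long = bt.cells.stack(["congruency", "bin_center"], future_stack=True)
        long = long.rename("y").reset_index()
        long.columns = ["subject", "congruency", "bin", "y"]
        ref = pg.rm_anova(long, dv="y", within=["congruency", "bin"],
                          subject="subject", effsize="ng2")
        for mine, source in ((res.congruency, "congruency"), (res.bin, "bin"),
                             (res.interaction, "congruency * bin")):
            row = ref[ref.Source == source].iloc[0]
            assert mine.F == pytest.approx(row.F, rel=1e-8)
            assert mine.p == pytest.approx(row["p_unc"], rel=1e-8)
            assert mine.eta2_g == pytest.approx(row["ng2"], rel=1e-8)
            if mine.df1 > 1:
                assert mine.gg_epsilon == pytest.approx(row["eps"], rel=1e-6)
                assert mine.p_gg == pytest.approx(row["p_GG_corr"], rel=1e-6)

    def test_fewer_than_two_participants_rejected(self):
        rng = np.random.default_rng(8)
        bt = _random_cells(rng, n=1, b=3)
        with pytest.raises(ValueError, match="participants"):
            rm_anova_2way(bt)


class TestCongruencyEffect:
    def test_identical_conditions_all_zero(self):
        rng = np.random.default_rng(9)
        bt = _random_cells(rng, n=6, b=4)
        bt.cells.loc[:, "incongruent"] = bt.cells["congruent"].to_numpy()
        assert (congruency_effect(bt).to_numpy() == 0).all()

    def test_difference_arithmetic(self):
        rng = np.random.default_rng(10)
        bt = _random_cells(rng, n=5, b=3)
        bt.cells.loc["P00", ("congruent", 50)] = 0.9
        bt.cells.loc["P00", ("incongruent", 50)] = 0.4
        eff = congruency_effect(bt)
        assert eff.loc["P00", 50] == pytest.approx(0.5)

    def test_grand_mean_identity(self):
        rng = np.random.default_rng(11)
        bt = _random_cells(rng, n=7, b=5)
        eff = congruency_effect(bt)
        direct = (bt.condition_matrix("congruent").to_numpy().mean()
                  - bt.condition_matrix("incongruent").to_numpy().mean())
        assert eff.to_numpy().mean() == pytest.approx(direct, abs=1e-12)


class TestPrintedTableArithmetic:
    @pytest.mark.parametrize("table", [TABLE_SPATIAL, TABLE_NUMERICAL, TABLE_SIMON])
    def test_d_equals_t_over_sqrt_n(self, table):
        # t is printed to 2 decimals, so the recomputed d may differ from
        # the printed d by one unit in the last digit
        for _, _, t, df, _, _, d in table:
            assert abs(round(cohens_d_paired(t, df + 1), 2) - d) <= 0.01 + 1e-9

    @pytest.mark.parametrize("table", [TABLE_SPATIAL, TABLE_NUMERICAL, TABLE_SIMON])
    def test_bonferroni_reproduces_adjusted_column(self, table):
        for _, _, _, df, p, p_adj, _ in table:
            m = FAMILY[df]
            if p == 0.001:  # printed as "< .001": only an upper bound
                assert bonferroni_adjust(p, m) >= p_adj
            else:
                # p is printed to 3 decimals: the adjusted value can move
                # by up to m * 0.0005 before its own 2-decimal rounding
                tol = m * 0.0005 + 0.005 + 1e-9
                assert abs(bonferroni_adjust(p, m) - p_adj) <= tol

    def test_specific_printed_cells(self):
        assert round(cohens_d_paired(0.50, 10), 2) == 0.16
        assert round(cohens_d_paired(-5.00, 12), 2) == -1.44
        assert bonferroni_adjust(0.011, 21) == pytest.approx(0.231)
        assert round(bonferroni_adjust(0.011, 21), 2) == 0.23
        assert bonferroni_adjust(0.632, 15) == 1.00


class TestBonferroniProperties:
    @given(p=st.floats(0, 1), m=st.integers(1, 50), m2=st.integers(1, 50))
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_capped(self, p, m, m2):
        out = bonferroni_adjust(p, m)
        assert 0 <= out <= 1
        if m2 >= m:
            assert bonferroni_adjust(p, m2) >= out
        assert bonferroni_adjust(out, 1) == out  # idempotent at the cap

    @given(t=st.floats(-50, 50), n=st.integers(2, 40))
    @settings(max_examples=50, deadline=None)
    def test_d_times_sqrt_n_recovers_t(self, t, n):
        assert cohens_d_paired(t, n) * np.sqrt(n) == pytest.approx(t, abs=1e-12)


class TestPosthoc:
    def test_reproduces_scipy_and_formats(self):
        rng = np.random.default_rng(12)
        data = pd.DataFrame(rng.random((10, 4)), columns=[50, 150, 250, 350])
        table = posthoc_paired_t(data)
        assert len(table) == 6
        row = table[(table.level_a == 50) & (table.level_b == 150)].iloc[0]
        t, p = stats.ttest_rel(data[50], data[150])
        assert row.t == pytest.approx(t)
        assert row.p == pytest.approx(p)
        assert row.p_adj == pytest.approx(min(1, 6 * p))
        assert row.d == pytest.approx(t / np.sqrt(10))
        assert row.df == 9

    def test_identical_columns_give_zero_t(self):
        data = pd.DataFrame({50: [0.5, 0.6, 0.7], 150: [0.5, 0.6, 0.7]})
        table = posthoc_paired_t(data)
        row = table.iloc[0]
        assert row.t == 0.0 and row.p == 1.0 and row.d == 0.0

    def test_constant_nonzero_difference_flagged(self):
        data = pd.DataFrame({50: [0.5, 0.6, 0.7], 150: [0.4, 0.5, 0.6]})
        table = posthoc_paired_t(data)
        assert table.iloc[0]["significance"] == "undefined"

    def test_family_size_override(self):
        rng = np.random.default_rng(13)
        data = pd.DataFrame(rng.random((8, 2)), columns=[1, 2])
        t21 = posthoc_paired_t(data, family_size=21)
        t1 = posthoc_paired_t(data)
        assert t21.iloc[0].p_adj == pytest.approx(
            min(1, 21 * t1.iloc[0].p))
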