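"""Inference layer: ANOVA vs manual sums of squares, FDR, rank statistics,
Hodges-Lehmann intervals, slopes, and the one-sided JZS Bayes factor."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from reachatten.config import REACHING_TYPES
from reachatten.stats import (
    StatsError,
    bayes_factor_one_sided,
    bayes_factor_two_sided_t,
    bh_adjust,
    between_group_comparisons,
    fit_participant_slopes,
    hodges_lehmann_ci_independent,
    hodges_lehmann_ci_paired,
    mixed_anova,
    normalize_pses,
    one_sample_comparison,
    planned_comparisons,
    rank_biserial_independent,
    rank_biserial_paired,
    rm_anova,
    signed_rank_statistic,
    two_sample_comparison,
)


def wide_table(data, index=None):
    df = pd.DataFrame(data, columns=list(REACHING_TYPES))
    df.index = index or [f"P{i}" for i in range(len(df))]
    df.index.name = "participant"
    return df


# ---------------------------------------------------------------------------
# manual ANOVA oracles


def manual_rm_anova(values):
    """Textbook one-way repeated-measures decomposition (uncorrected df)."""
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    grand = values.mean()
    ss_subj = k * ((values.mean(axis=1) - grand) ** 2).sum()
    ss_treat = n * ((values.mean(axis=0) - grand) ** 2).sum()
    ss_tot = ((values - grand) ** 2).sum()
    ss_err = ss_tot - ss_subj - ss_treat
    df_t, df_e = k - 1, (k - 1) * (n - 1)
    F = (ss_treat / df_t) / (ss_err / df_e)
    np2 = ss_treat / (ss_treat + ss_err)
    return F, df_t, df_e, np2


def manual_gg_epsilon(values):
    """Greenhouse-Geisser epsilon from the double-centered covariance."""
    values = np.asarray(values, dtype=float)
    k = values.shape[1]
    S = np.cov(values, rowvar=False)
    H = np.eye(k) - np.ones((k, k)) / k
    Sc = H @ S @ H
    lam = np.linalg.eigvalsh(Sc)
    return (lam.sum() ** 2) / ((k - 1) * (lam**2).sum())


def manual_mixed_anova(values_a, values_b):
    """Two-group x k-level mixed decomposition (uncorrected df)."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    k = a.shape[1]
    na, nb = a.shape[0], b.shape[0]
    n = na + nb
    all_v = np.vstack([a, b])
    grand = all_v.mean()
    subj_means = all_v.mean(axis=1)
    group_means = np.array([a.mean(), b.mean()])
    ss_between_subj = k * ((subj_means - grand) ** 2).sum()
    ss_group = k * (na * (a.mean() - grand) ** 2 + nb * (b.mean() - grand) ** 2)
    ss_subj_within = ss_between_subj - ss_group
    level_means = all_v.mean(axis=0)
    ss_time = n * ((level_means - grand) ** 2).sum()
    cell_a = a.mean(axis=0)
    cell_b = b.mean(axis=0)
    ss_cells = k * 0 + na * ((cell_a - grand) ** 2).sum() + nb * (
        (cell_b - grand) ** 2
    ).sum()
    ss_inter = ss_cells - ss_group - ss_time
    ss_tot = ((all_v - grand) ** 2).sum()
    ss_err = ss_tot - ss_between_subj - ss_time - ss_inter
    F_group = (ss_group / 1) / (ss_subj_within / (n - 2))
    F_time = (ss_time / (k - 1)) / (ss_err / ((k - 1) * (n - 2)))
    F_inter = (ss_inter / (k - 1)) / (ss_err / ((k - 1) * (n - 2)))
    return F_group, F_time, F_inter


class TestNormalize:
    def fits(self, rows):
        return pd.DataFrame(rows, columns=["participant", "trial_type", "pse"])

    def test_subtraction(self):
        rows = [("P1", t, 1.8) for t in REACHING_TYPES] + [("P1", "baseline", 2.0)]
        wide = normalize_pses(self.fits(rows))
        assert wide.loc["P1", "early"] == pytest.approx(-0.2)

    def test_equal_reaching_and_baseline_zero(self):
        rows = [("P1", t, 2.0) for t in REACHING_TYPES] + [("P1", "baseline", 2.0)]
        wide = normalize_pses(self.fits(rows))
        assert (wide.loc["P1", list(REACHING_TYPES)] == 0).all()

    def test_incomplete_participant_dropped(self):
        rows = [("P1", t, 2.0) for t in REACHING_TYPES] + [
            ("P1", "baseline", 2.0),
            ("P2", "early", 1.9),
            ("P2", "baseline", 2.0),
        ]
        wide = normalize_pses(self.fits(rows))
        assert list(wide.index) == ["P1"]


class TestRmAnova:
    def test_identical_levels_F_zero(self):
        wide = wide_table(np.tile(np.arange(1.0, 7.0)[:, None], (1, 5)))
        rep = rm_anova(wide)
        eff = rep["trial_type"]
        assert eff.F == 0.0 and eff.p == 1.0

    def test_two_levels_equals_squared_paired_t(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 12)
        b = a + rng.normal(0.4, 0.8, 12)
        wide = pd.DataFrame({"early": a, "mid": b})
        wide.index = [f"P{i}" for i in range(12)]
        wide.index.name = "participant"
        rep = rm_anova(wide, levels=["early", "mid"])
        t = sps.ttest_rel(a, b).statistic
        assert rep["trial_type"].F == pytest.approx(t**2, rel=1e-9)
        assert rep["trial_type"].epsilon == pytest.approx(1.0)

    def test_matches_manual_sums_of_squares(self):
        rng = np.random.default_rng(42)
        values = rng.integers(0, 10, size=(5, 4)).astype(float)
        wide = pd.DataFrame(values, columns=["early", "mid", "late", "target"])
        wide.index = [f"P{i}" for i in range(5)]
        wide.index.name = "participant"
        rep = rm_anova(wide, levels=["early", "mid", "late", "target"])
        F, df_t, df_e, np2 = manual_rm_anova(values)
        eps = manual_gg_epsilon(values)
        eff = rep["trial_type"]
        assert eff.F == pytest.approx(F, rel=1e-10)
        assert eff.partial_eta_sq == pytest.approx(np2, rel=1e-10)
        assert eff.epsilon == pytest.approx(eps, rel=1e-8)
        assert eff.df1 == pytest.approx(min(eps, 1.0) * df_t, rel=1e-8)
        assert eff.df2 == pytest.approx(min(eps, 1.0) * df_e, rel=1e-8)

    def test_gg_epsilon_bounds_random_draws(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            k = rng.integers(3, 6)
            values = rng.normal(size=(rng.integers(6, 15), k))
            eps = manual_gg_epsilon(values)
            cols = list(REACHING_TYPES[:k])
            wide = pd.DataFrame(values, columns=cols)
            wide.index = [f"P{i}" for i in range(len(values))]
            wide.index.name = "participant"
            rep = rm_anova(wide, levels=cols)
            assert 1.0 / (k - 1) - 1e-9 <= rep["trial_type"].epsilon <= 1.0 + 1e-9
            assert rep["trial_type"].epsilon == pytest.approx(min(eps, 1.0), rel=1e-6)

    def test_incomplete_design_rejected(self):
        wide = wide_table(np.ones((4, 5)))
        wide.iloc[1, 2] = np.nan
        with pytest.raises(StatsError):
            rm_anova(wide)


class TestMixedAnova:
    def make_wide(self, a, b):
        wa = wide_table(a, index=[f"A{i}" for i in range(len(a))])
        wb = wide_table(b, index=[f"B{i}" for i in range(len(b))])
        wa["group"] = "g1"
        wb["group"] = "g2"
        return pd.concat([wa, wb])

    def test_identical_groups_zero_F(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(8, 5))
        wide = self.make_wide(a, a.copy())
        rep = mixed_anova(wide)
        assert rep["group"].F == pytest.approx(0.0, abs=1e-10)
        assert rep["interaction"].F == pytest.approx(0.0, abs=1e-10)

    def test_matches_manual_decomposition(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 8, size=(5, 5)).astype(float)
        b = rng.integers(0, 8, size=(4, 5)).astype(float) + 1.0
        wide = self.make_wide(a, b)
        rep = mixed_anova(wide)
        F_group, F_time, F_inter = manual_mixed_anova(a, b)
        assert rep["group"].F == pytest.approx(F_group, rel=1e-9)
        assert rep["trial_type"].F == pytest.approx(F_time, rel=1e-9)
        assert rep["interaction"].F == pytest.approx(F_inter, rel=1e-9)


class TestPlannedComparisons:
    def test_bh_closed_form(self):
        p = np.array([0.01, 0.02, 0.03, 0.04, 0.05, 0.2, 0.9])
        # step-up: p_(i) * m / i, enforced monotone from the largest rank
        m = len(p)
        expected = p * m / np.arange(1, m + 1)
        for i in range(m - 2, -1, -1):
            expected[i] = min(expected[i], expected[i + 1])
        np.testing.assert_allclose(bh_adjust(p), expected)

    def test_bh_all_equal_unchanged(self):
        p = np.full(6, 0.04)
        np.testing.assert_allclose(bh_adjust(p), p)

    def test_bh_monotone_in_rank(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=15)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_identical_vectors_rank_path_p_one(self):
        x = np.array([0.3, -0.1, 0.2, 0.5, 0.0, 0.4])
        res = one_sample_comparison(x - x, "null")
        assert res.test_used == "wilcoxon_signed_rank"
        assert res.p_raw == 1.0 and res.effect_size == 0.0

    def test_normality_gate_selects_paths(self):
        rng = np.random.default_rng(3)
        gauss = rng.normal(0.2, 1.0, 40)
        assert sps.shapiro(gauss).pvalue >= 0.05
        res = one_sample_comparison(gauss, "gauss")
        assert res.test_used == "paired_t"
        heavy = sps.cauchy.rvs(size=40, random_state=np.random.RandomState(7))
        assert sps.shapiro(heavy).pvalue < 0.05
        res = one_sample_comparison(heavy, "heavy")
        assert res.test_used == "wilcoxon_signed_rank"

    def test_two_sample_gate(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 25)
        y = rng.normal(0.5, 1, 25)
        res = two_sample_comparison(x, y, "norm")
        assert res.test_used == "welch_t"
        assert res.df is not None and res.df != float(int(res.df))  # fractional
        heavy = sps.cauchy.rvs(size=25, random_state=np.random.RandomState(1))
        res = two_sample_comparison(heavy, y, "heavy")
        assert res.test_used == "rank_sum"

    def test_plan_runs_and_adjusts(self):
        rng = np.random.default_rng(8)
        wide = wide_table(rng.normal(size=(20, 5)))
        results = planned_comparisons(wide)
        assert len(results) == 7
        assert all(r.p_fdr >= r.p_raw - 1e-12 for r in results)

    def test_between_group_count(self):
        rng = np.random.default_rng(8)
        wa = wide_table(rng.normal(size=(12, 5)), [f"A{i}" for i in range(12)])
        wb = wide_table(rng.normal(size=(11, 5)), [f"B{i}" for i in range(11)])
        wa["group"] = "g1"
        wb["group"] = "g2"
        results = between_group_comparisons(pd.concat([wa, wb]))
        assert len(results) == 5


class TestRankStatistics:
    def test_signed_rank_positive_sum(self):
        d = np.array([1.0, 2.0, 3.0, -4.0])
        w, n = signed_rank_statistic(d)
        assert w == 6.0 and n == 4  # ranks 1+2+3 positive
        assert rank_biserial_paired(d) == pytest.approx(2 * 6 / 10 - 1)

    def test_rank_biserial_sign_matches_dominance(self):
        x = np.array([5.0, 6.0, 7.0])
        y = np.array([1.0, 2.0, 3.0])
        assert rank_biserial_independent(x, y) == 1.0
        assert rank_biserial_independent(y, x) == -1.0

    def test_rank_biserial_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            d = rng.normal(size=15)
            assert -1.0 <= rank_biserial_paired(d) <= 1.0

    def test_hodges_lehmann_matches_R_wilcox(self):
        # frozen from R stats::wilcox.test(x, conf.int=TRUE, exact=TRUE)
        x = np.array([0.12, -0.25, 0.31, 0.05, -0.11, 0.42, 0.27, -0.03,
                      0.18, 0.09, 0.33, -0.19, 0.22, 0.15])
        est, ci = hodges_lehmann_ci_paired(x)
        assert est == pytest.approx(0.12, abs=1e-9)
        assert ci[0] == pytest.approx(-0.010, abs=1e-9)
        assert ci[1] == pytest.approx(0.235, abs=1e-9)
        assert signed_rank_statistic(x)[0] == 82.0  # R's V statistic

    def test_hodges_lehmann_independent_matches_R(self):
        y = np.array([0.4, 0.1, -0.2, 0.5, 0.3, 0.0, 0.25, 0.6, -0.1, 0.35])
        z = np.array([0.1, -0.3, 0.2, -0.15, 0.05, -0.25, 0.3, -0.05, 0.0,
                      0.15, -0.4, 0.22])
        est, ci = hodges_lehmann_ci_independent(y, z)
        assert est == pytest.approx(0.25, abs=0.01)
        assert ci[0] == pytest.approx(0.0, abs=0.01)
        assert ci[1] == pytest.approx(0.45, abs=0.01)

    def test_cohens_d_sign_matches_mean_difference(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0.5, 1, 30)
        res = one_sample_comparison(x, "pos")
        assert res.test_used == "paired_t" and res.effect_size > 0
        res = one_sample_comparison(-x, "neg")
        assert res.effect_size < 0


class TestSlopes:
    def make_wide(self, slopes, pcts=(12.0, 36.0, 64.0)):
        rows = []
        for s in slopes:
            rows.append(
                {
                    "early": s * pcts[0], "mid": s * pcts[1], "late": s * pcts[2],
                    "target": s * 100.0, "post_reach": 0.0,
                    "pct_early": pcts[0], "pct_mid": pcts[1], "pct_late": pcts[2],
                }
            )
        wide = pd.DataFrame(rows, index=[f"P{i}" for i in range(len(slopes))])
        wide.index.name = "participant"
        return wide

    def test_constant_pse_zero_slope(self):
        wide = self.make_wide([0.0] * 5)
        res = fit_participant_slopes(wide)
        assert np.allclose(res.slopes["slope"], 0.0)

    def test_exact_line_recovered_to_machine_precision(self):
        wide = self.make_wide([-0.002] * 4)
        res = fit_participant_slopes(wide)
        np.testing.assert_allclose(res.slopes["slope"], -0.002, rtol=1e-12)

    def test_early_late_span_excludes_target(self):
        wide = self.make_wide([-0.002] * 4)
        wide["target"] = 5.0  # corrupt the target cell
        res = fit_participant_slopes(wide, span="early_late")
        np.testing.assert_allclose(res.slopes["slope"], -0.002, rtol=1e-12)

    def test_insufficient_points_dropped(self):
        wide = self.make_wide([-0.002] * 6)
        wide.loc["P0", ["pct_mid", "pct_late"]] = np.nan
        res = fit_participant_slopes(wide)
        assert "P0" not in set(res.slopes["participant"])
        assert len(res.slopes) == 5


class TestBayesFactor:
    def test_null_sample_supports_null(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 30)
        x = (x - x.mean()) / x.std(ddof=1)  # mean exactly 0, sd exactly 1
        bf, label = bayes_factor_one_sided(x, alternative="greater")
        assert bf > 1.0

    def test_matches_fine_grid_quadrature(self):
        x = np.array([0.3, -0.1, 0.2, 0.6, 0.1, -0.2, 0.4, 0.0, 0.25, 0.5,
                      -0.05, 0.35])
        n = x.size
        t = x.mean() / (x.std(ddof=1) / np.sqrt(n))
        # independent trapezoid quadrature of the same marginal likelihood
        delta = np.linspace(1e-6, 60.0, 400_001)
        integrand = sps.nct.pdf(t, n - 1, delta * np.sqrt(n)) * 2 * sps.cauchy.pdf(
            delta, scale=0.707
        )
        m1 = np.trapezoid(integrand, delta)
        expected = sps.t.pdf(t, n - 1) / m1
        bf, _ = bayes_factor_one_sided(x, alternative="greater")
        assert bf == pytest.approx(expected, rel=1e-3)

    def test_one_sided_halves_combine_to_two_sided(self):
        # m1(two-sided) = (m1(+) + m1(-)) / 2, so
        # 1/BF0+ + 1/BF0- = 2 * BF10(two-sided)
        rng = np.random.default_rng(1)
        x = rng.normal(0.3, 1, 20)
        n = x.size
        t = x.mean() / (x.std(ddof=1) / np.sqrt(n))
        bf_plus, _ = bayes_factor_one_sided(x, alternative="greater")
        bf_minus, _ = bayes_factor_one_sided(x, alternative="less")
        bf10 = bayes_factor_two_sided_t(t, n)
        assert 1 / bf_plus + 1 / bf_minus == pytest.approx(2 * bf10, rel=1e-6)

    def test_two_sided_matches_pingouin(self):
        import pingouin as pg

        for t, n in [(2.1, 29), (0.5, 15), (-1.7, 40)]:
            mine = bayes_factor_two_sided_t(t, n)
            theirs = float(pg.bayesfactor_ttest(t, n, paired=True, r=0.707))
            assert mine == pytest.approx(theirs, rel=1e-4)

    def test_zero_variance_rejected(self):
        with pytest.raises(StatsError):
            bayes_factor_one_sided(np.ones(10))

    def test_evidence_bands(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 50)
        x = (x - x.mean()) / x.std(ddof=1)
        bf, label = bayes_factor_one_sided(x, alternative="greater")
        assert label in ("anecdotal", "moderate", "strong")
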