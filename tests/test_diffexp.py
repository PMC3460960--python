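"""Differential-expression statistics against independent oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from bloodmirna.diffexp import (
    ModeratedPrior,
    benjamini_hochberg,
    cohort_summary_tests,
    diffexp_table,
    display_fold,
    fisher_exact_2x2,
    fit_moderated_prior,
    fold_changes,
    moderated_t,
    pooled_t_from_summaries,
    trigamma_inverse,
    wilcoxon_table,
)
from bloodmirna.errors import ContentError


class TestModeratedPrior:
    def test_equal_variances_give_infinite_d0(self):
        prior = fit_moderated_prior(np.full(100, 0.05), residual_df=43)
        assert math.isinf(prior.d0)
        # s0^2 equals the common value up to the e^{log(d/2)-psi(d/2)} ~ 1+1/d factor
        assert prior.s0_sq == pytest.approx(0.05, rel=0.05)

    def test_parameter_recovery(self):
        """d0=4, s0^2=0.05 recovered from 2000 genes at df=43."""
        rng = np.random.default_rng(5)
        d0, s0_sq, df, n = 4.0, 0.05, 43, 2000
        true_var = s0_sq * d0 / rng.chisquare(d0, n)  # scaled inverse-chi-square
        s2 = true_var * rng.chisquare(df, n) / df
        prior = fit_moderated_prior(s2, df)
        assert abs(prior.d0 - d0) <= 1.0
        assert abs(prior.s0_sq - s0_sq) / s0_sq < 0.10

    def test_moment_self_consistency(self):
        """Plugging the estimate back reproduces the observed log-s2 moments."""
        rng = np.random.default_rng(6)
        d0, s0_sq, df, n = 6.0, 0.1, 20, 4000
        true_var = s0_sq * d0 / rng.chisquare(d0, n)
        s2 = true_var * rng.chisquare(df, n) / df
        prior = fit_moderated_prior(s2, df)
        z = np.log(s2)
        theo_mean = (
            math.log(prior.s0_sq)
            + special.digamma(df / 2)
            - math.log(df / 2)
            - special.digamma(prior.d0 / 2)
            + math.log(prior.d0 / 2)
        )
        theo_var = special.polygamma(1, df / 2) + special.polygamma(1, prior.d0 / 2)
        mc_se_mean = math.sqrt(theo_var / n)
        assert abs(z.mean() - theo_mean) < 4 * mc_se_mean
        assert abs(z.var(ddof=1) - theo_var) / theo_var < 0.15

    def test_trigamma_inverse_round_trip(self):
        for y in (1e-4, 0.01, 0.5, 2.0, 50.0):
            x = trigamma_inverse(y)
            assert special.polygamma(1, x) == pytest.approx(y, rel=1e-6)

    def test_nonpositive_variances_rejected(self):
        with pytest.raises(ContentError):
            fit_moderated_prior(np.array([0.1] * 9 + [0.0, 0.2]), 10)


class TestModeratedT:
    def test_zero_d0_reduces_to_ordinary_pooled_t(self, random_log2_matrix, balanced_classes):
        prior = ModeratedPrior(d0=0.0, s0_sq=1.0)
        table = moderated_t(random_log2_matrix, balanced_classes, prior)
        x = random_log2_matrix.to_numpy()
        case = x[:, balanced_classes == "case"]
        ctrl = x[:, balanced_classes == "control"]
        ref = stats.ttest_ind(case, ctrl, axis=1, equal_var=True)
        np.testing.assert_allclose(table["moderated_t"], ref.statistic, rtol=1e-10)
        np.testing.assert_allclose(table["p"], ref.pvalue, rtol=1e-10)

    def test_infinite_d0_fixed_variance_limit(self, random_log2_matrix, balanced_classes):
        s0_sq = 0.8
        prior = ModeratedPrior(d0=math.inf, s0_sq=s0_sq)
        table = moderated_t(random_log2_matrix, balanced_classes, prior)
        x = random_log2_matrix.to_numpy()
        diff = x[:, :12].mean(axis=1) - x[:, 12:].mean(axis=1)
        expected = diff / (math.sqrt(s0_sq) * math.sqrt(1 / 12 + 1 / 12))
        np.testing.assert_allclose(table["moderated_t"], expected, rtol=1e-12)

    def test_identical_group_means_give_t0_p1(self, balanced_classes):
        base = np.random.default_rng(0).normal(size=(5, 12))
        matrix = pd.DataFrame(np.hstack([base, base]))
        table = moderated_t(matrix, balanced_classes, ModeratedPrior(0.0, 1.0))
        np.testing.assert_allclose(table["moderated_t"], 0.0, atol=1e-12)
        np.testing.assert_allclose(table["p"], 1.0)

    def test_interpolates_between_limits(self, random_log2_matrix, balanced_classes):
        """|t| moves monotonically from the pooled t toward the fixed-variance z."""
        probe = random_log2_matrix.iloc[[0]]
        s0_sq = 2.0
        tvals = []
        for d0 in (0.0, 1.0, 10.0, 1e6):
            t = moderated_t(probe, balanced_classes, ModeratedPrior(d0, s0_sq))[
                "moderated_t"
            ].iloc[0]
            tvals.append(t)
        diffs = np.diff(tvals)
        assert (diffs >= -1e-12).all() or (diffs <= 1e-12).all()

    def test_small_class_rejected(self, random_log2_matrix):
        classes = np.array(["case"] + ["control"] * 23)
        with pytest.raises(ContentError):
            moderated_t(random_log2_matrix, classes)


class TestBenjaminiHochberg:
    def test_single_p(self):
        assert benjamini_hochberg(np.array([0.037]))[0] == pytest.approx(0.037)

    def test_hand_computed_step_up(self):
        q = benjamini_hochberg(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 100000), n=st.integers(1, 60))
    def test_matches_independent_step_up(self, seed, n):
        p = np.random.default_rng(seed).random(n)
        ours = benjamini_hochberg(p)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ContentError):
            benjamini_hochberg(np.array([0.5, 1.2]))


class TestWilcoxon:
    def test_exact_small_sample(self):
        matrix = pd.DataFrame([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]])
        classes = np.array(["case"] * 3 + ["control"] * 3)
        p = wilcoxon_table(matrix, classes).iloc[0]
        assert p == pytest.approx(0.1)

    def test_identical_samples_p1(self):
        matrix = pd.DataFrame([[5.0, 5.0, 5.0, 5.0, 5.0, 5.0]])
        classes = np.array(["case"] * 3 + ["control"] * 3)
        assert wilcoxon_table(matrix, classes).iloc[0] == pytest.approx(1.0)

    def test_normal_approximation_close_to_exact(self, rng):
        x = rng.normal(size=(40, 16))
        matrix = pd.DataFrame(x)
        classes = np.array(["case"] * 8 + ["control"] * 8)
        exact = wilcoxon_table(matrix, classes)
        approx = pd.Series(
            [
                stats.mannwhitneyu(
                    row[:8], row[8:], alternative="two-sided", method="asymptotic"
                ).pvalue
                for row in x
            ],
            index=matrix.index,
        )
        # the continuity-corrected normal approximation agrees with the exact
        # enumeration to ~0.01 at n=8/8 (worst case just above)
        assert (exact - approx).abs().max() < 0.02


class TestFoldChanges:
    @pytest.mark.parametrize(
        "mean_case,mean_control,expected",
        [
            (143.57, 267.88, 0.54),  # strongest under-expression row
            (211.82, 133.2, 1.59),  # strongest over-expression row
            (277.69, 185.25, 1.50),
            (172.56, 312.48, 0.55),
            (100.0, 100.0, 1.00),
        ],
    )
    def test_printed_group_means_reproduce_fold(self, mean_case, mean_control, expected):
        matrix = pd.DataFrame(
            [[mean_case] * 2 + [mean_control] * 2], index=["probe"],
        )
        classes = np.array(["case", "case", "control", "control"])
        fc = fold_changes(matrix, classes).iloc[0]
        assert display_fold(fc) == pytest.approx(expected)

    def test_zero_control_mean_rejected(self):
        matrix = pd.DataFrame([[1.0, 1.0, 0.0, 0.0]])
        classes = np.array(["case", "case", "control", "control"])
        with pytest.raises(ContentError):
            fold_changes(matrix, classes)


class TestCohortTests:
    def test_wbc_pooled_t_from_printed_summaries(self):
        """n=22, 6.7(1.8) vs n=17, 7.7(2.7) gives two-sided p ~ 0.17."""
        t, df, p = pooled_t_from_summaries(22, 6.7, 1.8, 17, 7.7, 2.7)
        assert df == 37
        assert p == pytest.approx(0.17, abs=0.005)

    def test_identical_groups_p1(self):
        t, _, p = pooled_t_from_summaries(10, 5.0, 1.0, 10, 5.0, 1.0)
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_fisher_matches_hypergeometric_enumeration(self):
        table = [[12, 10], [12, 11]]
        ours = fisher_exact_2x2(table)
        # exhaustive enumeration over all tables with the same margins
        r1, r2 = 22, 23
        c1 = 24
        n = r1 + r2
        probs = {
            a: stats.hypergeom.pmf(a, n, r1, c1)
            for a in range(max(0, c1 - r2), min(r1, c1) + 1)
        }
        obs = probs[12]
        expected = sum(p for p in probs.values() if p <= obs * (1 + 1e-12))
        assert ours == pytest.approx(expected, rel=1e-9)

    def test_cohort_table_on_synthetic_sheet(self, small_dataset):
        result = cohort_summary_tests(small_dataset.sample_sheet)
        assert set(result["variable"]) >= {"age", "gender", "smoking", "wbc"}
        age_p = result.loc[result["variable"] == "age", "p"].iloc[0]
        assert age_p < 0.01  # planted 10.7-year mean difference


class TestDiffexpTable:
    def test_columns_and_invariants(self, small_pipeline):
        dataset, matrix, _ = small_pipeline
        expr = matrix.expressed()
        table = diffexp_table(expr.values, dataset.sample_sheet.classes)
        assert {"mean_case", "sd_case", "fold_change", "moderated_t", "p", "q",
                "wilcoxon_p"} <= set(table.columns)
        assert (table["fold_change"] > 0).all()
        assert table["q"].between(0, 1).all()
        # q monotone non-decreasing in p-rank
        ordered = table.sort_values("p")
        assert (np.diff(ordered["q"].to_numpy()) >= -1e-12).all()

    def test_strong_planted_effects_found_by_both_tests(self, null_pipeline, rng):
        """Moderated-t and rank-sum discovery sets overlap >=90% on strong effects."""
        dataset, matrix, _ = null_pipeline
        expr = matrix.expressed()
        values = expr.values.copy()
        classes = dataset.sample_sheet.classes
        planted = list(values.index[:25])
        folds = np.exp2(rng.uniform(1.0, 1.6, 25))  # 2x-3x effects
        values.loc[planted, classes == "case"] = values.loc[
            planted, classes == "case"
        ].mul(folds, axis=0)
        table = diffexp_table(values, classes)
        found_t = set(table.index[table["q"] < 0.05])
        found_w = set(table.index[table["wilcoxon_q"] < 0.05])
        assert len(found_t & set(planted)) >= 20
        assert len(found_t & found_w) / len(found_t) >= 0.9
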