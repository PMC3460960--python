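"""ROC/DeLong, covariate profiling, clustering, concordance oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.cluster import hierarchy

from bloodmirna.errors import ContentError
from bloodmirna.evaluate import (
    analytic_null_flagged_fraction,
    correlate_covariate,
    correlation_distance_matrix,
    delong_compare,
    hierarchical_cluster,
    platform_concordance,
    resample_covariate_null,
    roc_auc,
)


class TestRocAuc:
    def test_perfect_separation(self):
        scores = [1, 2, 3, 10, 11, 12]
        labels = ["control"] * 3 + ["case"] * 3
        r = roc_auc(scores, labels)
        assert r.auc == 1.0
        assert r.fpr[0] == 0.0 and r.tpr[-1] == 1.0

    def test_all_ties_auc_half(self):
        r = roc_auc([5.0] * 8, ["case"] * 4 + ["control"] * 4)
        assert r.auc == 0.5

    def test_matches_pairwise_enumeration(self, rng):
        for _ in range(10):
            scores = rng.normal(size=30)
            labels = np.where(rng.random(30) < 0.5, "case", "control")
            if len(set(labels)) < 2:
                continue
            r = roc_auc(scores, labels)
            cases = scores[labels == "case"]
            ctrls = scores[labels == "control"]
            u = sum(
                1.0 if c > k else (0.5 if c == k else 0.0)
                for c, k in itertools.product(cases, ctrls)
            )
            assert r.auc == pytest.approx(u / (len(cases) * len(ctrls)), abs=1e-12)

    def test_curve_endpoints_and_monotone(self, rng):
        scores = rng.normal(size=50)
        labels = np.array(["case"] * 25 + ["control"] * 25)
        r = roc_auc(scores, labels)
        assert (r.fpr[0], r.tpr[0]) == (0.0, 0.0)
        assert (r.fpr[-1], r.tpr[-1]) == (1.0, 1.0)
        assert (np.diff(r.fpr) >= 0).all() and (np.diff(r.tpr) >= 0).all()

    def test_single_class_rejected(self):
        with pytest.raises(ContentError):
            roc_auc([1, 2, 3], ["case"] * 3)


class TestDeLong:
    def test_self_comparison_p1(self, rng):
        scores = rng.normal(size=40)
        labels = np.array(["case"] * 18 + ["control"] * 22)
        out = delong_compare(scores, scores, labels)
        assert out["delta"] == 0.0
        assert out["p"] == 1.0

    def test_symmetry(self, rng):
        a = rng.normal(size=40)
        b = rng.normal(size=40)
        labels = np.array(["case"] * 20 + ["control"] * 20)
        ab = delong_compare(a, b, labels)
        ba = delong_compare(b, a, labels)
        assert ab["p"] == pytest.approx(ba["p"], abs=1e-12)
        assert ab["delta"] == pytest.approx(-ba["delta"], abs=1e-12)

    def test_variance_nonnegative_many_draws(self, rng):
        labels = np.array(["case"] * 10 + ["control"] * 10)
        for _ in range(50):
            out = delong_compare(rng.normal(size=20), rng.normal(size=20), labels)
            assert out["ci_high"] >= out["ci_low"]

    def test_agrees_with_bootstrap(self):
        """DeLong p within 0.02 of a 10^4-replicate paired bootstrap (n=100)."""
        rng = np.random.default_rng(7)
        n = 100
        labels = np.array(["case"] * 50 + ["control"] * 50)
        truth = (labels == "case").astype(float)
        a = truth * 1.0 + rng.normal(0, 1.0, n)
        b = truth * 0.7 + rng.normal(0, 1.0, n)
        out = delong_compare(a, b, labels)

        def quick_auc(sa, lab):
            pos = sa[lab]
            neg = sa[~lab]
            return (
                (neg[None, :] < pos[:, None]).sum()
                + 0.5 * (neg[None, :] == pos[:, None]).sum()
            ) / (len(pos) * len(neg))

        is_case = labels == "case"
        deltas = np.empty(10_000)
        for i in range(10_000):
            idx = rng.integers(0, n, n)
            lab = is_case[idx]
            if lab.all() or not lab.any():
                deltas[i] = np.nan
                continue
            deltas[i] = quick_auc(a[idx], lab) - quick_auc(b[idx], lab)
        deltas = deltas[~np.isnan(deltas)]
        se = deltas.std(ddof=1)
        z = (out["auc_a"] - out["auc_b"]) / se
        boot_p = 2 * stats.norm.sf(abs(z))
        assert abs(out["p"] - boot_p) < 0.02

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ContentError):
            delong_compare([1, 2], [1, 2, 3], ["case", "control", "case"])


class TestCovariateCorrelation:
    def test_probe_equal_to_covariate_flagged(self, random_log2_matrix):
        cov = pd.Series(
            random_log2_matrix.iloc[0].to_numpy(), index=random_log2_matrix.columns
        )
        profile = correlate_covariate(random_log2_matrix, cov)
        assert profile.r.iloc[0] == pytest.approx(1.0)
        assert random_log2_matrix.index[0] in profile.flagged

    def test_affine_rescaling_invariant(self, random_log2_matrix):
        cov = pd.Series(
            np.linspace(30, 80, random_log2_matrix.shape[1]),
            index=random_log2_matrix.columns,
        )
        p1 = correlate_covariate(random_log2_matrix, cov)
        p2 = correlate_covariate(random_log2_matrix, 3.0 * cov - 17.0)
        pd.testing.assert_series_equal(p1.r, p2.r)

    def test_null_flagged_fraction_matches_analytic(self):
        """Null |r|>0.4 rate at n=39 is ~1.2-1.3%, matching the t-transform."""
        analytic = analytic_null_flagged_fraction(0.4, 39)
        assert 0.008 < analytic < 0.016
        rng = np.random.default_rng(3)
        fractions = []
        for rep in range(100):
            matrix = pd.DataFrame(
                rng.normal(size=(395, 39)),
                columns=[f"s{i}" for i in range(39)],
            )
            cov = pd.Series(rng.normal(size=39), index=matrix.columns)
            fractions.append(correlate_covariate(matrix, cov).flagged_fraction)
        mc_mean = np.mean(fractions)
        mc_se = np.std(fractions, ddof=1) / 10
        assert abs(mc_mean - analytic) < 4 * mc_se + 1e-4

    def test_pairwise_complete_n(self, random_log2_matrix):
        cov = pd.Series(
            np.linspace(1, 10, random_log2_matrix.shape[1]),
            index=random_log2_matrix.columns,
        )
        cov.iloc[:5] = np.nan
        profile = correlate_covariate(random_log2_matrix, cov)
        assert profile.n_used == random_log2_matrix.shape[1] - 5

    def test_constant_covariate_rejected(self, random_log2_matrix):
        cov = pd.Series(5.0, index=random_log2_matrix.columns)
        with pytest.raises(ContentError):
            correlate_covariate(random_log2_matrix, cov)


class TestResampledNull:
    def test_seeded_reproducible(self, random_log2_matrix):
        cov = pd.Series(
            np.linspace(30, 80, random_log2_matrix.shape[1]),
            index=random_log2_matrix.columns,
        )
        a = resample_covariate_null(random_log2_matrix, cov, n_reps=20, seed=9)
        b = resample_covariate_null(random_log2_matrix, cov, n_reps=20, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_planted_association_exceeds_null(self, small_pipeline):
        dataset, matrix, _ = small_pipeline
        expr = matrix.expressed()
        age = dataset.ground_truth.ages
        observed = correlate_covariate(expr.log2, age).flagged_fraction
        null = resample_covariate_null(expr.log2, age, n_reps=60, seed=4)
        assert observed > np.percentile(null, 95)

    def test_null_mean_matches_analytic(self, rng):
        matrix = pd.DataFrame(
            rng.normal(size=(300, 39)), columns=[f"s{i}" for i in range(39)]
        )
        cov = pd.Series(rng.normal(size=39), index=matrix.columns)
        null = resample_covariate_null(matrix, cov, n_reps=80, seed=11)
        analytic = analytic_null_flagged_fraction(0.4, 39)
        se = null.std(ddof=1) / math.sqrt(len(null))
        assert abs(null.mean() - analytic) < max(2 * se, 5e-3)


def _brute_force_average_linkage(dist):
    """Naive agglomeration: merge the closest clusters, average distance."""
    clusters = {i: [i] for i in range(dist.shape[0])}
    heights = []
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for a, b in itertools.combinations(keys, 2):
            d = np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or d < best[0] - 1e-15:
                best = (d, a, b)
        d, a, b = best
        heights.append(d)
        new_key = max(clusters) + 1
        clusters[new_key] = clusters.pop(a) + clusters.pop(b)
    return np.array(heights)


class TestClustering:
    def test_duplicate_sample_merges_first_at_zero(self, rng):
        x = rng.normal(size=(10, 5))
        x[:, 4] = x[:, 3] * 2.0 + 1.0  # perfectly correlated duplicate
        matrix = pd.DataFrame(x, columns=[f"s{i}" for i in range(5)])
        d = hierarchical_cluster(matrix, axis="samples")
        assert d.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
        merged = {int(d.linkage[0, 0]), int(d.linkage[0, 1])}
        assert merged == {3, 4}

    def test_merge_heights_match_brute_force(self, rng):
        x = rng.normal(size=(12, 6))
        matrix = pd.DataFrame(x, columns=[f"s{i}" for i in range(6)])
        d = hierarchical_cluster(matrix, axis="samples")
        brute = _brute_force_average_linkage(d.distance)
        np.testing.assert_allclose(np.sort(d.merge_heights()), np.sort(brute), atol=1e-12)

    def test_leaf_order_objective_not_worse_than_input(self, rng):
        x = rng.normal(size=(15, 9))
        matrix = pd.DataFrame(x, columns=[f"s{i}" for i in range(9)])
        d = hierarchical_cluster(matrix, axis="samples")
        default = hierarchy.leaves_list(hierarchy.average(
            d.distance[np.triu_indices(9, k=1)]
        ))
        assert d.adjacent_distance_sum() <= d.adjacent_distance_sum(default) + 1e-12

    def test_affine_profile_invariance(self, rng):
        x = rng.normal(size=(10, 6))
        m1 = pd.DataFrame(x, columns=list("abcdef"))
        m2 = pd.DataFrame(x * 3.5 - 7.0, columns=list("abcdef"))
        d1 = hierarchical_cluster(m1, axis="samples")
        d2 = hierarchical_cluster(m2, axis="samples")
        np.testing.assert_allclose(d1.merge_heights(), d2.merge_heights(), atol=1e-12)

    def test_constant_profile_gets_max_distance(self, rng):
        x = rng.normal(size=(8, 4))
        x[:, 0] = 2.0
        matrix = pd.DataFrame(x, columns=list("wxyz"))
        with pytest.warns(UserWarning, match="constant"):
            d = hierarchical_cluster(matrix, axis="samples")
        assert (d.distance[0, 1:] == 2.0).all()

    def test_newick_output_parses(self, rng):
        x = rng.normal(size=(10, 5))
        matrix = pd.DataFrame(x, columns=[f"s{i}" for i in range(5)])
        d = hierarchical_cluster(matrix, axis="samples")
        text = d.to_newick()
        assert text.endswith(";")
        for label in matrix.columns:
            assert label in text


class TestPlatformConcordance:
    def test_exact_inverse_linearity(self):
        sig = np.linspace(4, 10, 11)
        cq = 38.0 - 1.1 * sig
        out = platform_concordance(cq, sig)
        assert out["r"] == pytest.approx(-1.0)

    def test_identical_series_amplification_one(self):
        sig = np.linspace(4, 10, 8)
        out = platform_concordance(sig, sig)
        assert out["range_amplification"] == pytest.approx(1.0)

    def test_fisher_ci_close_to_bootstrap(self):
        rng = np.random.default_rng(12)
        sig = rng.normal(7, 1.5, 11)
        cq = 36 - 2.0 * sig + rng.normal(0, 1.0, 11)
        out = platform_concordance(cq, sig)
        rs = []
        for _ in range(10_000):
            idx = rng.integers(0, 11, 11)
            if np.ptp(sig[idx]) == 0:
                continue
            rs.append(stats.pearsonr(cq[idx], sig[idx]).statistic)
        lo, hi = np.percentile(rs, [2.5, 97.5])
        assert abs(out["ci_low"] - lo) < 0.12
        assert abs(out["ci_high"] - hi) < 0.12

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ContentError):
            platform_concordance([30.0, 31.0], [5.0, 6.0])
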