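"""PCA reduction, gap statistic, k-means, MANOVA/ANOVA, robustness loop."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ssmap import (anova_subscores, gap_statistic, kmeans_cluster,
                   manova_profiles, pca_reduce, robustness_simulation)
from ssmap.clustering import ANOVA_TARGETS, ClusterSolution, SUBSCORES
from ssmap.types import DEFAULT_FREQS, CohortStack


def make_stack(data):
    ns = data.shape[0]
    return CohortStack(data, [f"S{i}" for i in range(ns)],
                       [f"c{i}" for i in range(data.shape[1])],
                       DEFAULT_FREQS[:data.shape[2]])


def clin_for_labels(labels, shift=0.0, seed=0):
    """Clinical frame whose sub-score means shift with the (1-based) labels."""
    rng = np.random.default_rng(seed)
    n = labels.size
    df = pd.DataFrame({"subject_id": [f"S{i}" for i in range(n)],
                       "age": rng.normal(60, 8, n),
                       "years_dx": rng.normal(8, 3, n),
                       "updrs_total": rng.normal(35, 5, n)})
    for c in SUBSCORES:
        df[c] = rng.normal(8, 2, n) + shift * (labels - 1)
    return df


def blobs(k, n_per, sep, dim=3, seed=0):
    rng = np.random.default_rng(seed)
    centers = rng.normal(scale=sep, size=(k, dim))
    pts = np.concatenate([centers[i] + rng.normal(size=(n_per, dim)) for i in range(k)])
    labels = np.repeat(np.arange(1, k + 1), n_per)
    return pts, labels


class TestPca:
    def test_rank1_cohort_single_component(self):
        rng = np.random.default_rng(0)
        direction = rng.normal(size=21)
        data = (rng.normal(size=(20, 1)) * direction[None]).reshape(20, 3, 7)
        red = pca_reduce(make_stack(data), var_target=0.80)
        assert red.scores.shape[1] == 1
        assert red.explained_ratio[0] == pytest.approx(1.0)

    def test_matches_eigendecomposition_crossing(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(75, 60)) * np.linspace(3, 0.2, 60)[None]
        red = pca_reduce(make_stack(X.reshape(75, 6, 10)), var_target=0.80)
        C = np.cov(X.T)
        ev = np.sort(np.linalg.eigvalsh(C))[::-1]
        expect = int(np.searchsorted(np.cumsum(ev) / ev.sum(), 0.80) + 1)
        assert red.scores.shape[1] == expect

    def test_var_target_one_keeps_everything_nondegenerate(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 4, 6))
        red = pca_reduce(make_stack(X), var_target=1.0)
        assert red.scores.shape[1] == 9  # n-1 nonzero directions

    def test_bad_target_rejected(self):
        with pytest.raises(ValueError):
            pca_reduce(make_stack(np.zeros((5, 2, 3))), var_target=0.0)


class TestGap:
    def test_recovers_three_blobs(self):
        hits = 0
        for seed in range(10):
            pts, _ = blobs(3, 25, sep=10.0, seed=seed)
            hits += gap_statistic(pts, k_max=10, b_ref=20, seed=seed).k_star == 3
        assert hits >= 9

    def test_single_gaussian_prefers_k1(self):
        hits = 0
        for seed in range(10):
            pts = np.random.default_rng(seed).normal(size=(60, 3))
            hits += gap_statistic(pts, k_max=10, b_ref=20, seed=seed).k_star == 1
        assert hits >= 7

    def test_k_grid_bound_honored(self):
        pts, _ = blobs(4, 12, sep=6.0, seed=3)
        curve = gap_statistic(pts, k_max=10, b_ref=10, seed=0)
        assert 1 <= curve.k_star <= 10

    def test_same_seed_reproducible(self):
        pts, _ = blobs(2, 20, sep=5.0, seed=4)
        a = gap_statistic(pts, b_ref=15, seed=5)
        b = gap_statistic(pts, b_ref=15, seed=5)
        assert np.array_equal(a.gap, b.gap) and a.k_star == b.k_star

    def test_degenerate_scores_rejected(self):
        with pytest.raises(ValueError):
            gap_statistic(np.ones((30, 2)), k_max=5)


class TestKmeans:
    def test_separable_blobs_recovered(self):
        pts, labels = blobs(2, 20, sep=12.0, seed=6)
        sol = kmeans_cluster(pts, 2, seed=0)
        # agreement up to relabeling
        agree = max((sol.labels == labels).mean(), (sol.labels == 3 - labels).mean())
        assert agree == 1.0

    def test_k1_inertia_is_total_dispersion(self):
        pts = np.random.default_rng(7).normal(size=(30, 4))
        sol = kmeans_cluster(pts, 1, seed=0)
        assert sol.inertia == pytest.approx(((pts - pts.mean(0)) ** 2).sum(), rel=1e-9)

    def test_beats_random_assignments(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(40, 3))
        sol = kmeans_cluster(pts, 4, seed=1)
        for _ in range(100):
            lab = rng.integers(0, 4, size=40)
            inertia = sum(((pts[lab == c] - pts[lab == c].mean(0)) ** 2).sum()
                          for c in range(4) if (lab == c).any())
            assert sol.inertia <= inertia + 1e-9


class TestManovaAnova:
    def test_null_p_uniform(self):
        ps = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            labels = rng.integers(1, 4, size=60)
            sol = ClusterSolution(3, labels, np.zeros((3, 2)), 0.0, seed)
            ps.append(manova_profiles(sol, clin_for_labels(labels, shift=0.0, seed=seed)))
        ks = stats.kstest(ps, "uniform").statistic
        assert ks < 0.12

    def test_separated_profiles_significant(self):
        rng = np.random.default_rng(9)
        labels = np.repeat([1, 2], 30)
        sol = ClusterSolution(2, labels, np.zeros((2, 2)), 0.0, 0)
        clin = clin_for_labels(labels, shift=6.0, seed=10)  # 3 sigma separation
        assert manova_profiles(sol, clin) < 0.001

    def test_k1_returns_one(self):
        labels = np.ones(20, dtype=int)
        sol = ClusterSolution(1, labels, np.zeros((1, 2)), 0.0, 0)
        assert manova_profiles(sol, clin_for_labels(labels)) == 1.0

    def test_anova_flags_only_planted_target(self):
        rng = np.random.default_rng(11)
        labels = np.repeat([1, 2], 40)
        clin = clin_for_labels(labels, shift=0.0, seed=12)
        clin["tremor_contra"] += 4.0 * (labels - 1)
        sol = ClusterSolution(2, labels, np.zeros((2, 2)), 0.0, 0)
        tbl = anova_subscores(sol, clin)
        assert tbl.set_index("target").loc["tremor_contra", "p"] == tbl["p"].min()
        assert tbl.set_index("target").loc["tremor_contra", "sig"]

    def test_anova_null_rarely_significant_post_fdr(self):
        # P(any BH discovery among the 9 targets) under a global null is the
        # Simes level (~alpha); allow three binomial SDs above nominal
        sig = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            labels = rng.integers(1, 3, size=50)
            sol = ClusterSolution(2, labels, np.zeros((2, 2)), 0.0, seed)
            tbl = anova_subscores(sol, clin_for_labels(labels, shift=0.0, seed=seed))
            sig += tbl["sig"].any()
        assert sig <= 12

    def test_identical_groups_degenerate_p_one(self):
        labels = np.repeat([1, 2], 10)
        clin = clin_for_labels(labels, seed=13)
        for c in SUBSCORES + ["updrs_total", "age", "years_dx"]:
            clin[c] = 5.0
        sol = ClusterSolution(2, labels, np.zeros((2, 2)), 0.0, 0)
        tbl = anova_subscores(sol, clin)
        assert np.all(tbl["p"] == 1.0)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(14)
        labels = np.repeat([1, 2, 3], 15)
        clin = clin_for_labels(labels, shift=2.0, seed=15)
        sol1 = ClusterSolution(3, labels, np.zeros((3, 2)), 0.0, 0)
        relabel = np.array([0, 3, 1, 2])[labels]  # 1->3, 2->1, 3->2
        sol2 = ClusterSolution(3, relabel, np.zeros((3, 2)), 0.0, 0)
        assert manova_profiles(sol1, clin) == pytest.approx(manova_profiles(sol2, clin))
        t1 = anova_subscores(sol1, clin)["p"].to_numpy()
        t2 = anova_subscores(sol2, clin)["p"].to_numpy()
        assert np.allclose(t1, t2)


class TestRobustness:
    def test_single_iteration_reduces_to_one_run(self):
        pts, labels = blobs(2, 20, sep=10.0, seed=16)
        clin = clin_for_labels(labels, shift=5.0, seed=17)
        rep = robustness_simulation(pts, clin, n_iter=1, k_range=[2], seed=18)
        vals = rep.pct_significant["pct_significant"]
        assert set(vals.unique()) <= {0.0, 100.0}

    def test_planted_coupling_mostly_significant(self):
        pts, labels = blobs(2, 25, sep=12.0, seed=19)
        clin = clin_for_labels(labels, shift=5.0, seed=20)
        rep = robustness_simulation(pts, clin, n_iter=30, k_range=[2], seed=21)
        df = rep.pct_significant.set_index(["k", "test"])
        assert df.loc[(2, "manova"), "pct_significant"] >= 62.0

    def test_null_coupling_rarely_significant(self):
        pts, labels = blobs(2, 25, sep=12.0, seed=22)
        clin = clin_for_labels(labels, shift=0.0, seed=23)
        rep = robustness_simulation(pts, clin, n_iter=40, k_range=[2], seed=24)
        df = rep.pct_significant.set_index(["k", "test"])
        assert df.loc[(2, "manova"), "pct_significant"] <= 15.0
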