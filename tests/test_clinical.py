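"""Map-to-symptom linkage: regression, hotspots, feature selection, PLS."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ssmap import (CohortSpec, Hotspot, clinical_correlation_map,
                   compare_top_bottom, pixel_multiple_regression, pls_fit,
                   pls_permutation_validate, select_variance_pixels,
                   simulate_map_cohort, variance_hotspot_test)
from ssmap.clinical import CLINICAL_PREDICTORS
from ssmap.types import DEFAULT_FREQS, CohortStack

F = DEFAULT_FREQS


def make_stack(data):
    ns = data.shape[0]
    return CohortStack(data, [f"S{i+1:03d}" for i in range(ns)],
                       [f"c{i}" for i in range(data.shape[1])], F[:data.shape[2]])


def clin_frame(n, rng):
    df = pd.DataFrame({"subject_id": [f"S{i+1:03d}" for i in range(n)],
                       "age": rng.normal(60, 8, n), "years_dx": rng.normal(8, 3, n)})
    for c in CLINICAL_PREDICTORS[1:]:
        df[c] = rng.normal(10, 3, n)
    return df


class TestPixelRegression:
    def test_null_calibration(self):
        fracs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            stack = make_stack(rng.normal(size=(40, 7, 30)))
            res = pixel_multiple_regression(stack, clin_frame(40, rng))
            fracs.append(res.sig.mean())
        assert np.mean(fracs) < 0.01  # post-FDR under the null

    def test_planted_beta_coupling_peaks_in_band(self):
        cohort = CohortSpec(n_subjects=75, noise_sd=0.15, seed=30,
                            hotspots=[Hotspot(4, 6, 15, 30, sd=0.5, latent_index=0)])
        stack, clin, gt = simulate_map_cohort(cohort)
        res = pixel_multiple_regression(stack, clin)
        peak_freq = F[np.argmax(res.pct_by_freq)]
        assert 12 <= peak_freq <= 35

    def test_insufficient_df_rejected(self):
        rng = np.random.default_rng(1)
        stack = make_stack(rng.normal(size=(5, 3, 10)))
        with pytest.raises(ValueError, match="nsufficient"):
            pixel_multiple_regression(stack, clin_frame(5, rng))

    def test_per_coefficient_variant_finds_planted_predictor(self):
        rng = np.random.default_rng(21)
        stack = make_stack(rng.normal(size=(60, 3, 20)))
        clin = clin_frame(60, rng)
        stack.data[:, 1, 5] += 0.8 * clin["updrs_total"].to_numpy(float)
        res = pixel_multiple_regression(stack, clin, per_coefficient=True)
        assert res.sig[1, 5]

    def test_collinear_predictor_dropped_with_warning(self):
        rng = np.random.default_rng(2)
        stack = make_stack(rng.normal(size=(30, 3, 10)))
        clin = clin_frame(30, rng)
        clin["updrs_total"] = 2.0 * clin["brady_ipsi"] + 1.0  # exact collinearity
        with pytest.warns(UserWarning, match="collinear"):
            res = pixel_multiple_regression(stack, clin)
        assert len(res.dropped_predictors) == 1


class TestVarianceHotspot:
    def test_null_cohort_clean(self):
        clean = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            stack = make_stack(rng.normal(size=(20, 7, 107)))
            sm = variance_hotspot_test(stack, n_perm=200, seed=seed)
            clean += sm.sig_post_blob.sum() == 0
        assert clean >= 9

    def test_planted_hotspot_survives(self):
        hs = Hotspot(2, 3, 20, 26, sd=0.45)
        hits = 0
        for seed in range(10):
            spec = CohortSpec(n_subjects=30, noise_sd=0.15, hotspots=[hs],
                              seed=1000 + seed)
            stack, _, _ = simulate_map_cohort(spec)
            sm = variance_hotspot_test(stack, n_perm=200, seed=seed)
            hits += bool((sm.sig_post_blob & hs.mask(7, spec.freqs)).any())
        assert hits >= 9

    def test_determinism(self):
        rng = np.random.default_rng(3)
        stack = make_stack(rng.normal(size=(12, 5, 40)))
        a = variance_hotspot_test(stack, n_perm=150, seed=4)
        b = variance_hotspot_test(stack, n_perm=150, seed=4)
        assert np.array_equal(a.z, b.z)


class TestCorrelationMap:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(4)
        data = rng.normal(size=(20, 3, 10))
        totals = data[:, 1, 5].copy()
        rmap, _ = clinical_correlation_map(make_stack(data), totals)
        assert rmap.values[1, 5] == pytest.approx(1.0)

    def test_null_scale(self):
        rng = np.random.default_rng(5)
        n = 75
        data = rng.normal(size=(n, 7, 107))
        totals = rng.normal(size=n)
        rmap, p = clinical_correlation_map(make_stack(data), totals)
        # null |r| concentrates at the 1/sqrt(n) scale: E|r| ~ sqrt(2/(pi n))
        assert np.abs(rmap.values).mean() == pytest.approx(np.sqrt(2 / (np.pi * n)),
                                                           rel=0.15)
        assert (p < 0.05).mean() == pytest.approx(0.05, abs=0.02)

    def test_variance_and_correlation_hotspots_overlap(self):
        hs = Hotspot(3, 5, 18, 28, sd=0.6, latent_index=0)
        spec = CohortSpec(n_subjects=75, noise_sd=0.15, hotspots=[hs], seed=31)
        stack, clin, _ = simulate_map_cohort(spec)
        rmap, _ = clinical_correlation_map(stack, clin["updrs_total"].to_numpy(float))
        v = stack.data.var(axis=0, ddof=1).ravel()
        r = np.abs(rmap.values).ravel()
        k = int(np.ceil(0.1 * v.size))
        top_v = set(np.argsort(-v)[:k])
        top_r = set(np.argsort(-r)[:k])
        jacc = len(top_v & top_r) / len(top_v | top_r)
        assert jacc > 0.3

    def test_constant_totals_rejected(self):
        stack = make_stack(np.random.default_rng(0).normal(size=(10, 3, 10)))
        with pytest.raises(ValueError):
            clinical_correlation_map(stack, np.ones(10))


class TestSelectVariancePixels:
    def test_ten_percent_of_7x107_is_75(self):
        rng = np.random.default_rng(6)
        stack = make_stack(rng.normal(size=(10, 7, 107)))
        idx = select_variance_pixels(stack, 0.10, "top")
        assert idx.size == 75  # ceil(74.9)

    def test_hotspot_pixels_only_in_top(self):
        hs = Hotspot(2, 3, 20, 26, sd=0.9)
        spec = CohortSpec(n_subjects=40, noise_sd=0.15, hotspots=[hs], seed=32)
        stack, _, _ = simulate_map_cohort(spec)
        m = hs.mask(7, spec.freqs).ravel()
        top = select_variance_pixels(stack, 0.10, "top")
        bottom = select_variance_pixels(stack, 0.10, "bottom")
        assert m[top].sum() == m.sum()
        assert m[bottom].sum() == 0

    def test_half_fraction_partitions_pixels(self):
        rng = np.random.default_rng(7)
        stack = make_stack(rng.normal(size=(10, 7, 107)))
        top = select_variance_pixels(stack, 0.5, "top")
        bottom = select_variance_pixels(stack, 0.5, "bottom")
        assert np.intersect1d(top, bottom).size == 0
        assert np.union1d(top, bottom).size == 7 * 107


class TestPls:
    def test_exact_rank1_coupling(self):
        # rank-1 noiseless coupling: one latent drives both blocks exactly,
        # so the LV1 X and Y scores are both proportional to it
        rng = np.random.default_rng(8)
        z = rng.normal(size=75)
        wx = rng.uniform(0.5, 1.5, size=40) * rng.choice([-1, 1], size=40)
        wy = rng.uniform(0.5, 1.5, size=3)
        X = np.outer(z, wx)
        Y = np.outer(z, wy)
        model = pls_fit(X, Y, n_lv=1)
        assert abs(model.r_obs[0]) == pytest.approx(1.0, abs=1e-6)

    def test_noisy_rank1_coupling_dominant_lv(self):
        rng = np.random.default_rng(80)
        X = rng.normal(size=(75, 40))
        y = X @ rng.normal(size=40)
        Y = np.column_stack([y, 2 * y, -y]) + 0.0
        model = pls_fit(X, Y, n_lv=3)
        assert model.r_obs[0] > 0.85

    def test_lv1_dominates_under_planted_coupling(self):
        # deflation does not make score correlations strictly monotone, but a
        # dominant planted coupling must land on the first latent variable
        for seed in range(10):
            rng = np.random.default_rng(seed)
            z = rng.normal(size=60)
            X = 3 * np.outer(z, rng.normal(size=30)) + rng.normal(size=(60, 30))
            Y = 3 * np.outer(z, rng.normal(size=5)) + rng.normal(size=(60, 5))
            model = pls_fit(X, Y, n_lv=5)
            assert model.r_obs[0] == pytest.approx(model.r_obs.max())

    def test_planted_rank2_subspace_recovered(self):
        rng = np.random.default_rng(10)
        n, p, q = 75, 40, 6
        W = np.linalg.qr(rng.normal(size=(p, 2)))[0]
        T = rng.normal(size=(n, 2))
        X = T @ W.T + 0.2 * rng.normal(size=(n, p))
        Y = T @ rng.normal(size=(2, q)) + 0.2 * rng.normal(size=(n, q))
        model = pls_fit(X, Y, n_lv=4)
        # principal angles between planted and recovered weight subspaces
        U = np.linalg.qr(model.x_weights[:, :2])[0]
        s = np.linalg.svd(U.T @ W, compute_uv=False)
        angles = np.degrees(np.arccos(np.clip(s, -1, 1)))
        assert angles.max() < 15.0

    def test_permutation_p_zero_for_exact_coupling(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(40, 20))
        Y = np.column_stack([X @ rng.normal(size=20), X @ rng.normal(size=20)])
        model = pls_fit(X, Y, n_lv=2)
        model = pls_permutation_validate(model, X, Y, n_perm=200, seed=1)
        assert model.p_perm[0] == 0.0
        assert model.sig_percentile[0]

    def test_permutation_determinism(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(30, 15))
        Y = rng.normal(size=(30, 4))
        m1 = pls_permutation_validate(pls_fit(X, Y, 3), X, Y, n_perm=150, seed=9)
        m2 = pls_permutation_validate(pls_fit(X, Y, 3), X, Y, n_perm=150, seed=9)
        assert np.array_equal(m1.p_perm, m2.p_perm)

    def test_subject_reordering_invariance(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(30, 15))
        Y = rng.normal(size=(30, 4))
        m1 = pls_permutation_validate(pls_fit(X, Y, 2), X, Y, n_perm=100, seed=3)
        perm = rng.permutation(30)
        m2 = pls_permutation_validate(pls_fit(X[perm], Y[perm], 2),
                                      X[perm], Y[perm], n_perm=100, seed=3)
        assert m1.r_obs[0] == pytest.approx(m2.r_obs[0], abs=1e-9)

    def test_zero_variance_column_rejected(self):
        X = np.random.default_rng(14).normal(size=(20, 5))
        X[:, 2] = 1.0
        with pytest.raises(ValueError, match="variance"):
            pls_fit(X, np.random.default_rng(15).normal(size=(20, 3)))


class TestCompareTopBottom:
    def _coupled_cohort(self, seed):
        hs = Hotspot(3, 5, 18, 28, sd=0.6, latent_index=0)
        spec = CohortSpec(n_subjects=75, noise_sd=0.15, hotspots=[hs], seed=seed)
        return simulate_map_cohort(spec)

    def test_top_explains_more_y_variance(self):
        from ssmap.clinical import _clinical_matrix
        wins = 0
        for seed in range(5):
            stack, clin, _ = self._coupled_cohort(40 + seed)
            flat = stack.data.reshape(75, -1)
            Y = _clinical_matrix(clin, stack.subject_ids)
            top = pls_fit(flat[:, select_variance_pixels(stack, 0.1, "top")], Y, 5)
            bottom = pls_fit(flat[:, select_variance_pixels(stack, 0.1, "bottom")], Y, 5)
            rep = compare_top_bottom(top, bottom)
            wins += rep["varexp_y_diff_pct"].iloc[0] > 0
        assert wins >= 5

    def test_identical_models_zero_difference(self):
        rng = np.random.default_rng(16)
        X = rng.normal(size=(30, 20))
        Y = rng.normal(size=(30, 4))
        m = pls_fit(X, Y, 3)
        rep = compare_top_bottom(m, m)
        assert np.allclose(rep["varexp_y_diff_pct"], 0.0)

    def test_mismatched_models_rejected(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(30, 20))
        m1 = pls_fit(X, rng.normal(size=(30, 4)), 3)
        m2 = pls_fit(X, rng.normal(size=(30, 4)), 2)
        with pytest.raises(ValueError):
            compare_top_bottom(m1, m2)
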