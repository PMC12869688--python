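"""Permutation nulls, pixel Z-tests, BH-FDR, blob correction, rank-sum, MVPA."""
from __future__ import annotations

from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssmap import (CohortSpec, Hotspot, bh_fdr, blob_correction,
                   group_difference_map, mvpa_classify, pixel_z_test,
                   simulate_map_cohort, spatial_shuffle_null)
from ssmap.types import DEFAULT_FREQS, CohortStack

F = DEFAULT_FREQS


def make_stack(data):
    ns, nc, nf = data.shape
    return CohortStack(data, [f"S{i}" for i in range(ns)],
                       [f"c{i}" for i in range(nc)], F[:nf])


class TestShuffleNull:
    def test_identical_rows_degenerate_sigma(self):
        data = np.tile(np.random.default_rng(0).normal(size=(5, 1, 20)), (1, 4, 1))
        st_ = make_stack(data)
        mu, sigma = spatial_shuffle_null(st_, n_perm=100, seed=0)
        assert np.allclose(sigma, 0.0)
        with pytest.raises(ValueError, match="degenerate"):
            pixel_z_test(st_, (mu, sigma))

    def test_frequency_constant_maps_have_grand_mean_null(self):
        rng = np.random.default_rng(1)
        rows = rng.normal(size=(6, 5, 1))
        data = np.repeat(rows, 30, axis=2)
        st_ = make_stack(data)
        mu, _ = spatial_shuffle_null(st_, n_perm=400, seed=1)
        grand = data.mean(axis=(0, 1))  # closed-form expectation per pixel
        assert np.allclose(mu, grand[None, :], atol=0.05 * np.abs(grand).mean() + 0.05)

    def test_determinism(self, null_cohort_20):
        stack, _, _ = null_cohort_20
        a = spatial_shuffle_null(stack, n_perm=150, seed=9)
        b = spatial_shuffle_null(stack, n_perm=150, seed=9)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


class TestPixelZ:
    def test_null_center_gives_p_one(self):
        z_map = pixel_z_test(
            make_stack(np.zeros((5, 3, 10)) + 1.0),
            (np.ones((3, 10)), np.ones((3, 10))))
        assert np.allclose(z_map.z, 0.0) and np.allclose(z_map.p_raw, 1.0)

    def test_z_196_gives_p_005(self):
        mu = np.zeros((1, 10))
        sigma = np.ones((1, 10))
        data = np.full((4, 1, 10), 1.96)
        sm = pixel_z_test(make_stack(data), (mu, sigma))
        assert np.allclose(sm.p_raw, 0.05, atol=1e-3)

    def test_planted_mean_offset_peaks_inside(self):
        spec = CohortSpec(n_subjects=20, peaks=[], hotspots=[], noise_sd=0.2, seed=33)
        stack, _, _ = simulate_map_cohort(spec)
        patch = np.zeros((7, 107), dtype=bool)
        patch[4:6, 14:19] = True
        stack.data[:, patch] += 0.6  # 3-sigma anterior beta offset
        null = spatial_shuffle_null(stack, n_perm=300, seed=3)
        sm = pixel_z_test(stack, null)
        idx = np.unravel_index(np.nanargmax(np.abs(sm.z)), sm.z.shape)
        assert patch[idx]


class TestBhFdr:
    def test_hand_computed_small(self):
        rej, adj = bh_fdr(np.array([0.001, 0.2, 0.9]), alpha=0.05)
        assert rej.tolist() == [True, False, False]
        assert adj[0] == pytest.approx(0.003)

    def test_all_ones_no_rejections(self):
        rej, _ = bh_fdr(np.ones(10), alpha=0.05)
        assert not rej.any()

    def test_boundary_all_rejected(self):
        # p(4) = 0.04 <= 4 * 0.05 / 4 -> step-up rejects all four
        rej, _ = bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]), alpha=0.05)
        assert rej.all()

    def test_nan_excluded_from_family(self):
        p = np.array([0.012, np.nan, 0.5])
        rej, adj = bh_fdr(p, alpha=0.05)
        assert rej[0] and not rej[2] and np.isnan(adj[1])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40),
           st.floats(min_value=0.01, max_value=0.2))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_stepup_oracle(self, ps, alpha):
        p = np.array(ps)
        rej, _ = bh_fdr(p, alpha=alpha)
        # independent brute-force step-up
        order = np.argsort(p)
        m = p.size
        k = 0
        for i, j in enumerate(order, start=1):
            if p[j] <= i * alpha / m:
                k = i
        expect = np.zeros(m, bool)
        expect[order[:k]] = True
        assert np.array_equal(rej, expect)


def blob_oracle(mask, min_channels=2, min_hz=3):
    """Brute-force 4-connected component enumeration (independent of ndimage)."""
    mask = np.asarray(mask, bool)
    seen = np.zeros_like(mask)
    out = np.zeros_like(mask)
    nc, nf = mask.shape
    for i in range(nc):
        for j in range(nf):
            if mask[i, j] and not seen[i, j]:
                comp = []
                stack_ = [(i, j)]
                seen[i, j] = True
                while stack_:
                    a, b = stack_.pop()
                    comp.append((a, b))
                    for da, db in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        x, y = a + da, b + db
                        if 0 <= x < nc and 0 <= y < nf and mask[x, y] and not seen[x, y]:
                            seen[x, y] = True
                            stack_.append((x, y))
                rows = {a for a, _ in comp}
                runs_ok = False
                for r in rows:
                    cols = sorted(b for a, b in comp if a == r)
                    run = best = 1
                    for u, v in zip(cols, cols[1:]):
                        run = run + 1 if v == u + 1 else 1
                        best = max(best, run)
                    if best >= min_hz:
                        runs_ok = True
                if len(rows) >= min_channels and runs_ok:
                    for a, b in comp:
                        out[a, b] = True
    return out


class TestBlob:
    def test_single_channel_stripe_cleared(self):
        m = np.zeros((7, 30), bool)
        m[3, 5:15] = True
        assert blob_correction(m).sum() == 0

    def test_two_channel_three_hz_retained(self):
        m = np.zeros((7, 30), bool)
        m[2:4, 10:13] = True
        assert np.array_equal(blob_correction(m), m)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.random((7, 40)) < 0.25
        assert np.array_equal(blob_correction(m), blob_oracle(m))

    @given(st.integers(0, 2 ** 32 - 1), st.floats(0.05, 0.5))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_idempotent_and_monotone(self, seed, density):
        rng = np.random.default_rng(seed)
        m = rng.random((6, 25)) < density
        once = blob_correction(m)
        assert np.array_equal(blob_correction(once), once)  # idempotent
        assert not np.any(once & ~m)  # output is a subset of the input
        # monotone: removing an input pixel never adds output pixels
        m2 = m.copy()
        on = np.argwhere(m)
        if on.size:
            r, c = on[rng.integers(len(on))]
            m2[r, c] = False
        out2 = blob_correction(m2)
        assert not np.any(out2 & ~once)


class TestGroupDifference:
    def test_identical_cohorts_nothing_survives(self, null_cohort_20):
        stack, _, _ = null_cohort_20
        sm = group_difference_map(stack, stack)
        assert sm.sig_post_blob.sum() == 0

    def test_disjoint_supports_exact_enumeration(self):
        a = make_stack(np.zeros((10, 1, F.size)))
        b = make_stack(np.ones((10, 1, F.size)))
        sm = group_difference_map(a, b, method="exact")
        assert np.allclose(sm.p_raw, 2 / comb(20, 10))

    def test_planted_beta_difference_recovered(self):
        # PD-like vs ET-like differ in the anterior beta peak
        hits = 0
        for seed in range(10):
            sa, _, _ = simulate_map_cohort(CohortSpec(n_subjects=20, seed=400 + seed,
                                                      noise_sd=0.15))
            sb, _, _ = simulate_map_cohort(CohortSpec(n_subjects=20, seed=900 + seed,
                                                      disease="et_like", noise_sd=0.15))
            sm = group_difference_map(sa, sb)
            beta = (F >= 12) & (F <= 35)
            hits += sm.sig_post_blob[:, beta].any() and not sm.sig_post_blob[:, ~beta].any()
        assert hits >= 9


class TestMvpa:
    def _split(self, stack):
        n = stack.n_subjects // 2
        a = make_stack(stack.data[:n])
        b = CohortStack(stack.data[n:], [f"T{i}" for i in range(stack.n_subjects - n)],
                        stack.channels, stack.freqs)
        return a, b

    def test_separable_groups_perfect_accuracy(self):
        rng = np.random.default_rng(0)
        a = make_stack(rng.uniform(0, 1, size=(15, 3, 20)))
        b = CohortStack(rng.uniform(5, 6, size=(15, 3, 20)),
                        [f"T{i}" for i in range(15)], [f"c{i}" for i in range(3)], F[:20])
        res = mvpa_classify(a, b, folds=10, n_perm=50, seed=1)
        assert res.accuracy == 1.0
        assert res.p_perm <= 1 / 50

    def test_determinism(self, null_cohort_20):
        stack, _, _ = null_cohort_20
        a, b = self._split(stack)
        r1 = mvpa_classify(a, b, folds=5, n_perm=30, seed=5)
        r2 = mvpa_classify(a, b, folds=5, n_perm=30, seed=5)
        assert r1.accuracy == r2.accuracy and r1.p_perm == r2.p_perm
        assert np.array_equal(r1.null_accuracies, r2.null_accuracies)

    def test_too_few_subjects_rejected(self):
        rng = np.random.default_rng(2)
        a = make_stack(rng.normal(size=(3, 2, 10)))
        b = CohortStack(rng.normal(size=(3, 2, 10)), ["T0", "T1", "T2"],
                        ["c0", "c1"], F[:10])
        with pytest.raises(ValueError, match="folds"):
            mvpa_classify(a, b, folds=10, n_perm=10, seed=0)
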