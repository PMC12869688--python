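"""Calibration and recovery experiments for the statistical machinery.

Each function sets up a synthetic study with known ground truth, runs the
corresponding analysis chain end-to-end, and returns the measured operating
characteristic: the false-discovery proportion of the permutation-Z + BH
chain under a global null, the coverage of the population percentile
interval, the type-I rate of the MVPA label-permutation test, the
per-pixel subject deviation rate for exchangeable cohorts, and the power
of hotspot / coupling / cluster-count recovery.  They are used by the
acceptance checks and are convenient for sensitivity analyses.
"""
from __future__ import annotations

import numpy as np

from . import clinical as clin_mod
from .clustering import gap_statistic
from .consistency import ci_containment, subject_deviation_rate
from .permstats import mvpa_classify, pixel_z_test, spatial_shuffle_null
from .spectral import fit_aperiodic, multitaper_psd
from .preprocess import build_bipolar_montage
from .synthetic import (CohortSpec, Hotspot, simulate_map_cohort,
                        simulate_segment_replicates, simulate_timeseries_subject)
from .types import CohortStack


def _seed_stream(seed: int, tag: int, n: int) -> np.ndarray:
    return np.random.default_rng([seed % (2 ** 31), tag]).integers(2 ** 31 - 1, size=n)


def fdr_null_calibration(n_cohorts: int = 200, n_subjects: int = 20,
                         n_perm: int = 200, alpha: float = 0.05,
                         seed: int = 0) -> float:
    """Mean false-discovery proportion of the Z->BH chain under a global null.

    Cohorts are i.i.d. pixel noise on the 7 x 107 grid (channel rows
    exchangeable), so every BH discovery is false and the per-cohort FDP is
    1 when anything is discovered and 0 otherwise.
    """
    seeds = _seed_stream(seed, 11, n_cohorts)
    fdp = 0.0
    for s in seeds:
        spec = CohortSpec(n_subjects=n_subjects, peaks=[], hotspots=[],
                          n_clusters=1, noise_sd=1.0, seed=int(s))
        stack, _, _ = simulate_map_cohort(spec)
        null = spatial_shuffle_null(stack, n_perm=n_perm, seed=int(s) + 1)
        sm = pixel_z_test(stack, null, alpha=alpha)
        fdp += 1.0 if sm.sig_pre_blob.any() else 0.0
    return fdp / n_cohorts


def containment_calibration(n_subjects: int = 75, level: float = 95.0,
                            seed: int = 0) -> float:
    """Mean per-subject containment (%) in the pointwise percentile interval
    for an i.i.d. cohort (template plus pixel noise)."""
    spec = CohortSpec(n_subjects=n_subjects, noise_sd=0.15, seed=seed)
    stack, _, _ = simulate_map_cohort(spec)
    obs, _, _ = ci_containment(stack, level=level, seed=seed + 1)
    return float(obs.mean())


def mvpa_null_calibration(n_datasets: int = 200, n_per_group: int = 20,
                          n_perm: int = 200, folds: int = 10,
                          alpha: float = 0.05, seed: int = 0) -> float:
    """Type-I rate of the MVPA label-permutation test for identical groups."""
    seeds = _seed_stream(seed, 23, n_datasets)
    rej = 0
    for s in seeds:
        spec = CohortSpec(n_subjects=2 * n_per_group, peaks=[], noise_sd=1.0,
                          seed=int(s))
        stack, _, _ = simulate_map_cohort(spec)
        a = CohortStack(stack.data[:n_per_group], stack.subject_ids[:n_per_group],
                        stack.channels, stack.freqs)
        b = CohortStack(stack.data[n_per_group:], stack.subject_ids[n_per_group:],
                        stack.channels, stack.freqs)
        res = mvpa_classify(a, b, folds=folds, n_perm=n_perm, seed=int(s) + 1)
        rej += res.p_perm < alpha
    return rej / n_datasets


def deviation_rate_calibration(n_cohorts: int = 8, n_subjects: int = 75,
                               n_segments: int = 60, alpha: float = 0.05,
                               seed: int = 0, pooled: bool = False) -> float:
    """Max per-pixel percentage of exchangeable subjects flagged as deviating.

    With ``pooled=False`` returns the mean over cohorts of the per-cohort
    maximum (the single-cohort summary used in reporting, stabilized over
    replicate cohorts).  With ``pooled=True`` the subject tests of all
    cohorts are pooled per pixel before taking the maximum, which estimates
    the per-pixel flag *rate* itself (it converges to the test's level).
    """
    seeds = _seed_stream(seed, 31, n_cohorts)
    maxima = []
    flags = None
    for s in seeds:
        spec = CohortSpec(n_subjects=n_subjects, noise_sd=0.15, seed=int(s))
        ws = simulate_segment_replicates(spec, n_segments=n_segments)
        pct, _ = subject_deviation_rate(ws, alpha=alpha)
        maxima.append(pct.max())
        flags = pct if flags is None else flags + pct
    if pooled:
        return float((flags / n_cohorts).max())
    return float(np.mean(maxima))


def hotspot_recovery_rate(n_cohorts: int = 50, n_subjects: int = 20,
                          n_perm: int = 200, seed: int = 0) -> float:
    """Fraction of cohorts where a planted 2-channel x 5-Hz, 3-sigma mean
    offset survives the full Z -> BH -> blob chain inside the patch."""
    seeds = _seed_stream(seed, 41, n_cohorts)
    noise_sd = 1.0
    ch = slice(3, 5)
    fr = slice(16, 21)  # five 1-Hz bins: 20..24 Hz on the 4..110 grid
    hits = 0
    for s in seeds:
        spec = CohortSpec(n_subjects=n_subjects, peaks=[], noise_sd=noise_sd,
                          seed=int(s))
        stack, _, _ = simulate_map_cohort(spec)
        stack.data[:, ch, fr] += 3.0 * noise_sd
        null = spatial_shuffle_null(stack, n_perm=n_perm, seed=int(s) + 1)
        sm = pixel_z_test(stack, null)
        patch = np.zeros_like(sm.sig_post_blob)
        patch[ch, fr] = True
        hits += bool((sm.sig_post_blob & patch).any())
    return hits / n_cohorts


def pls_coupling_recovery(n_runs: int = 20, n_subjects: int = 75,
                          n_features: int = 75, n_clinical: int = 7,
                          snr: float = 2.0, n_perm: int = 500,
                          seed: int = 0) -> tuple[float, float]:
    """Rank-1 brain-behavior coupling recovery by PLS.

    Plants X = a z w_x' + noise and Y = a z w_y' + noise with overall
    signal-to-noise ``snr``; returns (fraction of runs with LV1 flagged
    significant, mean |correlation| between the recovered and planted X
    weight vectors).
    """
    seeds = _seed_stream(seed, 43, n_runs)
    sig = 0
    wcorr = []
    for s in seeds:
        rng = np.random.default_rng(int(s))
        z = rng.normal(size=n_subjects)
        wx = rng.normal(size=n_features)
        wx /= np.linalg.norm(wx)
        wy = rng.normal(size=n_clinical)
        wy /= np.linalg.norm(wy)
        a = snr * np.sqrt(n_features)  # per-column signal sd ~ snr on average
        X = a * np.outer(z, wx) + rng.normal(size=(n_subjects, n_features))
        Y = a * np.outer(z, wy) / np.sqrt(n_features / n_clinical) \
            + rng.normal(size=(n_subjects, n_clinical))
        model = clin_mod.pls_fit(X, Y, n_lv=5)
        model = clin_mod.pls_permutation_validate(model, X, Y, n_perm=n_perm,
                                                  seed=int(s) + 1)
        sig += bool(model.sig_fdr[0] and model.sig_percentile[0])
        wcorr.append(abs(np.corrcoef(model.x_weights[:, 0], wx)[0, 1]))
    return sig / n_runs, float(np.mean(wcorr))


def gap_recovery_rate(n_runs: int = 20, k_true: int = 3, n_per: int = 25,
                      sep: float = 10.0, b_ref: int = 50, seed: int = 0) -> float:
    """Fraction of runs where the gap statistic recovers a planted k."""
    seeds = _seed_stream(seed, 47, n_runs)
    hits = 0
    for s in seeds:
        rng = np.random.default_rng(int(s))
        centers = rng.normal(scale=sep, size=(k_true, 3))
        pts = np.concatenate([c + rng.normal(size=(n_per, 3)) for c in centers])
        hits += gap_statistic(pts, k_max=10, b_ref=b_ref, seed=int(s) + 1).k_star == k_true
    return hits / n_runs


def aperiodic_roundtrip_errors(duration_s: float = 300.0, rate_hz: float = 1375.0,
                               seed: int = 0) -> dict[tuple[float, float], float]:
    """Absolute chi recovery error over the (knee, exponent) grid.

    Simulates a background-only recording per grid point, estimates the
    multitaper PSD of one bipolar channel, fits the aperiodic model and
    compares the recovered exponent with the planted one.
    """
    errors = {}
    for k in (0.0, 10.0, 50.0):
        for chi in (0.8, 1.5, 2.5):
            spec = CohortSpec(n_subjects=1, aperiodic=(0.0, k, chi), peaks=[],
                              noise_sd=0.0, seed=seed)
            ecog, _, _ = simulate_timeseries_subject(spec, 0, duration_s=duration_s,
                                                     rate_hz=rate_hz)
            bip = build_bipolar_montage(ecog, "ecog_adjacent_7")
            fit = fit_aperiodic(multitaper_psd(bip, 3))
            errors[(k, chi)] = abs(fit.chi - chi)
    return errors
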