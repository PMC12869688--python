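"""Group-level significance machinery for spatio-spectral maps.

Implements the spatial-permutation pixel test (channel rows of every
subject's map are shuffled independently, the permuted group means form the
null), Benjamini-Hochberg FDR control, the contiguity ("blob") correction
requiring clusters of at least two adjacent electrodes by 3 Hz of
consecutive bins, two-group rank-sum difference maps, and multivariate
pattern classification (linear SVM) with a label-permutation test.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

from .types import CohortStack, PixelStatMap

#: 4-connectivity structuring element (no diagonals): adjacency means
#: neighbouring electrodes or consecutive frequency bins
_STRUCTURE = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def spatial_shuffle_null(stack: CohortStack, n_perm: int = 1000, seed: int = 0,
                         chunk: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Permutation null of the group-average map under channel-row shuffling.

    Each permutation independently permutes the channel rows of every
    subject's map (frequency axis intact) and averages across subjects;
    returns the per-pixel mean and SD over the ``n_perm`` permuted group
    means.
    """
    if len(stack.channels) < 2:
        raise ValueError("need >= 2 channels to shuffle")
    if n_perm < 100:
        warnings.warn("n_perm < 100: sigma_null will be unstable")
    rng = np.random.default_rng(seed)
    ns, nc, nf = stack.data.shape
    total = np.zeros((nc, nf))
    total_sq = np.zeros((nc, nf))
    subj = np.arange(ns)[None, :, None]
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        # random row permutation per (perm, subject)
        idx = np.argsort(rng.random((m, ns, nc)), axis=-1)
        permuted = stack.data[subj, idx, :]  # (m, ns, nc, nf)
        means = permuted.mean(axis=1)
        total += means.sum(axis=0)
        total_sq += (means ** 2).sum(axis=0)
        done += m
    mu = total / n_perm
    var = total_sq / n_perm - mu ** 2
    # unbiased correction; clamp cancellation noise (shuffle-invariant pixels
    # must come out exactly degenerate, not at float epsilon)
    var = np.maximum(var * n_perm / (n_perm - 1), 0.0)
    var[var <= 1e-14 * np.maximum(total_sq / n_perm, 1e-300)] = 0.0
    return mu, np.sqrt(var)


def pixel_z_test(stack: CohortStack, null: tuple[np.ndarray, np.ndarray],
                 alpha: float = 0.05, min_channels: int = 2, min_hz: int = 3,
                 n_perm: int = 0) -> PixelStatMap:
    """Z-score the observed group mean against the permutation null.

    Z = (X_true - mu_null) / sigma_null and p = 2[1 - Phi(|Z|)].  Pixels with
    sigma_null == 0 are undefined (NaN) and excluded from the FDR family.
    The full correction chain (BH at ``alpha`` then blob correction) is
    applied.
    """
    mu, sigma = null
    x = stack.data.mean(axis=0)
    if np.all(sigma == 0):
        raise ValueError("degenerate null: sigma_null is zero everywhere "
                         "(shuffle-invariant input)")
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sigma > 0, (x - mu) / np.where(sigma > 0, sigma, 1.0), np.nan)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return _finish_statmap(z, p, alpha, min_channels, min_hz, mu, sigma, n_perm)


def _finish_statmap(z: np.ndarray, p: np.ndarray, alpha: float, min_channels: int,
                    min_hz: int, mu=None, sigma=None, n_perm: int = 0) -> PixelStatMap:
    rej, p_adj = bh_fdr(p.ravel(), alpha)
    sig_pre = rej.reshape(p.shape)
    sig_post = blob_correction(sig_pre, min_channels=min_channels, min_hz=min_hz)
    return PixelStatMap(z=z, p_raw=p, p_fdr=p_adj.reshape(p.shape),
                        sig_pre_blob=sig_pre, sig_post_blob=sig_post,
                        mu_null=mu, sigma_null=sigma, n_perm=n_perm)


def bh_fdr(p_values: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up over the defined (non-NaN) p-values.

    Rejects the k smallest p-values where k = max{i : p(i) <= i * alpha / m};
    returns the rejection mask and step-up adjusted p-values, with NaN
    propagated for undefined entries (they do not count toward m).
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("empty p-value input")
    ok = ~np.isnan(p)
    rej = np.zeros(p.size, dtype=bool)
    adj = np.full(p.size, np.nan)
    if ok.sum():
        r, a, _, _ = multipletests(p[ok], alpha=alpha, method="fdr_bh")
        rej[ok] = r
        adj[ok] = a
    return rej, adj


def blob_correction(mask: np.ndarray, min_channels: int = 2, min_hz: int = 3) -> np.ndarray:
    """Retain only contiguous clusters spanning enough electrodes and bins.

    Connected components under 4-connectivity survive iff they span at least
    ``min_channels`` distinct channel rows and contain a run of at least
    ``min_hz`` consecutive frequency bins on at least one channel row; all
    pixels of non-surviving components are cleared.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D (channels x freqs)")
    labeled, n = ndimage.label(mask, structure=_STRUCTURE)
    out = np.zeros_like(mask)
    for comp in range(1, n + 1):
        rows, cols = np.nonzero(labeled == comp)
        if np.unique(rows).size < min_channels:
            continue
        ok = False
        for r in np.unique(rows):
            c = np.sort(cols[rows == r])
            if _longest_run(c) >= min_hz:
                ok = True
                break
        if ok:
            out[labeled == comp] = True
    return out


def _longest_run(sorted_idx: np.ndarray) -> int:
    if sorted_idx.size == 0:
        return 0
    breaks = np.flatnonzero(np.diff(sorted_idx) != 1)
    run_ends = np.r_[breaks, sorted_idx.size - 1]
    run_starts = np.r_[0, breaks + 1]
    return int((run_ends - run_starts + 1).max())


def rank_sum_p_map(a: np.ndarray, b: np.ndarray, method: str = "asymptotic") -> np.ndarray:
    """Per-pixel two-sided Wilcoxon rank-sum p-values between two stacks."""
    if method == "asymptotic":
        res = stats.mannwhitneyu(a, b, axis=0, alternative="two-sided", method="asymptotic")
        return np.asarray(res.pvalue)
    res = stats.mannwhitneyu(a, b, axis=0, alternative="two-sided", method=method)
    return np.asarray(res.pvalue)


def group_difference_map(stack_a: CohortStack, stack_b: CohortStack,
                         alpha: float = 0.05, min_channels: int = 2, min_hz: int = 3,
                         method: str = "asymptotic") -> PixelStatMap:
    """Pixelwise rank-sum comparison of two cohorts with FDR + blob correction.

    Z carries the signed normal quantile of the (two-sided) p with the sign
    of the A-vs-B location difference, for display purposes.
    """
    if stack_a.channels != stack_b.channels or not np.array_equal(stack_a.freqs, stack_b.freqs):
        raise ValueError("cohort axes mismatch")
    if stack_a.n_subjects < 3 or stack_b.n_subjects < 3:
        raise ValueError("need >= 3 subjects per group")
    p = rank_sum_p_map(stack_a.data, stack_b.data, method=method)
    sign = np.sign(np.median(stack_a.data, axis=0) - np.median(stack_b.data, axis=0))
    with np.errstate(divide="ignore"):
        z = sign * stats.norm.isf(np.clip(p, 1e-300, 1.0) / 2.0)
    return _finish_statmap(z, p, alpha, min_channels, min_hz)


@dataclass
class MvpaResult:
    """Cross-validated classification accuracy with its permutation null."""

    accuracy: float
    fold_accuracies: np.ndarray
    null_accuracies: np.ndarray
    p_perm: float
    n_perm: int
    folds: int
    p_convention: str = "r_over_n"  # or "r_plus1_over_n_plus1"


def _stratified_folds(y: np.ndarray, folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Class-stratified fold assignment (list of test-index arrays)."""
    out: list[list[int]] = [[] for _ in range(folds)]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = idx[rng.permutation(idx.size)]
        for i, j in enumerate(idx):
            out[i % folds].append(int(j))
    return [np.array(sorted(f), dtype=int) for f in out]


def _cv_accuracy(X: np.ndarray, y: np.ndarray, folds: int, rng: np.random.Generator,
                 C: float = 1.0) -> tuple[float, np.ndarray]:
    accs = []
    for test in _stratified_folds(y, folds, rng):
        train = np.setdiff1d(np.arange(y.size), test)
        ytr = y[train]
        if np.unique(ytr).size < 2:
            raise ValueError("a class is absent from a training fold")
        mu = X[train].mean(axis=0)
        sd = X[train].std(axis=0)
        sd[sd == 0] = 1.0
        Xtr = (X[train] - mu) / sd
        Xte = (X[test] - mu) / sd
        # precomputed linear kernel: identical decision function, faster solve
        clf = SVC(kernel="precomputed", C=C)
        clf.fit(Xtr @ Xtr.T, ytr)
        accs.append(float((clf.predict(Xte @ Xtr.T) == y[test]).mean()))
    return float(np.mean(accs)), np.array(accs)


def mvpa_classify(stack_a: CohortStack, stack_b: CohortStack, folds: int = 10,
                  n_perm: int = 1000, seed: int = 0, C: float = 1.0,
                  p_convention: str = "r_over_n") -> MvpaResult:
    """Linear-SVM decoding of group membership from flattened maps.

    Maps are flattened to feature vectors, standardized with training-fold
    statistics only, and classified with stratified k-fold cross-validation.
    The permutation p-value is the fraction of ``n_perm`` label shuffles
    whose mean CV accuracy meets or exceeds the observed accuracy (the
    plain r/N convention by default; ``r_plus1_over_n_plus1`` is available).
    """
    na, nb = stack_a.n_subjects, stack_b.n_subjects
    if na + nb < folds:
        raise ValueError("fewer subjects than folds")
    X = np.concatenate([stack_a.data.reshape(na, -1), stack_b.data.reshape(nb, -1)])
    y = np.r_[np.zeros(na, dtype=int), np.ones(nb, dtype=int)]
    rng = np.random.default_rng(seed)
    acc, fold_accs = _cv_accuracy(X, y, folds, rng, C=C)
    null = np.empty(n_perm)
    for i in range(n_perm):
        yp = y[rng.permutation(y.size)]
        null[i], _ = _cv_accuracy(X, yp, folds, rng, C=C)
    r = int((null >= acc).sum())
    if p_convention == "r_plus1_over_n_plus1":
        p = (r + 1) / (n_perm + 1)
    else:
        p = r / n_perm
    return MvpaResult(accuracy=acc, fold_accuracies=fold_accs, null_accuracies=null,
                      p_perm=float(p), n_perm=n_perm, folds=folds,
                      p_convention=p_convention)
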