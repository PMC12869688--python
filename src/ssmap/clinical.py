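"""Linking spatio-spectral maps to motor symptom scores.

Pixelwise multiple regression of map values on clinical predictors,
permutation tests for variance hotspots, pixelwise clinical correlation
maps, variance-ranked feature selection, and permutation-validated partial
least squares (PLS) between the selected electrophysiological features and
the UPDRS III score vector.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression

from .mapping import variance_map
from .permstats import _finish_statmap, bh_fdr
from .synthetic import CLINICAL_COLUMNS
from .types import CohortStack, PixelStatMap, SpatioSpectralMap

#: predictors of the pixelwise regression and the PLS clinical block
CLINICAL_PREDICTORS = ["years_dx"] + CLINICAL_COLUMNS


def _clinical_matrix(clin: pd.DataFrame, subject_ids: list[str],
                     columns: list[str] | None = None) -> np.ndarray:
    columns = CLINICAL_PREDICTORS if columns is None else columns
    df = clin.set_index("subject_id").loc[subject_ids]
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    return df[columns].to_numpy(dtype=float)


@dataclass
class RegressionMapResult:
    p_fdr: np.ndarray
    sig: np.ndarray
    pct_by_channel: np.ndarray
    pct_by_freq: np.ndarray
    dropped_predictors: list[str] = field(default_factory=list)
    condition_number: float = 0.0


def pixel_multiple_regression(stack: CohortStack, clin: pd.DataFrame,
                              alpha: float = 0.05,
                              per_coefficient: bool = False) -> RegressionMapResult:
    """OLS of each pixel's value on the clinical predictor set.

    Dependent variable: map value at the pixel.  Predictors: years since
    diagnosis, UPDRS III total and the six lateralized sub-scores (plus an
    intercept).  Significance is the overall model F-test, BH-corrected
    across pixels; with ``per_coefficient=True`` the family is instead all
    (pixel, coefficient) t-tests and a pixel counts as significant when any
    of its coefficients survives.  Marginal percentages of significant
    pixels are reported per channel row and per frequency column.
    Collinear predictors are dropped with a warning.
    """
    cols = list(CLINICAL_PREDICTORS)
    X = _clinical_matrix(clin, stack.subject_ids, cols)
    n, _ = X.shape
    if n <= X.shape[1] + 2:
        raise ValueError(f"insufficient subjects ({n}) for {X.shape[1]} predictors")
    dropped: list[str] = []
    # drop constant, then exactly collinear columns (QR rank reveal)
    keep = [j for j in range(X.shape[1]) if X[:, j].std() > 0]
    dropped += [cols[j] for j in range(X.shape[1]) if j not in keep]
    X = X[:, keep]
    cols = [cols[j] for j in keep]
    while X.shape[1] > 1 and np.linalg.matrix_rank(np.column_stack([np.ones(n), X])) < X.shape[1] + 1:
        # remove the column most explained by the others
        r2 = []
        for j in range(X.shape[1]):
            others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
            beta, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
            resid = X[:, j] - others @ beta
            r2.append(1 - resid.var() / max(X[:, j].var(), 1e-300))
        j = int(np.argmax(r2))
        dropped.append(cols.pop(j))
        X = np.delete(X, j, axis=1)
    if dropped:
        warnings.warn(f"dropped collinear/constant predictors: {dropped}")
    k = X.shape[1]
    if n <= k + 2:
        raise ValueError(f"insufficient subjects ({n}) for {k} predictors")
    D = np.column_stack([np.ones(n), X])
    cond = float(np.linalg.cond(D))
    Y = stack.data.reshape(n, -1)
    beta, *_ = np.linalg.lstsq(D, Y, rcond=None)
    resid = Y - D @ beta
    rss = (resid ** 2).sum(axis=0)
    tss = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    df_model, df_resid = k, n - k - 1
    nc, nf = len(stack.channels), stack.freqs.size
    if per_coefficient:
        xtx_inv = np.linalg.inv(D.T @ D)
        se = np.sqrt(np.outer(np.diag(xtx_inv)[1:], rss / df_resid))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = beta[1:] / np.where(se > 0, se, np.inf)
        p_all = 2.0 * stats.t.sf(np.abs(t), df=df_resid)  # (k, n_pixels)
        rej_all, p_adj_all = bh_fdr(p_all.ravel(), alpha)
        sig = rej_all.reshape(k, -1).any(axis=0).reshape(nc, nf)
        p_adj = p_adj_all.reshape(k, -1).min(axis=0)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            F = ((tss - rss) / df_model) / (rss / df_resid)
        p = np.where(tss > 0, stats.f.sf(F, df_model, df_resid), 1.0)
        rej, p_adj = bh_fdr(p, alpha)
        sig = rej.reshape(nc, nf)
    return RegressionMapResult(
        p_fdr=p_adj.reshape(nc, nf), sig=sig,
        pct_by_channel=100.0 * sig.mean(axis=1),
        pct_by_freq=100.0 * sig.mean(axis=0),
        dropped_predictors=dropped, condition_number=cond)


def variance_hotspot_test(stack: CohortStack, n_perm: int = 1000, seed: int = 0,
                          alpha: float = 0.05, min_channels: int = 2,
                          min_hz: int = 3, chunk: int = 100) -> PixelStatMap:
    """Z-test of the observed variance map against channel-shuffled nulls.

    Null variance maps are produced by independently permuting each
    subject's channel rows and recomputing the per-pixel cross-subject
    variance; the observed variance is Z-scored against the permutation
    mean/SD, with the usual BH + blob correction chain.
    """
    if stack.n_subjects < 5:
        raise ValueError("need >= 5 subjects")
    obs = variance_map(stack).values
    rng = np.random.default_rng(seed)
    ns, nc, nf = stack.data.shape
    subj = np.arange(ns)[None, :, None]
    total = np.zeros((nc, nf))
    total_sq = np.zeros((nc, nf))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        idx = np.argsort(rng.random((m, ns, nc)), axis=-1)
        permuted = stack.data[subj, idx, :]
        v = permuted.var(axis=1, ddof=1)
        total += v.sum(axis=0)
        total_sq += (v ** 2).sum(axis=0)
        done += m
    mu = total / n_perm
    var = np.maximum((total_sq / n_perm - mu ** 2) * n_perm / (n_perm - 1), 0.0)
    var[var <= 1e-14 * np.maximum(total_sq / n_perm, 1e-300)] = 0.0
    sigma = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sigma > 0, (obs - mu) / np.where(sigma > 0, sigma, 1.0), np.nan)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return _finish_statmap(z, p, alpha, min_channels, min_hz, mu, sigma, n_perm)


def clinical_correlation_map(stack: CohortStack, totals: np.ndarray
                             ) -> tuple[SpatioSpectralMap, np.ndarray]:
    """Pearson correlation of each pixel's values with total UPDRS III.

    Returns the r map and the companion two-sided p map.
    """
    y = np.asarray(totals, dtype=float)
    n = stack.n_subjects
    if n < 5:
        raise ValueError("need >= 5 subjects")
    if y.size != n:
        raise ValueError("totals length does not match cohort")
    if y.std() == 0:
        raise ValueError("constant clinical totals")
    X = stack.data.reshape(n, -1)
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    denom = np.linalg.norm(xc, axis=0) * np.linalg.norm(yc)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, (yc @ xc) / np.where(denom > 0, denom, 1.0), 0.0)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1 - r ** 2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    nc, nf = len(stack.channels), stack.freqs.size
    rmap = SpatioSpectralMap(r.reshape(nc, nf), list(stack.channels), stack.freqs,
                             kind="statistic")
    return rmap, p.reshape(nc, nf)


def select_variance_pixels(stack: CohortStack, fraction: float = 0.10,
                           which: str = "top") -> np.ndarray:
    """Flat indices of the most (or least) cross-subject-variable pixels.

    Pixels are ranked by unbiased cross-subject variance; ``top`` takes the
    ceil(fraction * n_pixels) highest, ``bottom`` the lowest.  Ties break
    deterministically in (channel, frequency) order.  With an odd pixel
    count the bottom set at fraction 0.5 is one pixel smaller than the top
    set so the two halves partition the map.
    """
    if not (0.0 < fraction <= 0.5):
        raise ValueError("fraction must be in (0, 0.5]")
    if which not in ("top", "bottom"):
        raise ValueError("which must be 'top' or 'bottom'")
    v = variance_map(stack).values.ravel()
    n_pix = v.size
    k = int(np.ceil(fraction * n_pix))
    if which == "top":
        order = np.argsort(-v, kind="stable")
        return np.sort(order[:k])
    # bottom: never overlap the would-be top half (odd pixel counts)
    k = min(k, n_pix - k)
    order = np.argsort(v, kind="stable")
    return np.sort(order[:k])


@dataclass
class PlsModel:
    """Fitted two-block PLS with per-LV diagnostics.

    ``r_obs[i]`` is the Pearson correlation between the i-th X and Y score
    vectors; ``varexp_x`` / ``varexp_y`` are the per-LV fractions of total
    sum of squares captured by the rank-one reconstructions.
    """

    x_weights: np.ndarray
    y_weights: np.ndarray
    x_scores: np.ndarray
    y_scores: np.ndarray
    r_obs: np.ndarray
    varexp_x: np.ndarray
    varexp_y: np.ndarray
    feature_idx: np.ndarray | None = None
    p_perm: np.ndarray | None = None
    sig_percentile: np.ndarray | None = None
    sig_fdr: np.ndarray | None = None
    null_r: np.ndarray | None = None
    n_perm: int = 0


def _zscore_cols(A: np.ndarray) -> np.ndarray:
    sd = A.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise ValueError("zero-variance column")
    return (A - A.mean(axis=0)) / sd


def pls_fit(X: np.ndarray, Y: np.ndarray, n_lv: int = 10,
            feature_idx: np.ndarray | None = None, standardize: bool = True) -> PlsModel:
    """NIPALS-style two-block PLS on column-standardized X and Y.

    Latent-variable count is capped at min(n_samples - 1, n_features).
    Variance explained per LV is computed from the rank-one reconstruction
    t_i p_i' (X block) and t_i q_i' (Y block) relative to the total sum of
    squares of the standardized blocks.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    if standardize:
        X = _zscore_cols(X)
        Y = _zscore_cols(Y)
    n_lv = int(min(n_lv, X.shape[0] - 1, X.shape[1]))
    pls = PLSRegression(n_components=n_lv, scale=False)
    with warnings.catch_warnings():
        # NIPALS hitting max_iter on late (noise-dominated) components is
        # routine, especially on permuted refits; scores remain usable
        warnings.filterwarnings("ignore", message="Maximum number of iterations")
        pls.fit(X, Y)
    T, U = pls.x_scores_, pls.y_scores_
    r = np.array([stats.pearsonr(T[:, i], U[:, i])[0] for i in range(n_lv)])
    ssx = (X ** 2).sum()
    ssy = (Y ** 2).sum()
    vx = np.array([np.sum(np.outer(T[:, i], pls.x_loadings_[:, i]) ** 2) / ssx
                   for i in range(n_lv)])
    # Y reconstruction uses the regression of Y on the X scores
    vy = np.array([np.sum(np.outer(T[:, i], pls.y_loadings_[:, i]) ** 2) / ssy
                   for i in range(n_lv)])
    return PlsModel(x_weights=pls.x_weights_, y_weights=pls.y_weights_,
                    x_scores=T, y_scores=U, r_obs=r, varexp_x=vx, varexp_y=vy,
                    feature_idx=feature_idx)


def pls_permutation_validate(model: PlsModel, X: np.ndarray, Y: np.ndarray,
                             n_perm: int = 10000, seed: int = 0,
                             alpha: float = 0.05) -> PlsModel:
    """Permutation test of per-LV score correlations.

    For each permutation the rows of Y are shuffled and the model refitted;
    p_perm per LV is the fraction of permutations whose score correlation
    meets or exceeds the observed one.  LVs are flagged by the
    95th-percentile rule and by BH across LVs as the final gate.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100: permutation p-values will be coarse")
    rng = np.random.default_rng(seed)
    n_lv = model.r_obs.size
    null = np.empty((n_perm, n_lv))
    for i in range(n_perm):
        perm = rng.permutation(Y.shape[0])
        m = pls_fit(X, Y[perm], n_lv=n_lv)
        null[i] = m.r_obs
    p = (null >= model.r_obs[None, :]).sum(axis=0) / n_perm
    pct95 = np.percentile(null, 95.0, axis=0)
    sig_pct = model.r_obs > pct95
    rej, _ = bh_fdr(p, alpha)
    model.p_perm = p
    model.sig_percentile = sig_pct
    model.sig_fdr = rej
    model.null_r = null
    model.n_perm = n_perm
    return model


def compare_top_bottom(top: PlsModel, bottom: PlsModel) -> pd.DataFrame:
    """Side-by-side per-LV variance explained and significance flags.

    Both models must target the same clinical block (same LV count); the
    returned frame carries one row per LV with top/bottom variance-explained
    percentages and the difference.
    """
    if top.r_obs.size != bottom.r_obs.size:
        raise ValueError("models have different LV counts (mismatched clinical block?)")
    n = top.r_obs.size
    df = pd.DataFrame({
        "lv": np.arange(1, n + 1),
        "r_top": top.r_obs, "r_bottom": bottom.r_obs,
        "varexp_y_top_pct": 100 * top.varexp_y,
        "varexp_y_bottom_pct": 100 * bottom.varexp_y,
        "varexp_x_top_pct": 100 * top.varexp_x,
        "varexp_x_bottom_pct": 100 * bottom.varexp_x,
    })
    if top.sig_fdr is not None and bottom.sig_fdr is not None:
        df["sig_top"] = top.sig_fdr
        df["sig_bottom"] = bottom.sig_fdr
    df["varexp_y_diff_pct"] = df["varexp_y_top_pct"] - df["varexp_y_bottom_pct"]
    return df
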