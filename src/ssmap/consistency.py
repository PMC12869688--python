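"""Consistency of individual maps with the canonical (group-average) map.

Four complementary views: pixelwise one-sample signed-rank tests of subject
values against the grand average; per-subject deviation rates using 1-s
segment maps as within-subject replicates; containment of individual maps
within the pointwise 95% population percentile interval (against a
channel-shuffled control); and Pearson correlation of each subject's map
with the grand average plus the full cross-subject correlation matrix.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .permstats import bh_fdr, blob_correction
from .types import CohortStack


def signed_rank_p(d: np.ndarray, axis: int = -1) -> np.ndarray:
    """Vectorized two-sided one-sample Wilcoxon signed-rank p-values.

    Normal approximation on the W+ statistic with zero-differences dropped
    (wilcox convention).  Intended for continuous data; exact ties among
    nonzero |d| are tolerated but make the test slightly conservative.
    Slices that are entirely zero return p = 1.
    """
    d = np.moveaxis(np.asarray(d, dtype=float), axis, -1)
    n_all = d.shape[-1]
    absd = np.abs(d)
    zero = absd == 0
    ranked = stats.rankdata(np.where(zero, np.inf, absd), axis=-1, method="average")
    n_eff = (~zero).sum(axis=-1)
    w_pos = np.where(d > 0, ranked, 0.0).sum(axis=-1)
    mean = n_eff * (n_eff + 1) / 4.0
    var = n_eff * (n_eff + 1) * (2 * n_eff + 1) / 24.0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (w_pos - mean) / np.sqrt(np.where(var > 0, var, 1.0))
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(var > 0, p, 1.0)
    return np.clip(p, 0.0, 1.0)


@dataclass
class ConsistencyReport:
    """Bundle of the consistency metrics for one cohort."""

    p_map: np.ndarray | None = None
    pct_significant: float | None = None
    subject_pct_map: np.ndarray | None = None
    subject_pct_map_blob: np.ndarray | None = None
    containment_pct: np.ndarray | None = None
    control_pct: np.ndarray | None = None
    containment_p: float | None = None
    rho: np.ndarray | None = None
    cross_matrix: np.ndarray | None = None
    tests: dict = field(default_factory=dict)


def pixel_signed_rank(stack: CohortStack, alpha: float = 0.05
                      ) -> tuple[np.ndarray, float]:
    """Per-pixel signed-rank test of subject values against the grand average.

    Returns the BH-corrected p map and the percentage of significant pixels.
    """
    if stack.n_subjects < 6:
        raise ValueError("need >= 6 subjects for the signed-rank test")
    grand = stack.data.mean(axis=0)
    d = stack.data - grand[None]
    p = signed_rank_p(d, axis=0)
    rej, p_adj = bh_fdr(p.ravel(), alpha)
    pct = 100.0 * rej.mean()
    return p_adj.reshape(p.shape), float(pct)


def subject_deviation_rate(window_stack: np.ndarray, alpha: float = 0.05,
                           min_channels: int = 2, min_hz: int = 3
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Percentage of subjects deviating from the population at each pixel.

    ``window_stack`` has shape (subjects, segments, channels, freqs); the
    1-s segment maps act as within-subject replicates.  For each subject
    and pixel a signed-rank test compares that subject's segment values
    with the population grand average (the mean over subjects of the
    subject-mean maps) at uncorrected ``alpha``.  Returns the per-pixel
    percentage of subjects flagged, and the blob-aggregated variant in
    which a subject counts at a pixel only when the pixel belongs to a
    surviving 2-contact x 3-Hz cluster of that subject's significance mask.
    """
    ws = np.asarray(window_stack, dtype=float)
    if ws.ndim != 4:
        raise ValueError("window_stack must be 4-D (subjects, segments, channels, freqs)")
    n_s, n_seg = ws.shape[:2]
    if n_seg < 20:
        raise ValueError("need >= 20 segment replicates per subject")
    grand = ws.mean(axis=1).mean(axis=0)  # population grand average map
    d = ws - grand[None, None]
    p = signed_rank_p(d, axis=1)  # (subjects, channels, freqs)
    sig = p < alpha
    pct = 100.0 * sig.mean(axis=0)
    blob = np.stack([blob_correction(sig[s], min_channels, min_hz) for s in range(n_s)])
    pct_blob = 100.0 * blob.mean(axis=0)
    return pct, pct_blob


def ci_containment(stack: CohortStack, level: float = 95.0, seed: int = 0,
                   leave_one_out: bool = False
                   ) -> tuple[np.ndarray, np.ndarray, float]:
    """Containment of individual maps in the pointwise population interval.

    The interval is the in-sample percentile interval across subjects at
    each pixel (2.5-97.5 for level 95); with ``leave_one_out=True`` each
    subject is scored against the interval of the remaining subjects.  Per
    subject, the containment percentage is the fraction of that subject's
    pixels inside the interval.  The control repeats the computation for
    subject maps whose channel rows were independently permuted; a paired
    signed-rank test compares observed and control percentages.
    """
    if not (0.0 < level < 100.0):
        raise ValueError("level must be in (0, 100)")
    if stack.n_subjects < 10:
        raise ValueError("need >= 10 subjects for a stable percentile interval")
    lo_q = (100.0 - level) / 2.0
    lo = np.percentile(stack.data, lo_q, axis=0)
    hi = np.percentile(stack.data, 100.0 - lo_q, axis=0)
    if leave_one_out:
        observed = np.empty(stack.n_subjects)
        for s in range(stack.n_subjects):
            rest = np.delete(stack.data, s, axis=0)
            lo_s = np.percentile(rest, lo_q, axis=0)
            hi_s = np.percentile(rest, 100.0 - lo_q, axis=0)
            observed[s] = 100.0 * ((stack.data[s] >= lo_s)
                                   & (stack.data[s] <= hi_s)).mean()
    else:
        inside = (stack.data >= lo[None]) & (stack.data <= hi[None])
        observed = 100.0 * inside.mean(axis=(1, 2))

    rng = np.random.default_rng(seed)
    nc = len(stack.channels)
    shuffled = np.stack([stack.data[s, rng.permutation(nc), :]
                         for s in range(stack.n_subjects)])
    inside_c = (shuffled >= lo[None]) & (shuffled <= hi[None])
    control = 100.0 * inside_c.mean(axis=(1, 2))

    diff = observed - control
    if np.allclose(diff, 0):
        p = 1.0
    else:
        p = float(stats.wilcoxon(observed, control).pvalue)
    return observed, control, p


def correlation_suite(stack: CohortStack) -> ConsistencyReport:
    """Per-subject correlation with the grand average and cross-subject matrix.

    rho_i is the Pearson correlation of subject i's flattened map with the
    grand-average map; R is the subjects x subjects correlation matrix.  The
    off-diagonal distribution (upper triangle) is tested against zero with a
    one-sample signed-rank test, as is the rho distribution.
    """
    if stack.n_subjects < 3:
        raise ValueError("need >= 3 subjects")
    flat = stack.data.reshape(stack.n_subjects, -1)
    if np.any(flat.std(axis=1) == 0):
        raise ValueError("zero-variance subject map")
    grand = flat.mean(axis=0)
    if grand.std() == 0:
        raise ValueError("zero-variance grand average")
    gc = grand - grand.mean()
    fc = flat - flat.mean(axis=1, keepdims=True)
    rho = (fc @ gc) / (np.linalg.norm(fc, axis=1) * np.linalg.norm(gc))
    R = np.corrcoef(flat)
    iu = np.triu_indices(stack.n_subjects, k=1)
    off = R[iu]
    tests = {
        "rho_vs_zero_p": float(stats.wilcoxon(rho).pvalue),
        "offdiag_vs_zero_p": float(stats.wilcoxon(off).pvalue),
        "rho_mean": float(rho.mean()),
        "offdiag_mean": float(off.mean()),
    }
    return ConsistencyReport(rho=rho, cross_matrix=R, tests=tests)
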