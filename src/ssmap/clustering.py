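"""Data-driven subtyping of spatio-spectral patterns and its validation.

PCA reduction to the components explaining 80% of cohort variance, gap
statistic selection of the cluster count (k = 1..10, uniform bounding-box
reference), k-means clustering, MANOVA/ANOVA association of clusters with
UPDRS III sub-score profiles, and the repeated-initialization robustness
simulation of that whole chain.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from statsmodels.multivariate.manova import MANOVA

from .permstats import bh_fdr
from .synthetic import CLINICAL_COLUMNS
from .types import CohortStack

ANOVA_TARGETS = CLINICAL_COLUMNS + ["age", "years_dx"]
SUBSCORES = CLINICAL_COLUMNS[1:]  # the six lateralized sub-scores


@dataclass
class PcaReduction:
    scores: np.ndarray  # (subjects, retained components)
    loadings: np.ndarray
    explained_ratio: np.ndarray
    var_target: float


def pca_reduce(stack: CohortStack | np.ndarray, var_target: float = 0.80) -> PcaReduction:
    """Project flattened subject maps onto the leading principal components.

    Components are retained until their cumulative explained variance first
    reaches ``var_target``.
    """
    if not (0.0 < var_target <= 1.0):
        raise ValueError("var_target must be in (0, 1]")
    X = stack.data.reshape(stack.n_subjects, -1) if isinstance(stack, CohortStack) \
        else np.asarray(stack, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need >= 3 subjects")
    pca = PCA()
    scores = pca.fit_transform(X)
    ratio = pca.explained_variance_ratio_
    cum = np.cumsum(ratio)
    nz = ratio > 1e-12
    if var_target >= 1.0:
        m = int(nz.sum())
    else:
        m = int(np.searchsorted(cum, var_target) + 1)
        m = min(m, int(nz.sum()))
    m = max(m, 1)
    return PcaReduction(scores=scores[:, :m], loadings=pca.components_[:m],
                        explained_ratio=ratio[:m], var_target=var_target)


@dataclass
class GapCurve:
    k_grid: np.ndarray
    gap: np.ndarray
    log_w_obs: np.ndarray
    log_w_ref_mean: np.ndarray
    k_star: int

    def __post_init__(self) -> None:
        assert self.k_grid[np.argmax(self.gap)] == self.k_star


def _within_dispersion(X: np.ndarray, k: int, rng: np.random.Generator,
                       n_init: int = 1) -> float:
    if k == 1:
        return float(((X - X.mean(axis=0)) ** 2).sum())
    km = KMeans(n_clusters=k, n_init=n_init,
                random_state=int(rng.integers(2 ** 31 - 1)))
    km.fit(X)
    return float(km.inertia_)


def gap_statistic(scores: np.ndarray, k_max: int = 10, b_ref: int = 50,
                  seed: int = 0, n_repeats: int = 1) -> GapCurve:
    """Gap statistic over k = 1..k_max with a uniform bounding-box reference.

    gap(k) = mean_b log(W_ref,b,k) - log(W_obs,k), with W the within-cluster
    sum of squared distances to centroids; the optimal k maximizes the gap.
    ``n_repeats`` > 1 averages the gap curve over independent repetitions
    (fresh k-means initializations and reference draws) before choosing k*,
    which is how fractional "average k" summaries arise when the argmax is
    taken per repeat (see :func:`gap_k_repeats`).
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim != 2:
        raise ValueError("scores must be 2-D")
    n = X.shape[0]
    if n <= k_max:
        raise ValueError("need more subjects than k_max")
    if np.allclose(X, X[0]):
        raise ValueError("degenerate scores: all points identical")
    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    ks = np.arange(1, k_max + 1)
    gap_acc = np.zeros(ks.size)
    lwo_acc = np.zeros(ks.size)
    lwr_acc = np.zeros(ks.size)
    for _ in range(max(1, n_repeats)):
        log_w_obs = np.array([np.log(_within_dispersion(X, k, rng)) for k in ks])
        log_w_ref = np.empty((b_ref, ks.size))
        for b in range(b_ref):
            ref = rng.uniform(lo, hi, size=X.shape)
            log_w_ref[b] = [np.log(_within_dispersion(ref, k, rng)) for k in ks]
        gap_acc += log_w_ref.mean(axis=0) - log_w_obs
        lwo_acc += log_w_obs
        lwr_acc += log_w_ref.mean(axis=0)
    r = max(1, n_repeats)
    gap = gap_acc / r
    k_star = int(ks[np.argmax(gap)])
    return GapCurve(k_grid=ks, gap=gap, log_w_obs=lwo_acc / r,
                    log_w_ref_mean=lwr_acc / r, k_star=k_star)


def gap_k_repeats(scores: np.ndarray, n_repeats: int = 10, **kw) -> float:
    """Average optimal k over repeated gap-statistic runs (fractional k)."""
    seeds = np.random.default_rng(kw.pop("seed", 0)).integers(2 ** 31 - 1, size=n_repeats)
    return float(np.mean([gap_statistic(scores, seed=int(s), **kw).k_star for s in seeds]))


@dataclass
class ClusterSolution:
    k: int
    labels: np.ndarray  # 1-based
    centroids: np.ndarray
    inertia: float
    seed: int


def kmeans_cluster(scores: np.ndarray, k: int, seed: int = 0,
                   n_restarts: int = 10) -> ClusterSolution:
    """Best-inertia k-means over ``n_restarts`` k-means++ initializations."""
    X = np.asarray(scores, dtype=float)
    if k > X.shape[0]:
        raise ValueError("k exceeds the number of subjects")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(X) + 1
    return ClusterSolution(k=k, labels=labels, centroids=km.cluster_centers_,
                           inertia=float(km.inertia_), seed=seed)


def manova_profiles(solution: ClusterSolution, clin: pd.DataFrame) -> float:
    """Wilks' lambda p-value of the UPDRS sub-score vector across clusters.

    The six lateralized sub-scores form the multivariate response and the
    cluster assignment the factor.  k = 1 (or any degenerate grouping)
    returns p = 1.  Collinear response columns are reduced before fitting.
    """
    labels = np.asarray(solution.labels)
    if np.unique(labels).size < 2:
        return 1.0
    counts = pd.Series(labels).value_counts()
    if counts.min() < 2:
        return 1.0
    Y = clin[SUBSCORES].to_numpy(dtype=float)
    keep = [j for j in range(Y.shape[1]) if Y[:, j].std() > 0]
    Yk = Y[:, keep]
    # reduce to full column rank
    while Yk.shape[1] > 1 and np.linalg.matrix_rank(Yk - Yk.mean(axis=0)) < Yk.shape[1]:
        Yk = Yk[:, :-1]
    if Yk.shape[1] == 0:
        return 1.0
    df = pd.DataFrame(Yk, columns=[f"y{j}" for j in range(Yk.shape[1])])
    df["cluster"] = labels
    formula = " + ".join(df.columns[:-1]) + " ~ C(cluster)"
    try:
        mv = MANOVA.from_formula(formula, data=df)
        tbl = mv.mv_test().results["C(cluster)"]["stat"]
        return float(tbl.loc["Wilks' lambda", "Pr > F"])
    except Exception:
        return 1.0


def anova_subscores(solution: ClusterSolution, clin: pd.DataFrame,
                    alpha: float = 0.05) -> pd.DataFrame:
    """One-way ANOVA per clinical target across clusters, BH-corrected.

    Targets are the six sub-scores, the UPDRS total, age and years since
    diagnosis.  Zero within-group variance for a target yields p = 1
    (degenerate exact ties).
    """
    labels = np.asarray(solution.labels)
    groups = np.unique(labels)
    ps = []
    for target in ANOVA_TARGETS:
        vals = [clin.loc[labels == g, target].to_numpy(dtype=float) for g in groups]
        if groups.size < 2 or any(len(v) < 2 for v in vals):
            ps.append(1.0)
            continue
        within = np.concatenate([v - v.mean() for v in vals])
        if np.allclose(within, 0):
            ps.append(1.0)
            continue
        ps.append(float(stats.f_oneway(*vals).pvalue))
    p = np.array(ps)
    rej, p_adj = bh_fdr(p, alpha)
    return pd.DataFrame({"target": ANOVA_TARGETS, "p": p, "p_fdr": p_adj, "sig": rej})


@dataclass
class RobustnessReport:
    pct_significant: pd.DataFrame  # rows (k, test) with % of iterations significant
    n_iter: int


def robustness_simulation(scores: np.ndarray, clin: pd.DataFrame, n_iter: int = 1000,
                          k_range: range | list[int] = range(2, 11), seed: int = 0,
                          alpha: float = 0.05) -> RobustnessReport:
    """Repeat k-means -> MANOVA -> ANOVAs with fresh random initializations.

    Each iteration clusters with a single random initialization, then runs
    the MANOVA on the sub-score vector (compared at ``alpha``) and the
    per-target ANOVAs (BH-corrected within iteration).  The report gives,
    per (k, test), the percentage of iterations that were significant.
    """
    rng = np.random.default_rng(seed)
    ks = list(k_range)
    counts: dict[tuple[int, str], int] = {(k, t): 0 for k in ks
                                          for t in ["manova"] + ANOVA_TARGETS}
    for _ in range(n_iter):
        for k in ks:
            s = int(rng.integers(2 ** 31 - 1))
            km = KMeans(n_clusters=k, n_init=1, init="random", random_state=s)
            labels = km.fit_predict(np.asarray(scores, dtype=float)) + 1
            sol = ClusterSolution(k=k, labels=labels, centroids=km.cluster_centers_,
                                  inertia=float(km.inertia_), seed=s)
            if manova_profiles(sol, clin) < alpha:
                counts[(k, "manova")] += 1
            tbl = anova_subscores(sol, clin, alpha)
            for t, sig in zip(tbl["target"], tbl["sig"]):
                if sig:
                    counts[(k, t)] += 1
    rows = [{"k": k, "test": t, "pct_significant": 100.0 * c / n_iter}
            for (k, t), c in sorted(counts.items())]
    return RobustnessReport(pct_significant=pd.DataFrame(rows), n_iter=n_iter)
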