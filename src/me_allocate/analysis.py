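"""Statistical characterization of condition-dependent biomass compositions.

The condition x component demand matrix produced by a panel scan is analyzed
four ways: principal components (aerobic and anaerobic states separate along
PC1; PC2 tracks residual growth-rate dependence), univariate outlier calling
(|z| > 3 per component, reported with log2 fold change against the mean),
Ward-linkage hierarchical clustering with the cluster count selected by the
gap statistic, and per-cluster Wilcoxon rank-sum characterization against
the out-of-cluster conditions (retained at p < 1e-5 and |log2 fold change|
> 0.15 by default).  A conditional-essentiality matrix flags, per condition,
which cofactors carry any synthesis demand at all.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import mannwhitneyu, spearmanr, pearsonr
from sklearn.decomposition import PCA

__all__ = [
    "PCAResult",
    "ClusteringResult",
    "pca_compositions",
    "find_outliers",
    "max_normalize",
    "cluster_conditions",
    "gap_statistic",
    "characterize_clusters",
    "conditional_essentiality",
    "wilcoxon_rank_sum",
]

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# PCA
# --------------------------------------------------------------------------

@dataclass
class PCAResult:
    scores: pd.DataFrame            # conditions x PCs
    loadings: pd.DataFrame          # components x PCs
    explained_variance_ratio: np.ndarray
    pc2_growth_spearman: Optional[float] = None
    pc2_growth_pearson: Optional[float] = None


def pca_compositions(table: pd.DataFrame, standardize: bool = True,
                     growth: Optional[pd.Series] = None,
                     aerobic: Optional[pd.Series] = None,
                     n_components: Optional[int] = None) -> PCAResult:
    """Principal components of the condition x component demand matrix.

    Components are z-scored first by default since demand magnitudes span
    orders of magnitude; ``standardize=False`` gives covariance PCA.  When an
    ``aerobic`` label series is supplied, the PC1 sign is fixed so aerobic
    conditions score on the negative side (cofactors favored aerobically get
    negative loadings).  When ``growth`` is supplied, the rank (Spearman) and
    Pearson correlations of PC2 scores with growth rate are reported.
    """
    if table.shape[0] < 3 or table.shape[1] < 2:
        raise ValueError("need at least 3 conditions and 2 components")
    X = table.to_numpy(dtype=float)
    col_sd = X.std(axis=0, ddof=0)
    if np.all(col_sd == 0):
        raise ValueError("degenerate input: demand matrix is constant")
    if standardize:
        keep = col_sd > 0
        X = (X[:, keep] - X[:, keep].mean(axis=0)) / col_sd[keep]
        columns = table.columns[keep]
    else:
        columns = table.columns
    n_comp = n_components or min(X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T  # components x PCs
    # deterministic signs: largest-magnitude loading positive per PC
    for k in range(scores.shape[1]):
        pivot = np.argmax(np.abs(loadings[:, k]))
        if loadings[pivot, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    if aerobic is not None and scores.shape[1] >= 1:
        aer = aerobic.reindex(table.index).astype(bool).to_numpy()
        if aer.any() and scores[aer, 0].mean() > 0:
            scores[:, 0] *= -1
            loadings[:, 0] *= -1
    pc_names = [f"PC{k + 1}" for k in range(scores.shape[1])]
    result = PCAResult(
        scores=pd.DataFrame(scores, index=table.index, columns=pc_names),
        loadings=pd.DataFrame(loadings, index=columns, columns=pc_names),
        explained_variance_ratio=pca.explained_variance_ratio_,
    )
    if growth is not None and scores.shape[1] >= 2:
        g = growth.reindex(table.index).to_numpy(dtype=float)
        if np.std(g) > 0 and np.std(scores[:, 1]) > 0:
            result.pc2_growth_spearman = float(spearmanr(scores[:, 1], g)[0])
            result.pc2_growth_pearson = float(pearsonr(scores[:, 1], g)[0])
    return result


# --------------------------------------------------------------------------
# Outliers
# --------------------------------------------------------------------------

def find_outliers(table: pd.DataFrame, z_thresh: float = 3.0) -> pd.DataFrame:
    """Per-component z-scoring across conditions; report |z| > z_thresh.

    Returns a frame with columns condition, component, z, log2fc where
    log2fc compares the outlying value to the component's cross-condition
    mean.  Zero-variance components are skipped with a log line.
    """
    rows = []
    for component in table.columns:
        vals = table[component].to_numpy(dtype=float)
        sd = vals.std(ddof=1) if len(vals) > 1 else 0.0
        if sd == 0:
            logger.info("component %s has zero variance; skipped", component)
            continue
        mean = vals.mean()
        z = (vals - mean) / sd
        for idx, cond in enumerate(table.index):
            if abs(z[idx]) > z_thresh:
                value = vals[idx]
                log2fc = (math.log2(value / mean)
                          if value > 0 and mean > 0 else float("nan"))
                rows.append({"condition": cond, "component": component,
                             "z": float(z[idx]), "log2fc": log2fc})
    return pd.DataFrame(rows, columns=["condition", "component", "z", "log2fc"])


# --------------------------------------------------------------------------
# Clustering with gap-statistic model selection
# --------------------------------------------------------------------------

@dataclass
class ClusteringResult:
    labels: pd.Series               # condition -> cluster index (1-based)
    k: int
    gap_curve: dict[int, float] = field(default_factory=dict)
    linkage_method: str = "ward"
    normalization: str = "max"
    excluded_outliers: list[str] = field(default_factory=list)


def max_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Divide each component by its maximum across conditions (max -> 1).

    All-zero columns are dropped (no scale to normalize by).
    """
    maxima = table.max(axis=0)
    keep = maxima > 0
    return table.loc[:, keep] / maxima[keep]


def _ward_labels(X: np.ndarray, k: int) -> np.ndarray:
    if k <= 1 or X.shape[0] <= 1:
        return np.ones(X.shape[0], dtype=int)
    Z = linkage(X, method="ward")
    return fcluster(Z, t=k, criterion="maxclust")


def _within_dispersion(X: np.ndarray, labels: np.ndarray) -> float:
    """W_k = sum over clusters of D_r / (2 n_r), D_r = sum of pairwise sq dists."""
    total = 0.0
    for lab in np.unique(labels):
        pts = X[labels == lab]
        if len(pts) < 2:
            continue
        d = pdist(pts, metric="sqeuclidean").sum()
        total += d / (2.0 * len(pts))
    return total


def gap_statistic(X: np.ndarray, k_range: Sequence[int], B: int = 50,
                  seed: int = 0) -> tuple[int, dict[int, float]]:
    """Gap(k) = E*[log W_k] - log W_k against a uniform reference over the
    data's bounding box.

    The optimal k is selected with the standard elbow rule: the smallest k
    such that Gap(k) >= Gap(k+1) - s(k+1), where s(k) is the reference
    standard deviation inflated by sqrt(1 + 1/B).  This guards against the
    near-flat gap plateau beyond the true cluster count; if the rule never
    triggers, the k with the largest gap is returned.
    """
    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    gaps: dict[int, float] = {}
    sks: dict[int, float] = {}
    ref_sets = [rng.uniform(lo, hi, size=X.shape) for _ in range(B)]
    for k in k_range:
        if k > X.shape[0]:
            break
        w = _within_dispersion(X, _ward_labels(X, k))
        log_w = math.log(w) if w > 0 else -np.inf
        ref_logs = []
        for ref in ref_sets:
            wr = _within_dispersion(ref, _ward_labels(ref, k))
            ref_logs.append(math.log(wr) if wr > 0 else -np.inf)
        gaps[k] = float(np.mean(ref_logs) - log_w)
        sks[k] = float(np.std(ref_logs, ddof=0) * math.sqrt(1.0 + 1.0 / B))
    if not gaps:
        raise ValueError("empty k range")
    ks = sorted(gaps)
    for k, k_next in zip(ks, ks[1:]):
        if gaps[k] >= gaps[k_next] - sks[k_next]:
            return k, gaps
    best = max(gaps, key=lambda k: (gaps[k], -k))
    return best, gaps


def cluster_conditions(table: pd.DataFrame,
                       outliers: Optional[pd.DataFrame] = None,
                       k: Optional[int] = None,
                       k_range: Sequence[int] = range(1, 9),
                       B: int = 50, seed: int = 0) -> ClusteringResult:
    """Ward-linkage clustering of max-normalized compositions.

    Conditions named in ``outliers`` (as produced by :func:`find_outliers`)
    are removed first, then each component is divided by its maximum across
    the remaining conditions.  ``k=None`` selects the cluster count by
    maximizing the gap statistic over ``k_range`` with ``B`` seeded uniform
    reference draws.
    """
    excluded: list[str] = []
    work = table
    if outliers is not None and len(outliers):
        excluded = sorted(set(outliers["condition"]) & set(table.index))
        work = table.drop(index=excluded)
    if work.empty:
        raise ValueError("no conditions left after outlier removal")
    norm = max_normalize(work)
    X = norm.to_numpy(dtype=float)
    gap_curve: dict[int, float] = {}
    if k is None:
        k, gap_curve = gap_statistic(X, k_range, B=B, seed=seed)
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds condition count {X.shape[0]}")
    labels = _ward_labels(X, k)
    return ClusteringResult(
        labels=pd.Series(labels, index=norm.index, name="cluster"),
        k=int(len(np.unique(labels))), gap_curve=gap_curve,
        excluded_outliers=excluded)


# --------------------------------------------------------------------------
# Rank-sum characterization
# --------------------------------------------------------------------------

def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float],
                      exact_max_n: int = 40) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    For small tie-free samples the exact null distribution of the rank-sum
    statistic (equivalently the Mann-Whitney U enumeration) is used, which
    matches a full permutation test; larger or tied samples fall back on the
    normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= exact_max_n and not has_ties) \
        else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def characterize_clusters(table: pd.DataFrame, labels: pd.Series,
                          p_thresh: float = 1e-5,
                          lfc_thresh: float = 0.15) -> pd.DataFrame:
    """Per-cluster components that differ from the out-of-cluster conditions.

    Two-sided Wilcoxon rank-sum per (cluster, component), in-cluster vs
    out-of-cluster; retained when p < ``p_thresh`` and |log2 fold change of
    the cluster mean over the non-cluster mean| > ``lfc_thresh``.  Clusters
    of size 1 (or with an empty complement) are skipped — the rank test is
    degenerate there.
    """
    labels = labels.reindex(table.index)
    rows = []
    for cluster in sorted(labels.dropna().unique()):
        in_mask = (labels == cluster).to_numpy()
        if in_mask.sum() < 2 or (~in_mask).sum() < 1:
            logger.warning("cluster %s skipped (size %d, complement %d)",
                           cluster, in_mask.sum(), (~in_mask).sum())
            continue
        for component in table.columns:
            vals = table[component].to_numpy(dtype=float)
            a, b = vals[in_mask], vals[~in_mask]
            if np.all(a == a[0]) and np.all(b == a[0]):
                continue  # identical across all conditions: never retained
            p = wilcoxon_rank_sum(a, b)
            mean_in, mean_out = a.mean(), b.mean()
            if mean_in > 0 and mean_out > 0:
                log2fc = math.log2(mean_in / mean_out)
            else:
                log2fc = float("nan")
            if p < p_thresh and abs(log2fc) > lfc_thresh:
                rows.append({"cluster": cluster, "component": component,
                             "log2fc": log2fc, "p": p})
    return pd.DataFrame(rows, columns=["cluster", "component", "log2fc", "p"])


# --------------------------------------------------------------------------
# Conditional essentiality
# --------------------------------------------------------------------------

def conditional_essentiality(table: pd.DataFrame,
                             cofactors: Optional[Sequence[str]] = None
                             ) -> pd.DataFrame:
    """Boolean condition x cofactor matrix: demand > 0 in that condition.

    ``cofactors`` restricts the columns (e.g. to prosthetic groups and
    coenzymes); by default every column of the table is assessed.
    """
    work = table if cofactors is None else table.loc[:, list(cofactors)]
    return work > 0.0
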