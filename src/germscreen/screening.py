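"""Multivariate screening: PCA, hierarchical k-means, and group tests.

The STI matrix (accessions x indices) is standardized, summarized by PCA,
and partitioned by hierarchical k-means: Ward agglomeration cut at k seeds a
Lloyd k-means refinement, making the partition reproducible.  Group
differences are assessed with one-way ANOVA plus Sidak-adjusted all-pairs
contrasts (parametric path) or Kruskal-Wallis plus Dunn's test with a
Bonferroni correction (rank path), both emitting compact letter displays.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = [
    "PCAResult",
    "ClusterAssignment",
    "GroupTestResult",
    "pca_sti",
    "hkmeans",
    "kruskal_wallis",
    "dunn_bonferroni",
    "anova_pairwise",
    "compact_letters",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAResult:
    scores: pd.DataFrame  # observation x component coordinates
    loadings: pd.DataFrame  # feature x component weights (orthonormal columns)
    var_explained: np.ndarray  # proportion of total variance per component
    mean: np.ndarray
    scale: np.ndarray


def _standardize(X: pd.DataFrame, scale: bool) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean().to_numpy()
    if scale:
        sd = X.std(ddof=1).to_numpy()
        zero = np.where(sd == 0)[0]
        if zero.size:
            names = [X.columns[i] for i in zero]
            raise ValueError(f"constant column(s) cannot be scaled: {names}")
    else:
        sd = np.ones(X.shape[1])
    return (X.to_numpy() - mean) / sd, mean, sd


def _impute_column_means(X: pd.DataFrame) -> pd.DataFrame:
    """Column-mean imputation for missing STIs (undefined GSI/NR etc.)."""
    n_missing = int(X.isna().to_numpy().sum())
    if n_missing:
        log.info("imputing %d missing value(s) with column means", n_missing)
        X = X.fillna(X.mean())
    return X

def pca_sti(X: pd.DataFrame, scale: bool = True) -> PCAResult:
    """PCA of the (optionally standardized) STI matrix.

    Components are ordered by variance; signs are fixed so the largest-
    magnitude loading of each component is positive, making outputs stable
    for snapshot comparison.  Missing entries are column-mean imputed.
    """
    if X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("need at least 3 observations and 2 features")
    X = _impute_column_means(X)
    Z, mean, sd = _standardize(X, scale)
    n_comp = min(Z.shape)
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(Z)
    load = pca.components_.T  # feature x component
    # sign convention
    for j in range(load.shape[1]):
        i = int(np.argmax(np.abs(load[:, j])))
        if load[i, j] < 0:
            load[:, j] *= -1
            scores[:, j] *= -1
    names = [f"PC{i + 1}" for i in range(load.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(scores, index=X.index, columns=names),
        loadings=pd.DataFrame(load, index=X.columns, columns=names),
        var_explained=pca.explained_variance_ratio_,
        mean=mean,
        scale=sd,
    )


# ---------------------------------------------------------------------------
# Hierarchical k-means
# ---------------------------------------------------------------------------


@dataclass
class ClusterAssignment:
    k: int
    labels: pd.Series  # observation -> cluster id (1..k, by descending size)
    centroids: np.ndarray
    inertia: float  # total within-cluster SS after k-means refinement
    init_inertia: float  # at the Ward initialization
    linkage_method: str = "ward"
    distance: str = "euclidean"
    rng_seed: int | None = None


def _within_ss(Z: np.ndarray, labels: np.ndarray) -> float:
    tot = 0.0
    for lab in np.unique(labels):
        pts = Z[labels == lab]
        tot += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return tot


def hkmeans(
    features: pd.DataFrame,
    k: int = 3,
    seed: int | None = None,
    scale: bool = True,
) -> ClusterAssignment:
    """Hierarchical k-means: Ward cut at k initializes Lloyd's refinement.

    The refinement can only lower the total within-cluster sum of squares
    relative to the hierarchical cut.  Cluster ids are renumbered 1..k by
    descending size so labels are stable across runs.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if features.shape[0] <= k:
        raise ValueError("need more observations than clusters")
    X = _impute_column_means(features)
    Z, _, _ = _standardize(X, scale)
    lk = linkage(Z, method="ward")
    init_labels = fcluster(lk, t=k, criterion="maxclust")
    centroids = np.vstack([Z[init_labels == c].mean(axis=0) for c in range(1, k + 1)])
    init_inertia = _within_ss(Z, init_labels)
    km = KMeans(n_clusters=k, init=centroids, n_init=1, random_state=seed)
    km.fit(Z)
    labels = km.labels_
    # renumber by descending cluster size, ties broken by first appearance
    sizes = np.bincount(labels, minlength=k)
    order = sorted(range(k), key=lambda c: (-sizes[c], np.argmax(labels == c)))
    remap = {old: new + 1 for new, old in enumerate(order)}
    new_labels = np.array([remap[c] for c in labels])
    new_centroids = km.cluster_centers_[order]
    return ClusterAssignment(
        k=k,
        labels=pd.Series(new_labels, index=features.index, name="cluster"),
        centroids=new_centroids,
        inertia=float(km.inertia_),
        init_inertia=init_inertia,
        rng_seed=seed,
    )


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------


@dataclass
class GroupTestResult:
    method: str
    statistic: float
    df: float
    p_value: float
    pairwise: pd.DataFrame | None = None  # group_a, group_b, statistic, adjusted_p, significant
    letters: dict = field(default_factory=dict)
    flagged: bool = False


def _as_groups(groups: dict | list) -> dict:
    if isinstance(groups, dict):
        return {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    return {i + 1: np.asarray(v, dtype=float) for i, v in enumerate(groups)}


def compact_letters(
    groups_ordered: list,
    significant_pairs: set[tuple],
) -> dict:
    """Compact letter display via the insert-and-absorb algorithm.

    Groups sharing a letter are not significantly different.  ``groups_ordered``
    fixes letter ordering (typically by descending mean or mean rank).
    """
    sets: list[set] = [set(groups_ordered)]
    for a, b in significant_pairs:
        new_sets: list[set] = []
        for s in sets:
            if a in s and b in s:
                new_sets.extend([s - {a}, s - {b}])
            else:
                new_sets.append(s)
        # absorb: drop empty sets, strict subsets and duplicates
        pruned: list[set] = []
        for s in new_sets:
            if not s or any(s < t for t in new_sets) or s in pruned:
                continue
            pruned.append(s)
        sets = pruned
    pos = {g: i for i, g in enumerate(groups_ordered)}
    sets.sort(key=lambda s: min(pos[g] for g in s))
    letters = {g: "" for g in groups_ordered}
    for i, s in enumerate(sets):
        ch = chr(ord("a") + i)
        for g in groups_ordered:
            if g in s:
                letters[g] += ch
    return letters


def kruskal_wallis(groups: dict | list) -> GroupTestResult:
    """Kruskal-Wallis H with tie correction against chi-square(k-1)."""
    gd = _as_groups(groups)
    if len(gd) < 2:
        raise ValueError("need at least two groups")
    values = np.concatenate(list(gd.values()))
    if np.unique(values).size < 2:
        return GroupTestResult("kruskal-wallis", 0.0, len(gd) - 1, 1.0)
    H, p = stats.kruskal(*gd.values())
    return GroupTestResult("kruskal-wallis", float(H), len(gd) - 1, float(p))


def dunn_bonferroni(groups: dict | list, alpha: float = 0.05) -> GroupTestResult:
    """Dunn's rank-based pairwise test with Bonferroni adjustment.

    z_ab = (mean-rank difference) / sqrt((N(N+1)/12 - tie term)(1/n_a + 1/n_b)),
    tie term = sum(t^3 - t) / (12 (N - 1)); adjusted p = min(1, p * k(k-1)/2).
    """
    gd = _as_groups(groups)
    omnibus = kruskal_wallis(gd)
    names = list(gd)
    values = np.concatenate([gd[g] for g in names])
    sizes = {g: gd[g].size for g in names}
    N = values.size
    ranks = stats.rankdata(values)
    mean_rank = {}
    start = 0
    for g in names:
        n = sizes[g]
        mean_rank[g] = float(ranks[start : start + n].mean())
        start += n
    _, counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (N - 1)) if N > 1 else 0.0
    var_base = N * (N + 1) / 12.0 - tie_term
    m = len(names) * (len(names) - 1) // 2
    rows = []
    sig = set()
    for a, b in combinations(names, 2):
        denom = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_rank[a] - mean_rank[b]) / denom if denom > 0 else 0.0
        p = 2 * stats.norm.sf(abs(z))
        adj = min(1.0, p * m)
        significant = adj <= alpha
        if significant:
            sig.add((a, b))
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "statistic": z,
                "p": p,
                "adjusted_p": adj,
                "significant": significant,
            }
        )
    ordered = sorted(names, key=lambda g: -mean_rank[g])
    letters = compact_letters(ordered, sig)
    return GroupTestResult(
        method="dunn-bonferroni",
        statistic=omnibus.statistic,
        df=omnibus.df,
        p_value=omnibus.p_value,
        pairwise=pd.DataFrame(rows),
        letters=letters,
    )


def anova_pairwise(
    groups: dict | list,
    adjust: str = "sidak",
    alpha: float = 0.05,
) -> GroupTestResult:
    """One-way ANOVA with all-pairs mean contrasts.

    Contrasts use the pooled error variance; p-values are Sidak-adjusted
    (1 - (1-p)^m over the m pairs) by default, with Tukey's HSD available via
    ``adjust="tukey"``.  If every group has zero within-group variance the F
    statistic is undefined and the result is flagged.
    """
    if adjust not in ("sidak", "tukey"):
        raise ValueError("adjust must be 'sidak' or 'tukey'")
    gd = _as_groups(groups)
    names = list(gd)
    k = len(names)
    if k < 2 or any(v.size < 2 for v in gd.values()):
        raise ValueError("need >= 2 groups with >= 2 values each")
    N = sum(v.size for v in gd.values())
    grand = np.concatenate(list(gd.values())).mean()
    ssw = sum(float(((v - v.mean()) ** 2).sum()) for v in gd.values())
    ssb = sum(v.size * (v.mean() - grand) ** 2 for v in gd.values())
    dfw = N - k
    dfb = k - 1
    if ssw == 0:
        return GroupTestResult(
            method=f"anova-{adjust}",
            statistic=float("nan"),
            df=dfb,
            p_value=float("nan"),
            flagged=True,
        )
    mse = ssw / dfw
    F = (ssb / dfb) / mse
    p_omni = float(stats.f.sf(F, dfb, dfw))
    m = k * (k - 1) // 2
    rows = []
    sig = set()
    if adjust == "tukey":
        res = stats.tukey_hsd(*gd.values())
    for idx, (a, b) in enumerate(combinations(range(k), 2)):
        ga, gb = names[a], names[b]
        va, vb = gd[ga], gd[gb]
        t = (va.mean() - vb.mean()) / np.sqrt(mse * (1 / va.size + 1 / vb.size))
        if adjust == "sidak":
            p_raw = 2 * stats.t.sf(abs(t), dfw)
            adj = 1 - (1 - p_raw) ** m
        else:
            adj = float(res.pvalue[a, b])
        significant = adj <= alpha
        if significant:
            sig.add((ga, gb))
        rows.append(
            {
                "group_a": ga,
                "group_b": gb,
                "statistic": float(t),
                "adjusted_p": float(adj),
                "significant": significant,
            }
        )
    ordered = sorted(names, key=lambda g: -gd[g].mean())
    letters = compact_letters(ordered, sig)
    return GroupTestResult(
        method=f"anova-{adjust}",
        statistic=float(F),
        df=dfb,
        p_value=p_omni,
        pairwise=pd.DataFrame(rows),
        letters=letters,
    )
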