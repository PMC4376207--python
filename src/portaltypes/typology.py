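"""Outlier exclusion, factor-score reduction, Ward clustering and k selection.

The reduction is a principal-components factor analysis: columns are
z-scored, loadings are the leading eigenvectors of the correlation matrix
scaled by the square roots of their eigenvalues, rotated by varimax with
Kaiser normalization, and factor scores are obtained by the regression
method (``scores = Z R^{-1} L``).  A deterministic sign convention makes
each rotated factor's largest-magnitude loading positive.

Clustering is Ward's minimum-variance agglomeration on the factor scores.
The number of clusters is chosen with the cubic clustering criterion (CCC,
Sarle's uniform-hypercube null formulation) used as a guide together with
the Duda–Hart pseudo-t² merge statistic: a local CCC peak corroborated by a
pseudo-t² jump at the corresponding merge.  The full diagnostic table is
always reported so callers can override the automatic choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = [
    "OutlierReport",
    "FactorModel",
    "ClusterTree",
    "KSelection",
    "filter_outliers",
    "fit_factors",
    "varimax",
    "ward_cluster",
    "select_k",
    "cut_clusters",
    "cubic_clustering_criterion",
]


# ---------------------------------------------------------------- outliers


@dataclass
class OutlierReport:
    threshold_value: float
    excluded_ids: list[str]
    retained_matrix: pd.DataFrame
    column: str = "sess"
    percentile: float = 99.0


def nearest_rank_percentile(values: np.ndarray, percentile: float) -> float:
    """Nearest-rank (type 1) empirical percentile: the smallest observation
    with at least ``percentile`` percent of the sample at or below it."""
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    ordered = np.sort(np.asarray(values))
    rank = math.ceil(percentile / 100.0 * ordered.size)
    return float(ordered[rank - 1])


def filter_outliers(
    matrix: pd.DataFrame,
    on: str = "sess",
    percentile: float = 99.0,
) -> OutlierReport:
    """Drop patients whose ``on`` value strictly exceeds the empirical
    percentile (nearest-rank).  A constant column yields zero exclusions."""
    if matrix.empty:
        raise ValueError("matrix is empty")
    threshold = nearest_rank_percentile(matrix[on].to_numpy(), percentile)
    mask = matrix[on] > threshold
    return OutlierReport(
        threshold_value=threshold,
        excluded_ids=sorted(matrix.index[mask]),
        retained_matrix=matrix.loc[~mask],
        column=on,
        percentile=percentile,
    )


# ---------------------------------------------------------------- factors


@dataclass
class FactorModel:
    n_factors: int
    loadings: pd.DataFrame  # variables x factors, varimax-rotated
    scores: pd.DataFrame  # patients x factors, regression method
    variance_explained: np.ndarray  # per rotated factor, proportion of total
    mean: pd.Series
    scale: pd.Series

    @property
    def communalities(self) -> pd.Series:
        return (self.loadings**2).sum(axis=1)


def varimax(loadings: np.ndarray, kaiser: bool = True, max_iter: int = 500,
            tol: float = 1e-10) -> np.ndarray:
    """Varimax rotation (orthogonal), optionally Kaiser-normalized.

    Iterative SVD-based algorithm; returns the rotated loading matrix.
    Communalities (row sums of squares) are invariant under the rotation.
    """
    L = np.asarray(loadings, dtype=float).copy()
    p, k = L.shape
    if k < 2:
        return L
    h = np.sqrt((L**2).sum(axis=1))
    if kaiser:
        safe = np.where(h > 0, h, 1.0)
        L = L / safe[:, None]
    R = np.eye(k)
    var = 0.0
    for _ in range(max_iter):
        Lr = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (Lr**3 - Lr @ np.diag((Lr**2).sum(axis=0)) / p)
        )
        R = u @ vt
        new_var = s.sum()
        if new_var <= var * (1 + tol):
            break
        var = new_var
    L = L @ R
    if kaiser:
        L = L * safe[:, None]
        L[h == 0] = 0.0
    return L


def fit_factors(
    matrix: pd.DataFrame,
    n_factors: int = 10,
    standardize: bool = True,
) -> FactorModel:
    """Principal-components factor analysis with varimax rotation.

    Requires more patients than variables and no missing values; a
    zero-variance column is an error naming the column (the caller must drop
    or jitter it).
    """
    X = matrix.to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more patients ({n}) than variables ({p})")
    if np.isnan(X).any():
        raise ValueError("matrix contains missing values")
    if not 1 <= n_factors <= p:
        raise ValueError(f"n_factors must be in [1, {p}]")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [matrix.columns[j] for j in dead]
        raise ValueError(f"zero-variance column(s): {names}")
    Z = (X - mean) / sd if standardize else X - mean
    R = np.corrcoef(Z, rowvar=False) if standardize else np.cov(Z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1][:n_factors]
    lam = np.clip(eigval[order], 0.0, None)
    L = eigvec[:, order] * np.sqrt(lam)
    L = varimax(L)
    # deterministic sign: each factor's largest-|loading| entry positive
    for j in range(L.shape[1]):
        i = int(np.argmax(np.abs(L[:, j])))
        if L[i, j] < 0:
            L[:, j] = -L[:, j]
    # order rotated factors by explained variance, descending
    ssq = (L**2).sum(axis=0)
    order2 = np.argsort(-ssq, kind="stable")
    L = L[:, order2]
    ssq = ssq[order2]
    # regression-method scores: W = R^{-1} L  (R is the correlation matrix)
    W = np.linalg.solve(R, L)
    scores = Z @ W
    cols = [f"factor{j + 1}" for j in range(n_factors)]
    return FactorModel(
        n_factors=n_factors,
        loadings=pd.DataFrame(L, index=matrix.columns, columns=cols),
        scores=pd.DataFrame(scores, index=matrix.index, columns=cols),
        variance_explained=ssq / p,
        mean=pd.Series(mean, index=matrix.columns),
        scale=pd.Series(sd if standardize else np.ones(p), index=matrix.columns),
    )


# ---------------------------------------------------------------- clustering


@dataclass
class ClusterTree:
    """Ward agglomeration: scipy linkage matrix plus the leaf identifiers."""

    linkage_matrix: np.ndarray
    leaf_ids: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]


def ward_cluster(scores: pd.DataFrame) -> ClusterTree:
    """Ward's minimum-variance agglomerative tree on the factor scores.

    At each step the pair of clusters whose merge least increases the total
    within-cluster sum of squares is joined; merge heights are monotone
    non-decreasing and relate to that increase by ``height^2 = 2 * dSSE``.
    """
    X = scores.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 observations to cluster")
    if not np.isfinite(X).all():
        raise ValueError("scores must be finite")
    Z = linkage(X, method="ward")
    return ClusterTree(Z, list(scores.index))


def cut_clusters(tree: ClusterTree, k: int) -> pd.Series:
    """Cut the tree into k clusters, renumbered 1..k by descending size.

    Size ties keep the order of first appearance in the raw cut, so the
    labelling is deterministic.
    """
    if not 1 <= k <= tree.n_leaves:
        raise ValueError(f"k must be in [1, {tree.n_leaves}]")
    raw = fcluster(tree.linkage_matrix, t=k, criterion="maxclust")
    sizes = pd.Series(raw).value_counts()  # sorted desc, stable for ties
    remap = {old: new for new, old in enumerate(sizes.index, start=1)}
    labels = pd.Series([remap[r] for r in raw], index=tree.leaf_ids, name="cluster")
    labels.index.name = "patient_id"
    return labels


# ---------------------------------------------------------------- k selection


def cubic_clustering_criterion(X: np.ndarray, labels: np.ndarray) -> float:
    """CCC for one partition, following Sarle's SAS technical-report form.

    The observed R² (between-cluster share of total sum of squares) is
    compared with its expectation under a uniform distribution on a
    hyperbox aligned with the data's principal axes; large positive values
    indicate more cluster structure than the uniform null produces.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    q = len(np.unique(labels))
    Xc = X - X.mean(axis=0)
    total_ss = float((Xc**2).sum())
    if total_ss == 0:
        raise ValueError("degenerate data: zero total variance")
    within = 0.0
    for g in np.unique(labels):
        sub = X[labels == g]
        within += float(((sub - sub.mean(axis=0)) ** 2).sum())
    r2 = 1.0 - within / total_ss

    # hyperbox edge lengths proportional to sqrt eigenvalues of the covariance
    s = np.sqrt(np.clip(np.linalg.eigvalsh(np.cov(X, rowvar=False)), 0, None))[::-1]
    s = np.where(s > 0, s, np.finfo(float).tiny)
    # p*: dimensionality of between-cluster variation; largest p* with
    # u_{p*} >= 1, capped at q - 1
    p_star = 1
    for cand in range(min(p, q - 1), 0, -1):
        c = (np.prod(s[:cand]) / q) ** (1.0 / cand)
        if s[cand - 1] / c >= 1.0:
            p_star = cand
            break
    c = (np.prod(s[:p_star]) / q) ** (1.0 / p_star)
    u = s / c
    num = (1.0 / (n + u[:p_star])).sum() + (u[p_star:] ** 2 / (n + u[p_star:])).sum()
    e_r2 = 1.0 - (num / (u**2).sum()) * ((n - q) ** 2 / n) * (1 + 4.0 / n)
    e_r2 = min(max(e_r2, 1e-12), 1 - 1e-12)
    r2 = min(r2, 1 - 1e-12)
    return float(
        math.log((1 - e_r2) / (1 - r2))
        * math.sqrt(n * p_star / 2.0)
        / ((0.001 + e_r2) ** 1.2)
    )


def _pseudo_t2_by_k(tree: ClusterTree) -> dict[int, float]:
    """Duda–Hart pseudo-t² of the merge that produces each k-cluster level.

    For a merge joining clusters A and B, t² = dSSE / ((W_A + W_B)/(n_A+n_B-2))
    where W are within-cluster sums of squares and dSSE = height² / 2 under
    Ward.  Merging two singletons has an undefined denominator; reported as 0
    when the merge is at height 0 and +inf otherwise.
    """
    Z = tree.linkage_matrix
    n = tree.n_leaves
    wss = np.zeros(n + len(Z))  # within-SS per node
    sizes = np.ones(n + len(Z))
    out: dict[int, float] = {}
    for m, (a, b, h, size) in enumerate(Z):
        a, b = int(a), int(b)
        d_sse = h * h / 2.0
        node = n + m
        wss[node] = wss[a] + wss[b] + d_sse
        sizes[node] = size
        dof = sizes[a] + sizes[b] - 2
        pooled = wss[a] + wss[b]
        if dof <= 0 or pooled == 0:
            t2 = 0.0 if d_sse == 0 else math.inf
        else:
            t2 = d_sse / (pooled / dof)
        out[n - m - 1] = t2  # this merge leaves n-m-1 clusters
    return out


@dataclass
class KSelection:
    k_range: list[int]
    ccc_values: dict[int, float]
    pseudo_t2_values: dict[int, float]  # keyed by resulting cluster count
    chosen_k: int
    diagnostics: pd.DataFrame = field(repr=False, default=None)


def select_k(
    tree: ClusterTree,
    scores: pd.DataFrame,
    k_range: range | list[int] = range(2, 16),
) -> KSelection:
    """Choose the number of clusters from CCC and pseudo-t² diagnostics.

    For each candidate k the CCC of the k-cluster cut is computed, and the
    pseudo-t² of the merge that would reduce k clusters to k-1 is read off
    the tree.  The rule: candidate k values where CCC peaks locally are
    scored by the pseudo-t² jump (t² of the merge going below k minus t² of
    the merge that formed k); the candidate with the largest positive jump
    wins, falling back to the largest jump overall.  The full table is
    returned so the choice can be overridden.
    """
    ks = [k for k in k_range if 2 <= k <= tree.n_leaves - 1]
    if not ks:
        raise ValueError("k_range contains no feasible k")
    X = scores.to_numpy(dtype=float)
    pt2 = _pseudo_t2_by_k(tree)
    ccc: dict[int, float] = {}
    for k in ks:
        labels = fcluster(tree.linkage_matrix, t=k, criterion="maxclust")
        ccc[k] = cubic_clustering_criterion(X, labels)

    def jump(k: int) -> float:
        below = pt2.get(k - 1, 0.0)  # merge destroying the k-cluster level
        formed = pt2.get(k, 0.0)  # merge that created the k-cluster level
        if math.isinf(below):
            return math.inf
        if math.isinf(formed):
            return -math.inf
        return below - formed

    peaks = [
        k
        for i, k in enumerate(ks)
        if (i == 0 or ccc[k] >= ccc[ks[i - 1]])
        and (i == len(ks) - 1 or ccc[k] >= ccc[ks[i + 1]])
    ]
    candidates = [k for k in peaks if jump(k) > 0] or ks
    chosen = max(candidates, key=lambda k: (jump(k), ccc[k]))
    table = pd.DataFrame(
        {
            "k": ks,
            "ccc": [ccc[k] for k in ks],
            "pseudo_t2_to_k": [pt2.get(k, math.nan) for k in ks],
            "pseudo_t2_jump": [jump(k) for k in ks],
            "ccc_local_peak": [k in peaks for k in ks],
        }
    ).set_index("k")
    return KSelection(
        k_range=ks,
        ccc_values=ccc,
        pseudo_t2_values={k: pt2.get(k, math.nan) for k in ks},
        chosen_k=chosen,
        diagnostics=table,
    )
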