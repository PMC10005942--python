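"""Hierarchical clustering of participant variate scores.

Operates on the 2-D cloud of first-mode canonical scores (cognitive score,
marker score).  Provides linkage comparison via the agglomerative
coefficient, silhouette-based selection of the cluster count, a parametric
Gaussian simulation test for the presence of cluster structure, and
bootstrap Jaccard cluster stability in the style of cluster-wise stability
assessment (clusterboot).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import silhouette_score

__all__ = [
    "LINKAGES",
    "ClusterSolution",
    "linkage_tree",
    "cut_tree_labels",
    "agglomerative_coefficient",
    "select_k",
    "silhouette_significance",
    "bootstrap_jaccard",
    "order_labels_by_score",
    "cluster_scores",
]

LINKAGES = ("average", "single", "complete", "ward")


def linkage_tree(points: np.ndarray, method: str) -> np.ndarray:
    """Agglomerate on Euclidean distances with the named update rule.

    Returns the standard (n−1)×4 merge table; heights are on the distance
    scale for all four methods (Ward heights are the square root of the
    within-cluster sum-of-squares increase, times √2 — the usual
    distance-scale convention).
    """
    points = np.asarray(points, dtype=float)
    if method not in LINKAGES:
        raise ValueError(f"unknown linkage {method!r}; expected one of {LINKAGES}")
    if points.ndim != 2 or points.shape[0] < 2:
        raise ValueError("need at least 2 points with 2-D coordinates")
    if np.isnan(points).any():
        raise ValueError("points contain missing coordinates")
    return linkage(points, method=method, metric="euclidean")


def cut_tree_labels(Z: np.ndarray, k: int) -> np.ndarray:
    """Labels (1..k) from cutting the merge tree into k clusters."""
    return fcluster(Z, t=k, criterion="maxclust")


def agglomerative_coefficient(Z: np.ndarray) -> float:
    """Agglomerative coefficient: mean over observations of 1 − m(i)/h_final.

    ``m(i)`` is the height at which observation i is first merged and
    ``h_final`` the final merge height; values near 1 indicate strong
    clustering structure.  Defined as 0 when all points coincide.
    """
    n = Z.shape[0] + 1
    h_final = Z[-1, 2]
    if h_final == 0:
        return 0.0
    first_merge = np.full(n, np.nan)
    for a, b, h, _ in Z:
        for idx in (int(a), int(b)):
            if idx < n and np.isnan(first_merge[idx]):
                first_merge[idx] = h
    return float(np.mean(1.0 - first_merge / h_final))


def select_k(
    Z: np.ndarray,
    points: np.ndarray,
    k_candidates=range(2, 11),
) -> tuple[int, dict[int, float], dict[int, float]]:
    """Silhouette-maximal cluster count over candidate k.

    Returns ``(k, silhouette_by_k, wss_by_k)``; the within-cluster
    sum-of-squares table supports an elbow plot but plays no role in the
    selection.
    """
    points = np.asarray(points, dtype=float)
    k_candidates = [k for k in k_candidates if 2 <= k < points.shape[0]]
    if not k_candidates:
        raise ValueError("no valid candidate k (need 2 <= k < n)")
    D = squareform(pdist(points))
    sil_by_k: dict[int, float] = {}
    wss_by_k: dict[int, float] = {}
    for k in k_candidates:
        labels = cut_tree_labels(Z, k)
        if len(np.unique(labels)) < 2:
            continue
        sil_by_k[k] = float(silhouette_score(D, labels, metric="precomputed"))
        wss_by_k[k] = _within_ss(points, labels)
    best = max(sil_by_k, key=sil_by_k.get)
    return best, sil_by_k, wss_by_k


def _within_ss(points: np.ndarray, labels: np.ndarray) -> float:
    tot = 0.0
    for lab in np.unique(labels):
        sub = points[labels == lab]
        tot += float(((sub - sub.mean(axis=0)) ** 2).sum())
    return tot


def best_silhouette(points: np.ndarray, method: str = "ward", k_candidates=range(2, 11)) -> float:
    """Highest average silhouette over the candidate cluster counts."""
    Z = linkage_tree(points, method)
    _, sil_by_k, _ = select_k(Z, points, k_candidates)
    return max(sil_by_k.values())


def silhouette_significance(
    points: np.ndarray,
    n_sim: int = 1000,
    seed: int = 0,
    method: str = "ward",
    k_candidates=range(2, 11),
) -> tuple[float, np.ndarray]:
    """Parametric test of cluster presence against a single Gaussian.

    The null model is a multivariate normal with the sample mean and
    covariance of the score cloud.  For each simulated sample of the same
    size the full linkage + silhouette-selection procedure is applied and
    the best average silhouette recorded; the add-one p-value counts null
    best-silhouettes at least as large as the observed one.
    """
    points = np.asarray(points, dtype=float)
    mean = points.mean(axis=0)
    cov = np.cov(points, rowvar=False)
    if np.linalg.matrix_rank(cov) < points.shape[1]:
        raise ValueError("degenerate score covariance; cannot simulate null")
    observed = best_silhouette(points, method, k_candidates)
    rng = np.random.default_rng(seed)
    null = np.empty(n_sim)
    for i in range(n_sim):
        sim = rng.multivariate_normal(mean, cov, size=points.shape[0], method="cholesky")
        null[i] = best_silhouette(sim, method, k_candidates)
    p = (1.0 + np.sum(null >= observed)) / (n_sim + 1.0)
    return float(p), null


def bootstrap_jaccard(
    points: np.ndarray,
    k: int,
    n_boot: int = 1000,
    seed: int = 0,
    method: str = "ward",
    reference_labels: np.ndarray | None = None,
) -> np.ndarray:
    """Cluster-wise bootstrap stability (mean Jaccard per reference cluster).

    Each bootstrap resamples n rows with replacement, re-clusters the
    resample at the same k, and scores every reference cluster by its best
    Jaccard overlap with a bootstrap cluster.  Sets are compared on the
    universe of resampled original indices, duplicates counted once, so a
    perfectly re-found cluster scores 1.  Mean Jaccard > 0.7 is the
    customary stability yardstick.
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if reference_labels is None:
        reference_labels = cut_tree_labels(linkage_tree(points, method), k)
    ref_sets = [set(np.where(reference_labels == lab)[0]) for lab in np.unique(reference_labels)]
    rng = np.random.default_rng(seed)
    sums = np.zeros(len(ref_sets))
    done = 0
    redraws = 0
    while done < n_boot:
        idx = rng.integers(0, n, size=n)
        if len(np.unique(idx)) < k:  # cannot form k clusters; redraw
            redraws += 1
            if redraws > 100 * n_boot:
                raise RuntimeError("bootstrap resamples repeatedly degenerate")
            continue
        boot_labels = cut_tree_labels(linkage_tree(points[idx], method), k)
        drawn = set(idx.tolist())
        boot_sets = [
            set(idx[boot_labels == lab].tolist()) for lab in np.unique(boot_labels)
        ]
        for ci, A in enumerate(ref_sets):
            A_drawn = A & drawn
            if not A_drawn:
                continue  # cluster absent from the resample: no evidence
            best = max(
                len(A_drawn & B) / len(A_drawn | B) for B in boot_sets
            )
            sums[ci] += best
        done += 1
    return sums / n_boot


def order_labels_by_score(points: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Relabel clusters so cluster 1 is lowest on the variate diagonal.

    Clusters are numbered by ascending mean of (x_score + y_score), matching
    the convention that cluster 1 holds jointly negative loading scores.
    """
    points = np.asarray(points, dtype=float)
    diag = points.sum(axis=1)
    uniq = np.unique(labels)
    means = [diag[labels == lab].mean() for lab in uniq]
    new = np.empty_like(labels)
    for rank, lab in enumerate(uniq[np.argsort(means)], start=1):
        new[labels == lab] = rank
    return new


@dataclass
class ClusterSolution:
    """Complete clustering report for one score cloud."""

    points: np.ndarray
    linkage: str
    agglomerative_coefficients: dict[str, float]
    merge_tree: np.ndarray
    k: int
    labels: np.ndarray
    silhouette_by_k: dict[int, float]
    avg_silhouette: float
    significance_p: float | None = None
    jaccard: np.ndarray | None = None
    wss_by_k: dict[int, float] = field(default_factory=dict)


def cluster_scores(
    points: np.ndarray,
    method: str = "auto",
    k_candidates=range(2, 11),
    n_sim: int = 1000,
    n_boot: int = 1000,
    seed: int = 0,
    run_significance: bool = True,
    run_stability: bool = True,
) -> ClusterSolution:
    """Full clustering stage: linkage choice, k selection, significance, stability.

    ``method="auto"`` evaluates all four linkages and keeps the one with the
    highest agglomerative coefficient.
    """
    points = np.asarray(points, dtype=float)
    acs = {m: agglomerative_coefficient(linkage_tree(points, m)) for m in LINKAGES}
    chosen = max(acs, key=acs.get) if method == "auto" else method
    Z = linkage_tree(points, chosen)
    k, sil_by_k, wss_by_k = select_k(Z, points, k_candidates)
    labels = order_labels_by_score(points, cut_tree_labels(Z, k))
    sol = ClusterSolution(
        points=points, linkage=chosen, agglomerative_coefficients=acs,
        merge_tree=Z, k=k, labels=labels, silhouette_by_k=sil_by_k,
        avg_silhouette=sil_by_k[k], wss_by_k=wss_by_k,
    )
    if run_significance:
        sol.significance_p, _ = silhouette_significance(
            points, n_sim=n_sim, seed=seed + 1, method=chosen, k_candidates=k_candidates
        )
    if run_stability:
        sol.jaccard = bootstrap_jaccard(
            points, k, n_boot=n_boot, seed=seed + 2, method=chosen,
            reference_labels=labels,
        )
    return sol
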