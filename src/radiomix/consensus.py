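"""Consensus clustering of the tumor feature table.

Tumors are repeatedly subsampled and clustered; the consensus matrix M(i, j)
records the fraction of co-sampled runs in which items i and j landed in the
same cluster. The empirical CDF of consensus entries summarizes partition
stability for each candidate cluster count k, and the largest relative change
in the area under that CDF selects k. Clustering algorithms: Ward
hierarchical clustering (HC_ward), k-means on the data matrix (KM), k-means
on the columns of the item-item distance matrix (KMdist), and partitioning
around medoids (PAM); dissimilarities: Euclidean, 1 - Pearson, 1 - Spearman.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

__all__ = [
    "ALGORITHMS",
    "DISSIMILARITIES",
    "ConsensusRun",
    "dissimilarity_matrix",
    "cluster_once",
    "run_consensus",
    "select_num_clusters",
    "median_cluster_consensus",
    "select_best_algorithm",
]

ALGORITHMS = ("HC_ward", "KM", "KMdist", "PAM")
DISSIMILARITIES = ("euclidean", "one_minus_pearson", "one_minus_spearman")


def _row_correlation(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=1)
    safe = x.copy()
    safe[sd == 0] = 0.0  # constant rows get correlation 0 with everything
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(safe) if safe.shape[0] > 1 else np.ones((1, 1))
    c = np.nan_to_num(c, nan=0.0)
    np.fill_diagonal(c, 1.0)
    return c


def dissimilarity_matrix(x: np.ndarray, kind: str) -> np.ndarray:
    """Item-by-item dissimilarity of the rows of ``x``."""
    if kind == "euclidean":
        return squareform(pdist(x))
    if kind == "one_minus_pearson":
        return 1.0 - _row_correlation(x)
    if kind == "one_minus_spearman":
        ranks = np.apply_along_axis(rankdata, 1, x)
        return 1.0 - _row_correlation(ranks)
    raise ValueError(f"unknown dissimilarity {kind!r}")


def _pam(d: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 50) -> np.ndarray:
    """Seeded k-medoids on a dissimilarity matrix (greedy build + alternation)."""
    n = d.shape[0]
    medoids = [int(np.argmin(d.sum(axis=0)))]
    while len(medoids) < k:
        cur = d[:, medoids].min(axis=1)
        gains = np.maximum(cur[None, :] - d, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        best = int(np.argmax(gains))
        if not np.isfinite(gains[best]) or gains[best] <= 0:
            # no cost-reducing candidate: pick a random non-medoid for diversity
            choices = np.setdiff1d(np.arange(n), medoids)
            best = int(rng.choice(choices))
        medoids.append(best)
    medoids = np.asarray(medoids)
    for _ in range(max_iter):
        labels = np.argmin(d[:, medoids], axis=1)
        new = medoids.copy()
        for c in range(k):
            members = np.flatnonzero(labels == c)
            if members.size:
                new[c] = members[np.argmin(d[np.ix_(members, members)].sum(axis=1))]
        if np.array_equal(new, medoids):
            break
        medoids = new
    return np.argmin(d[:, medoids], axis=1)


def cluster_once(
    x: np.ndarray,
    d: np.ndarray,
    algorithm: str,
    k: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Partition items into k groups; returns integer labels (0-based)."""
    if k >= x.shape[0]:
        return np.arange(x.shape[0])
    if algorithm == "HC_ward":
        z = linkage(squareform(d, checks=False), method="ward")
        return fcluster(z, k, criterion="maxclust") - 1
    if algorithm == "KM":
        seed = int(rng.integers(2**31 - 1))
        return KMeans(n_clusters=k, n_init=2, random_state=seed).fit_predict(x)
    if algorithm == "KMdist":
        seed = int(rng.integers(2**31 - 1))
        return KMeans(n_clusters=k, n_init=2, random_state=seed).fit_predict(d)
    if algorithm == "PAM":
        return _pam(d, k, rng)
    raise ValueError(f"unknown algorithm {algorithm!r}")


@dataclass
class ConsensusRun:
    """Consensus matrices and model-selection summaries for one setting."""

    algorithm: str
    dissimilarity: str
    k_range: tuple[int, ...]
    n_iter: int
    subsample_frac: float
    seed: int
    item_ids: list[str]
    consensus: dict[int, np.ndarray]  # per-k item x item consensus matrix
    cdf_area: dict[int, float] = field(default_factory=dict)
    delta_area: dict[int, float] = field(default_factory=dict)
    labels: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def selected_k(self) -> int:
        return select_num_clusters(self)


def _cdf_area(m: np.ndarray) -> float:
    """Area under the empirical CDF of the off-diagonal consensus entries."""
    vals = np.sort(m[np.triu_indices_from(m, k=1)])
    n = vals.size
    if n == 0:
        return 0.0
    cdf = np.arange(1, n + 1) / n
    # step integral over [0, 1]; CDF is 1 from the largest value to 1
    area = float(np.sum(np.diff(vals) * cdf[:-1])) + float((1.0 - vals[-1]) * 1.0)
    return area


def _final_labels(m: np.ndarray, k: int) -> np.ndarray:
    z = linkage(squareform(1.0 - m, checks=False), method="average")
    return fcluster(z, k, criterion="maxclust") - 1


def run_consensus(
    features: pd.DataFrame,
    algorithm: str,
    dissimilarity: str,
    k_range=(2, 3, 4, 5, 6),
    n_iter: int = 10_000,
    subsample_frac: float = 0.8,
    seed: int = 0,
) -> ConsensusRun:
    """Consensus clustering with item subsampling.

    Each iteration draws ``subsample_frac`` of the items without replacement
    and clusters them at every k in ``k_range``; co-clustering counts are
    normalized by co-sampling counts. Item pairs never co-sampled are imputed
    0 with a warning. Deterministic for a fixed seed.
    """
    if not 0 < subsample_frac <= 1:
        raise ValueError("subsample_frac must lie in (0, 1]")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    x = features.to_numpy(dtype=np.float64)
    n = x.shape[0]
    k_range = tuple(int(k) for k in k_range)
    d_full = dissimilarity_matrix(x, dissimilarity)
    rng = np.random.default_rng(seed)
    n_sub = max(2, int(round(subsample_frac * n)))

    co_sampled = np.zeros((n, n))
    co_clustered = {k: np.zeros((n, n)) for k in k_range}
    for _ in range(n_iter):
        idx = np.sort(rng.choice(n, size=n_sub, replace=False))
        co_sampled[np.ix_(idx, idx)] += 1.0
        d_sub = d_full[np.ix_(idx, idx)]
        x_sub = x[idx]
        for k in k_range:
            labels = cluster_once(x_sub, d_sub, algorithm, k, rng)
            for c in np.unique(labels):
                members = idx[labels == c]
                co_clustered[k][np.ix_(members, members)] += 1.0

    never = co_sampled == 0
    np.fill_diagonal(never, False)
    if never.any():
        logger.warning(
            "%d item pairs were never co-sampled; consensus imputed 0", never.sum() // 2
        )
    run = ConsensusRun(
        algorithm=algorithm,
        dissimilarity=dissimilarity,
        k_range=k_range,
        n_iter=n_iter,
        subsample_frac=subsample_frac,
        seed=seed,
        item_ids=[str(i) for i in features.index],
        consensus={},
    )
    for k in k_range:
        with np.errstate(invalid="ignore"):
            m = np.where(co_sampled > 0, co_clustered[k] / np.maximum(co_sampled, 1), 0.0)
        np.fill_diagonal(m, 1.0)
        m = (m + m.T) / 2.0
        run.consensus[k] = m
        run.cdf_area[k] = _cdf_area(m)
        run.labels[k] = _final_labels(m, k)
    ks = sorted(k_range)
    for i, k in enumerate(ks):
        if i == 0:
            run.delta_area[k] = run.cdf_area[k]
        else:
            prev = run.cdf_area[ks[i - 1]]
            run.delta_area[k] = (run.cdf_area[k] - prev) / prev if prev > 0 else 0.0
    return run


def select_num_clusters(run: ConsensusRun) -> int:
    """k with the largest relative change in CDF area; ties go to smaller k."""
    if len(run.k_range) < 2:
        raise ValueError("k_range must span at least two values")
    best_k, best_delta = None, -np.inf
    for k in sorted(run.k_range):
        d = run.delta_area[k]
        if d > best_delta + 1e-15:
            best_k, best_delta = k, d
    return int(best_k)


def cluster_consensus_values(run: ConsensusRun, k: int) -> np.ndarray:
    """Mean within-cluster consensus per cluster (singletons count as 1)."""
    m = run.consensus[k]
    labels = run.labels[k]
    out = []
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        if members.size < 2:
            out.append(1.0)
            continue
        sub = m[np.ix_(members, members)]
        out.append(float(sub[np.triu_indices_from(sub, k=1)].mean()))
    return np.asarray(out)


def median_cluster_consensus(run: ConsensusRun, k: int | None = None) -> float:
    """Median over clusters of the mean within-cluster consensus."""
    k = run.selected_k if k is None else int(k)
    return float(np.median(cluster_consensus_values(run, k)))


def select_best_algorithm(runs, labels_per_run, clinical_variable):
    """Pick the run whose labels associate most strongly with a clinical variable.

    Association strength is Cramér's V between cluster labels and the
    categorical variable (pairwise-complete); ties break by run order.
    Returns ``(run, V)``.
    """
    from .association import cramers_v_test

    best, best_v = None, -np.inf
    for run, labels in zip(runs, labels_per_run):
        _, _, _, v = cramers_v_test(labels, clinical_variable)
        if v > best_v + 1e-15:
            best, best_v = run, v
    return best, float(best_v)
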