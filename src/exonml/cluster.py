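"""Cluster-tendency statistics and clustering algorithms.

Implements the unsupervised toolbox used downstream of the exon PCA:

* multi-restart k-means (best of ``n_starts`` random initializations);
* cluster-number selection by the wss elbow, average silhouette and the
  gap statistic, with a rounded three-method consensus;
* hierarchical clustering on principal components (Ward linkage with
  k-means consolidation);
* fuzzy c-means membership coefficients;
* the Hopkins spatial-randomness statistic;
* VAT, the visual assessment of cluster tendency (MST-ordered
  dissimilarity matrix).

Orientation of the Hopkins statistic: real-point nearest-neighbour
distances in the numerator, so H is about 0.5 for spatially uniform
data and tends to 0 for strongly clustered data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .features import FeatureMatrix
from .pca import PCAResult

__all__ = [
    "ClusterAssignment",
    "KSelectionResult",
    "HopkinsResult",
    "VatResult",
    "kmeans_multi",
    "select_k",
    "hcpc",
    "fuzzy_cmeans",
    "hopkins",
    "vat",
    "order_clusters_by_abundance",
]


@dataclass
class ClusterAssignment:
    labels: pd.Series                  # observation -> cluster index (1..k)
    centers: pd.DataFrame              # cluster x variable
    total_wss: float
    method: str
    membership: pd.DataFrame | None = None  # observation x cluster (fuzzy)
    converged: bool = True

    @property
    def k(self) -> int:
        return len(self.centers)

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


@dataclass
class KSelectionResult:
    table: pd.DataFrame                # per-k: wss, silhouette, gap, gap_se
    elbow_k: int
    silhouette_k: int
    gap_k: int

    @property
    def consensus_k(self) -> int:
        return int(round((self.elbow_k + self.silhouette_k + self.gap_k) / 3.0))


@dataclass
class HopkinsResult:
    H: float
    m: int
    repeats: int
    per_repeat: np.ndarray = field(repr=False)
    sum_real: float = 0.0     # summed NN distances of sampled real points
    sum_uniform: float = 0.0  # summed NN distances of uniform probes


@dataclass
class VatResult:
    ordering: np.ndarray
    ordered_dissimilarity: np.ndarray


def _as_array(X) -> np.ndarray:
    if isinstance(X, FeatureMatrix):
        return X.values
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(float)
    return np.asarray(X, float)


def _index_of(X, n: int):
    if isinstance(X, FeatureMatrix):
        return X.data.index
    if isinstance(X, pd.DataFrame):
        return X.index
    return pd.RangeIndex(n)


def _columns_of(X, p: int):
    if isinstance(X, FeatureMatrix):
        return X.data.columns
    if isinstance(X, pd.DataFrame):
        return X.columns
    return pd.RangeIndex(p)


def kmeans_multi(X, k: int, n_starts: int = 50, seed: int = 0) -> ClusterAssignment:
    """Lloyd's algorithm from ``n_starts`` random initializations; the
    solution with the lowest total within-cluster sum of squares wins."""
    M = _as_array(X)
    n = len(M)
    if not 2 <= k < n:
        raise ValueError(f"k must satisfy 2 <= k < n_obs, got k={k}, n={n}")
    km = KMeans(n_clusters=k, init="random", n_init=n_starts, random_state=seed, algorithm="lloyd")
    km.fit(M)
    idx = _index_of(X, n)
    return ClusterAssignment(
        labels=pd.Series(km.labels_ + 1, index=idx, name="cluster"),
        centers=pd.DataFrame(km.cluster_centers_, index=range(1, k + 1), columns=_columns_of(X, M.shape[1])),
        total_wss=float(km.inertia_),
        method=f"kmeans(n_starts={n_starts})",
    )


def order_clusters_by_abundance(assignment: ClusterAssignment, abundance: pd.Series) -> pd.Series:
    """Relabel clusters so index 1 is the least abundant cluster and the
    highest index is the most abundant (cluster indices themselves are
    arbitrary; cross-references resolve by abundance ordering)."""
    means = abundance.groupby(assignment.labels).mean()
    order = means.sort_values().index.tolist()
    remap = {old: new + 1 for new, old in enumerate(order)}
    return assignment.labels.map(remap)


def _total_ss(M: np.ndarray) -> float:
    return float(((M - M.mean(axis=0)) ** 2).sum())


def _wss_for_k(M: np.ndarray, k: int, n_starts: int, seed: int) -> tuple[float, np.ndarray]:
    if k == 1:
        return _total_ss(M), np.zeros(len(M), int)
    km = KMeans(n_clusters=k, init="random", n_init=n_starts, random_state=seed, algorithm="lloyd").fit(M)
    return float(km.inertia_), km.labels_


def _pooled_pairwise_w(M: np.ndarray, labels: np.ndarray) -> float:
    # gap-statistic W_k: within-cluster sum of pairwise distances / (2 n_c)
    D = squareform(pdist(M))
    w = 0.0
    for c in np.unique(labels):
        idx = np.where(labels == c)[0]
        w += D[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return w


def _elbow_from_curve(ks: np.ndarray, wss: np.ndarray) -> int:
    """Automated 'bend' locator: the k whose point on the (normalized)
    wss curve lies farthest from the chord joining the endpoints."""
    x = (ks - ks[0]) / (ks[-1] - ks[0])
    rng_w = wss[0] - wss[-1]
    y = (wss - wss[-1]) / (rng_w if rng_w > 0 else 1.0)
    v = np.array([x[-1] - x[0], y[-1] - y[0]])
    v = v / np.linalg.norm(v)
    d = np.abs((x - x[0]) * v[1] - (y - y[0]) * v[0])
    return int(ks[int(np.argmax(d))])


def select_k(
    X,
    kmax: int = 10,
    n_starts: int = 50,
    gap_B: int = 100,
    seed: int = 0,
) -> KSelectionResult:
    """Choose the number of clusters by three methods and their consensus.

    * elbow: maximum perpendicular distance of the wss curve (squared
      distances) to the chord from k=1 to k=kmax;
    * silhouette: k in 2..kmax maximizing the mean silhouette width;
    * gap: Tibshirani's statistic with B uniform reference sets drawn in
      the data's bounding box and the first-k 1-SE rule; W_k here is the
      within-cluster sum of pairwise Euclidean distances over 2 n_c (the
      convention of the reference R implementation).

    The consensus is the rounded mean of the three choices.
    """
    M = _as_array(X)
    n = len(M)
    if kmax < 2:
        raise ValueError("kmax must be >= 2")
    if kmax >= n:
        raise ValueError("kmax must be smaller than the number of observations")
    rng = np.random.default_rng(seed)
    ks = np.arange(1, kmax + 1)

    wss = np.empty(kmax)
    sil = np.full(kmax, np.nan)
    labels_by_k = {}
    for i, k in enumerate(ks):
        wss[i], lab = _wss_for_k(M, k, n_starts, seed)
        labels_by_k[k] = lab
        if k >= 2 and len(np.unique(lab)) > 1:
            sil[i] = silhouette_score(M, lab)

    elbow_k = _elbow_from_curve(ks, wss)
    silhouette_k = int(ks[int(np.nanargmax(sil))])

    logw = np.array([np.log(max(_pooled_pairwise_w(M, labels_by_k[k]), 1e-300)) for k in ks])
    lo, hi = M.min(axis=0), M.max(axis=0)
    ref_logw = np.empty((gap_B, kmax))
    for b in range(gap_B):
        R = rng.uniform(lo, hi, size=M.shape)
        for i, k in enumerate(ks):
            _, lab = _wss_for_k(R, k, n_starts, seed)
            ref_logw[b, i] = np.log(max(_pooled_pairwise_w(R, lab), 1e-300))
    gap = ref_logw.mean(axis=0) - logw
    gap_se = ref_logw.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / gap_B)
    gap_k = kmax
    for i in range(kmax - 1):
        if gap[i] >= gap[i + 1] - gap_se[i + 1]:
            gap_k = int(ks[i])
            break

    table = pd.DataFrame(
        {"k": ks, "wss": wss, "silhouette": sil, "gap": gap, "gap_se": gap_se}
    ).set_index("k")
    return KSelectionResult(table=table, elbow_k=elbow_k, silhouette_k=silhouette_k, gap_k=gap_k)


def hcpc(pca: PCAResult, k: int | None = None, kmax: int = 10, seed: int = 0) -> ClusterAssignment:
    """Hierarchical clustering on principal components.

    Ward linkage on the factor scores; if ``k`` is not given, the tree
    is cut at the number of clusters with the largest relative jump in
    merge cost (the Ward merge heights measure between-cluster inertia
    gained by keeping clusters separate).  The partition is then
    consolidated by k-means seeded at the cluster barycenters, which can
    only lower the total within-cluster sum of squares.
    """
    S = pca.scores.to_numpy(float)
    n = len(S)
    if n < 3:
        raise ValueError("HCPC needs at least 3 observations")
    Zl = linkage(S, method="ward")
    heights = Zl[:, 2]
    if k is None:
        hi = min(kmax, n - 1)
        # merge that reduces k+1 -> k clusters has height heights[n-1-k]
        ratios = {}
        for kk in range(2, hi + 1):
            h_keep = heights[n - kk]       # cost of merging down to kk-1
            h_next = heights[n - kk - 1] if n - kk - 1 >= 0 else heights[0]
            ratios[kk] = h_keep / max(h_next, 1e-300)
        k = max(ratios, key=ratios.get)
    labels0 = fcluster(Zl, t=k, criterion="maxclust")
    centers0 = np.vstack([S[labels0 == c].mean(axis=0) for c in np.unique(labels0)])
    wss_before = float(sum(((S[labels0 == c] - S[labels0 == c].mean(axis=0)) ** 2).sum() for c in np.unique(labels0)))
    if len(centers0) < len(S):
        km = KMeans(n_clusters=len(centers0), init=centers0, n_init=1, algorithm="lloyd").fit(S)
        labels, centers, wss = km.labels_ + 1, km.cluster_centers_, float(km.inertia_)
        if wss > wss_before + 1e-9:  # k-means descent cannot worsen its own start
            labels, centers, wss = labels0, centers0, wss_before
    else:
        labels, centers, wss = labels0, centers0, 0.0
    return ClusterAssignment(
        labels=pd.Series(labels, index=pca.scores.index, name="cluster"),
        centers=pd.DataFrame(centers, index=range(1, len(centers) + 1), columns=pca.scores.columns),
        total_wss=wss,
        method="hcpc(ward+kmeans)",
    )


def fuzzy_cmeans(
    X,
    k: int,
    fuzzifier: float = 2.0,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> ClusterAssignment:
    """Fuzzy c-means: each observation receives a membership coefficient
    for every cluster (rows sum to 1); hard labels take the argmax."""
    M = _as_array(X)
    n = len(M)
    if not 2 <= k < n:
        raise ValueError(f"k must satisfy 2 <= k < n_obs, got k={k}, n={n}")
    if fuzzifier <= 1:
        raise ValueError("fuzzifier must exceed 1")
    rng = np.random.default_rng(seed)
    U = rng.dirichlet(np.ones(k), size=n)
    exponent = 2.0 / (fuzzifier - 1.0)
    converged = False
    for _ in range(max_iter):
        Um = U**fuzzifier
        centers = (Um.T @ M) / Um.sum(axis=0)[:, None]
        D = np.maximum(cdist(M, centers), 1e-12)
        U_new = 1.0 / ((D[:, :, None] / D[:, None, :]) ** exponent).sum(axis=2)
        if np.abs(U_new - U).max() < tol:
            U = U_new
            converged = True
            break
        U = U_new
    labels = U.argmax(axis=1) + 1
    idx = _index_of(X, n)
    Um = U**fuzzifier
    centers = (Um.T @ M) / Um.sum(axis=0)[:, None]
    hard_wss = float(sum(((M[labels == c + 1] - centers[c]) ** 2).sum() for c in range(k) if (labels == c + 1).any()))
    return ClusterAssignment(
        labels=pd.Series(labels, index=idx, name="cluster"),
        centers=pd.DataFrame(centers, index=range(1, k + 1), columns=_columns_of(X, M.shape[1])),
        total_wss=hard_wss,
        method=f"fcm(m={fuzzifier})",
        membership=pd.DataFrame(U, index=idx, columns=range(1, k + 1)),
        converged=converged,
    )


def hopkins(
    X,
    m: int | None = None,
    repeats: int = 100,
    seed: int = 0,
    ranges: tuple[np.ndarray, np.ndarray] | None = None,
) -> HopkinsResult:
    """Hopkins statistic for spatial randomness.

    Per repeat, ``m`` real observations are sampled without replacement
    and ``m`` uniform probe points are drawn inside the per-variable
    bounding box; the statistic compares summed nearest-neighbour
    distances of the real sample (to the other real points, excluding
    only the point itself, the numerator) against those of the probes
    (to all real points).  H is
    the mean over repeats: ~0.5 for uniform data, near 0 for clustered
    data.  Defaults: m = max(2, ceil(0.1 n)), 100 repeats.

    ``ranges`` optionally fixes the probe box to known (lo, hi) vectors;
    by default the observed per-variable min/max is used.  When the
    uniform null's true ranges are known (e.g. for generated reference
    data) passing them removes the bounding-box shrinkage bias that
    otherwise pushes H slightly above 0.5 in higher dimensions.
    """
    M = _as_array(X)
    n = len(M)
    if m is None:
        m = max(2, int(np.ceil(0.1 * n)))
    if m >= n:
        raise ValueError("Hopkins sample size m must be smaller than n")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = (M.min(axis=0), M.max(axis=0)) if ranges is None else (
        np.asarray(ranges[0], float), np.asarray(ranges[1], float))
    D = cdist(M, M)
    np.fill_diagonal(D, np.inf)
    hs = np.empty(repeats)
    tot_real = tot_unif = 0.0
    for r in range(repeats):
        idx = rng.choice(n, size=m, replace=False)
        sum_real = D[idx].min(axis=1).sum()
        probes = rng.uniform(lo, hi, size=(m, M.shape[1]))
        sum_unif = cdist(probes, M).min(axis=1).sum()
        denom = sum_real + sum_unif
        hs[r] = sum_real / denom if denom > 0 else 0.0
        tot_real += sum_real
        tot_unif += sum_unif
    return HopkinsResult(
        H=float(hs.mean()), m=m, repeats=repeats, per_repeat=hs,
        sum_real=tot_real, sum_uniform=tot_unif,
    )


def vat(X) -> VatResult:
    """Visual assessment of cluster tendency.

    Orders observations by a Prim-style minimum spanning tree traversal
    of the Euclidean dissimilarity matrix (seeded at the observation on
    the axis of maximal dissimilarity) and returns the consistently
    permuted matrix; clusters appear as dark diagonal blocks in a
    heatmap of the result.
    """
    M = _as_array(X)
    n = len(M)
    if n < 2:
        raise ValueError("VAT needs at least 2 observations")
    D = squareform(pdist(M))
    order = []
    i0 = int(np.unravel_index(np.argmax(D), D.shape)[0])
    order.append(i0)
    remaining = set(range(n)) - {i0}
    dist_to_set = D[i0].copy()
    while remaining:
        cand = min(remaining, key=lambda j: dist_to_set[j])
        order.append(cand)
        remaining.discard(cand)
        dist_to_set = np.minimum(dist_to_set, D[cand])
    order = np.array(order)
    return VatResult(ordering=order, ordered_dissimilarity=D[np.ix_(order, order)])
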