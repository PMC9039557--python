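"""Sample correlation/distance, hierarchical clustering, PCA and k-means.

Samples are columns of the normalized matrix; peaks (features) are rows.
The default sample dissimilarity is 1 - Pearson r, with the usual metric
alternatives (Euclidean, Manhattan, Canberra, binary, maximum, Minkowski)
available.  All outputs are purely numeric; sample annotations only ever
decorate plots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

_METRICS = {
    "euclidean": "euclidean",
    "manhattan": "cityblock",
    "canberra": "canberra",
    "maximum": "chebyshev",
    "minkowski": "minkowski",
}


@dataclass
class DistanceSpec:
    """Which sample dissimilarity to use; correlation distances are 1 - r."""

    base: str = "correlation_pearson"
    minkowski_p: float = 2.0

    def __post_init__(self) -> None:
        known = {"correlation_pearson", "correlation_spearman", "binary"} | set(_METRICS)
        if self.base not in known:
            raise ValueError(f"unknown distance {self.base!r}; options: {sorted(known)}")
        if self.minkowski_p <= 0:
            raise ValueError("minkowski_p must be > 0")


@dataclass
class ClusteringResult:
    sample_order: np.ndarray  # leaf permutation
    merge_tree: np.ndarray  # scipy linkage matrix (n-1, 4)
    feature_labels: np.ndarray | None = None


@dataclass
class PcaResult:
    scores: np.ndarray  # samples x components
    variance_explained: np.ndarray
    components: np.ndarray  # components x features


def correlation_matrix(matrix: np.ndarray, method: str = "pearson") -> np.ndarray:
    """Pairwise column (sample-sample) correlations with unit diagonal.

    Zero-variance columns yield 0 off-diagonal (with a warning) rather
    than NaN.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2 or m.shape[0] < 2:
        raise ValueError("need >=2 samples and >=2 peaks")
    if method == "spearman":
        m = np.apply_along_axis(stats.rankdata, 0, m)
    elif method != "pearson":
        raise ValueError("method must be 'pearson' or 'spearman'")
    sd = m.std(axis=0)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn("zero-variance sample(s); correlations set to 0", stacklevel=2)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(m, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    return corr


def distance_matrix(matrix: np.ndarray, spec: DistanceSpec | str = "correlation_pearson") -> np.ndarray:
    """Symmetric sample-sample distances under the chosen spec."""
    if isinstance(spec, str):
        spec = DistanceSpec(base=spec)
    m = np.asarray(matrix, dtype=float)
    cols = m.T  # samples as rows for pdist
    if spec.base.startswith("correlation_"):
        corr = correlation_matrix(m, method=spec.base.split("_", 1)[1])
        dist = 1.0 - corr
    elif spec.base == "binary":
        nz = cols != 0
        # R-style binary distance: Jaccard on the nonzero pattern
        dist = squareform(pdist(nz, metric="jaccard"))
    elif spec.base == "minkowski":
        dist = squareform(pdist(cols, metric="minkowski", p=spec.minkowski_p))
    else:
        dist = squareform(pdist(cols, metric=_METRICS[spec.base]))
    np.fill_diagonal(dist, 0.0)
    return dist


def hierarchical_cluster(dist: np.ndarray, linkage: str = "average") -> ClusteringResult:
    """Agglomerative clustering of a precomputed distance matrix."""
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    z = hierarchy.linkage(squareform(d, checks=False), method=linkage)
    order = hierarchy.leaves_list(z)
    return ClusteringResult(sample_order=np.asarray(order), merge_tree=z)


def pca(matrix: np.ndarray, n_components: int | None = None, scale: bool = False) -> PcaResult:
    """PCA of samples over peak features (centered, unscaled by default)."""
    m = np.asarray(matrix, dtype=float).T  # samples x features
    if m.shape[0] < 2:
        raise ValueError("PCA needs >=2 samples")
    centered = m - m.mean(axis=0, keepdims=True)
    sd = centered.std(axis=0)
    if (sd > 0).sum() < 2:
        raise ValueError("PCA needs >=2 non-constant features")
    if scale:
        centered = centered / np.where(sd == 0, 1.0, sd)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    k = min(m.shape[0] - 1, m.shape[1]) if n_components is None else n_components
    var = s**2 / (m.shape[0] - 1)
    total = centered.var(axis=0, ddof=1).sum()
    return PcaResult(
        scores=(u * s)[:, :k],
        variance_explained=var[:k] / total,
        components=vt[:k],
    )


def kmeans_features(
    matrix: np.ndarray, k: int, seed: int, restarts: int = 10
) -> np.ndarray:
    """Cluster peaks (rows) with k-means, best of ``restarts`` inits.

    Labels are 1..k, renumbered by descending cluster size; deterministic
    for a given seed.
    """
    from sklearn.cluster import KMeans

    m = np.asarray(matrix, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > m.shape[0]:
        raise ValueError("k exceeds the number of peaks")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    raw = km.fit_predict(m)
    sizes = np.bincount(raw, minlength=k)
    # stable renumber: big clusters first, ties by first occurrence
    order = np.lexsort((np.arange(k), -sizes))
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(1, k + 1)
    return remap[raw]
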