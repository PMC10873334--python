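"""Cell grouping: t-SNE embedding, density-peak centre detection, k-means.

Cells are first embedded into a low-dimensional space (3-D by default) with
t-SNE, the number of clusters and their centroids are estimated by adaptive
density-peak detection (kernel-density estimate plus delta-distance, centre
count chosen by average silhouette), and the final labels come from k-means
seeded at the detected peaks.  The resulting clusters are the grouping over
which the dropout mixture model is fitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score

from .matrix import ExpressionMatrix

_PCA_DIMS = 50  # pre-reduction before t-SNE, as Rtsne does internally


@dataclass
class CellEmbedding:
    """Low-dimensional cell coordinates (one row per cell)."""

    coords: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if not np.isfinite(self.coords).all():
            raise ValueError("embedding coordinates must be finite")


@dataclass
class CellClustering:
    """Per-cell integer labels in [0, k) with k centroids."""

    labels: np.ndarray
    k: int
    centroids: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.centroids = np.asarray(self.centroids, dtype=np.float64)
        if self.k < 1:
            raise ValueError("k must be >= 1")
        counts = np.bincount(self.labels, minlength=self.k)
        if (counts == 0).any():
            raise ValueError("every cluster must be non-empty")

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)


def embed_tsne(
    m: ExpressionMatrix, dims: int = 3, seed: int = 1, perplexity: float | None = None
) -> CellEmbedding:
    """Embed cells (columns of ``m``) with t-SNE.

    Expression is reduced to 50 principal components first; perplexity
    defaults to ``min(30, (n_cells - 1) / 3)``.  Deterministic for a fixed
    seed within one library build.
    """
    x = m.values.T  # cells x genes
    n = x.shape[0]
    if n < 2 * dims:
        raise ValueError(f"need at least {2 * dims} cells for a {dims}-D embedding")
    if perplexity is None:
        perplexity = min(30.0, (n - 1) / 3.0)
    if perplexity < 1 or n <= 3 * perplexity:
        perplexity = max(1.0, (n - 1) / 3.0)
    if x.shape[1] > _PCA_DIMS and n > _PCA_DIMS:
        x = PCA(n_components=_PCA_DIMS, random_state=seed).fit_transform(x)
    method = "barnes_hut" if dims < 4 else "exact"
    tsne = TSNE(
        n_components=dims,
        random_state=seed,
        perplexity=perplexity,
        init="pca",
        method=method,
    )
    coords = tsne.fit_transform(x)
    return CellEmbedding(np.asarray(coords, dtype=np.float64), seed)


def _silverman_bandwidth(x: np.ndarray) -> np.ndarray:
    """Per-dimension Silverman rule-of-thumb bandwidths."""
    n, d = x.shape
    sd = x.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return sd * (4.0 / (d + 2)) ** (1.0 / (d + 4)) * n ** (-1.0 / (d + 4))


def _kde_density(x: np.ndarray) -> np.ndarray:
    """Product-Gaussian kernel density estimate at every point."""
    h = _silverman_bandwidth(x)
    z = x / h
    sq = cdist(z, z, "sqeuclidean")
    # unnormalised density is sufficient: only the ordering matters
    return np.exp(-0.5 * sq).sum(axis=1)


def density_peaks(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rank points as cluster-centre candidates by density x delta.

    Returns (order, delta) where ``order`` lists point indices by decreasing
    centre score gamma = density * delta, delta being each point's distance
    to the nearest point of strictly higher density (the densest point gets
    the maximum pairwise distance).
    """
    dens = _kde_density(coords)
    dist = cdist(coords, coords)
    n = len(dens)
    delta = np.empty(n)
    for i in range(n):
        higher = dens > dens[i]
        if higher.any():
            delta[i] = dist[i, higher].min()
        else:
            delta[i] = dist[i].max()
    gamma = dens * delta
    return np.argsort(-gamma, kind="stable"), delta


def estimate_cluster_number(
    e: CellEmbedding, k_max: int | None = None, seed: int = 0
) -> tuple[int, np.ndarray]:
    """Choose the cluster count by silhouette over density-peak candidates.

    Candidate centres are the points with the largest density x delta score;
    for each k in 2..k_max a k-means pass seeded at the top-k peaks is
    scored by average silhouette width, and the best k wins.  A degenerate
    embedding (all points identical) yields k = 1 with a warning.
    """
    coords = e.coords
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least 2 cells")
    if np.allclose(coords, coords[0]):
        warnings.warn("degenerate embedding: all points identical; k = 1")
        return 1, coords[:1].copy()
    if k_max is None:
        k_max = min(15, n - 1)
    k_max = max(2, min(k_max, n - 1))
    order, _ = density_peaks(coords)
    # silhouette on a subsample keeps this O(n_sub^2) regardless of n
    if n > 2000:
        rng = np.random.default_rng(seed)
        sub = rng.choice(n, 2000, replace=False)
    else:
        sub = np.arange(n)
    best_k, best_score, best_centers = 2, -np.inf, coords[order[:2]]
    for k in range(2, k_max + 1):
        centers = coords[order[:k]]
        km = KMeans(n_clusters=k, init=centers, n_init=1, max_iter=300).fit(coords)
        labels = km.labels_
        if len(np.unique(labels[sub])) < 2:
            continue
        score = silhouette_score(coords[sub], labels[sub])
        if score > best_score:
            best_k, best_score, best_centers = k, score, coords[order[:k]]
    return best_k, best_centers


def kmeans_assign(e: CellEmbedding, k: int, centers: np.ndarray) -> CellClustering:
    """Lloyd k-means from the given centres; every cluster kept non-empty."""
    coords = e.coords
    if k > coords.shape[0]:
        raise ValueError("k exceeds the number of cells")
    km = KMeans(n_clusters=k, init=np.asarray(centers), n_init=1, max_iter=300,
                tol=1e-6).fit(coords)
    labels = km.labels_.copy()
    centroids = km.cluster_centers_.copy()
    # sklearn re-seeds empty clusters itself, but guard anyway
    for c in range(k):
        if not (labels == c).any():
            far = np.argmax(((coords - centroids[labels]) ** 2).sum(axis=1))
            labels[far] = c
            centroids[c] = coords[far]
    return CellClustering(labels, k, centroids)


def cluster_cells(
    m: ExpressionMatrix, dims: int = 3, seed: int = 1, k_max: int | None = None
) -> tuple[CellEmbedding, CellClustering]:
    """Full grouping pipeline: embed, estimate k and centres, assign."""
    emb = embed_tsne(m, dims=dims, seed=seed)
    k, centers = estimate_cluster_number(emb, k_max=k_max, seed=seed)
    if k == 1:
        return emb, CellClustering(
            np.zeros(emb.coords.shape[0], dtype=np.int64), 1,
            emb.coords.mean(axis=0, keepdims=True),
        )
    return emb, kmeans_assign(emb, k, centers)
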