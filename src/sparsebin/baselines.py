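"""Comparison clusterings of abundance-matrix columns.

Two reference methods: an LSA-style truncated SVD followed by greedy
leader clustering of the eigen-k-mer rows at a cosine threshold, and a
direct k-means over the bucket columns. The original LSA tool's stochastic
block-sampling/merging heuristic is replaced by a deterministic greedy
leader scan in ascending bucket order — the published description of that
heuristic is not reproducible, and the leader scan keeps the same cosine
decision rule while being exactly re-runnable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import svds
from sklearn.cluster import KMeans

from .abundance import AbundanceMatrix
from .factorize import BucketAssignment

__all__ = ["SvdModel", "truncated_svd", "lsa_baseline", "kmeans_baseline"]


@dataclass
class SvdModel:
    """Truncated SVD of the (row-normalized) abundance matrix restricted to
    occupied bucket columns: X_occ ~= U diag(s) Vt, singular values sorted
    non-increasing."""

    rank: int
    U: np.ndarray
    s: np.ndarray
    Vt: np.ndarray
    bucket_ids: np.ndarray

    def eigen_kmer_rows(self) -> np.ndarray:
        """sigma-weighted right-singular rows (one per occupied bucket)."""
        return (self.s[:, None] * self.Vt).T


def _occupied_columns(matrix: AbundanceMatrix) -> tuple[sp.csc_matrix, np.ndarray]:
    if not matrix.normalized:
        raise ValueError("matrix must be row-normalized first")
    occupied = matrix.occupied_buckets()
    return matrix.matrix.tocsc()[:, occupied], occupied


def truncated_svd(matrix: AbundanceMatrix, rank: int, seed: int = 0) -> SvdModel:
    """Seeded rank-d SVD of the occupied columns (ARPACK, deterministic v0)."""
    Xo, occupied = _occupied_columns(matrix)
    max_rank = min(Xo.shape) - 1
    if rank < 1 or rank > max_rank:
        raise ValueError(f"rank must be in [1, {max_rank}], got {rank}")
    rng = np.random.default_rng(seed)
    v0 = rng.standard_normal(min(Xo.shape))
    U, s, Vt = svds(Xo, k=rank, v0=v0)
    order = np.argsort(s)[::-1]
    return SvdModel(rank=rank, U=U[:, order], s=s[order], Vt=Vt[order], bucket_ids=occupied)


def _leader_clustering(rows: np.ndarray, cos_threshold: float) -> np.ndarray:
    """Greedy leader scan: join the first cluster whose centroid cosine
    reaches the threshold (centroid = mean of unit member vectors, updated
    incrementally), else found a new cluster."""
    n, d = rows.shape
    norms = np.linalg.norm(rows, axis=1)
    unit = np.zeros_like(rows)
    nz = norms > 0
    unit[nz] = rows[nz] / norms[nz, None]

    labels = np.empty(n, dtype=np.int64)
    cap = 256
    centroid_sum = np.zeros((cap, d))
    centroid_n = np.zeros(cap, dtype=np.int64)
    n_clusters = 0
    for i in range(n):
        v = unit[i]
        joined = -1
        if n_clusters and nz[i]:
            sums = centroid_sum[:n_clusters]
            cnorm = np.linalg.norm(sums, axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                cos = (sums @ v) / np.where(cnorm > 0, cnorm, 1.0)
            hits = np.flatnonzero(cos >= cos_threshold)
            if hits.size:
                joined = int(hits[0])
        if joined < 0:
            if n_clusters == cap:
                cap *= 2
                centroid_sum = np.vstack([centroid_sum, np.zeros((cap // 2, d))])
                centroid_n = np.concatenate([centroid_n, np.zeros(cap // 2, dtype=np.int64)])
            joined = n_clusters
            n_clusters += 1
        centroid_sum[joined] += v
        centroid_n[joined] += 1
        labels[i] = joined
    return labels


def lsa_baseline(
    matrix: AbundanceMatrix,
    rank: int,
    cos_threshold: float,
    seed: int = 0,
) -> BucketAssignment:
    """Truncated SVD + greedy cosine leader clustering of occupied buckets.

    Buckets are scanned in ascending bucket-index order; every occupied
    bucket is assigned.
    """
    if not 0 < cos_threshold <= 1:
        raise ValueError("cos_threshold must be in (0, 1]")
    model = truncated_svd(matrix, rank, seed=seed)
    labels = _leader_clustering(model.eigen_kmer_rows(), cos_threshold)
    used = np.unique(labels)
    return BucketAssignment(
        bucket_ids=model.bucket_ids,
        labels=labels,
        n_clusters=used.size,
        component_map={int(c): int(c) for c in used},
    )


def kmeans_baseline(
    matrix: AbundanceMatrix, n_clusters: int, seed: int = 0
) -> BucketAssignment:
    """Seeded k-means (k-means++ init) over occupied bucket columns."""
    Xo, occupied = _occupied_columns(matrix)
    if n_clusters > occupied.size:
        raise ValueError(
            f"n_clusters={n_clusters} exceeds occupied buckets ({occupied.size})"
        )
    if occupied.size == 0:
        raise ValueError("no occupied buckets to cluster")
    km = KMeans(n_clusters=n_clusters, init="k-means++", n_init=1, random_state=seed)
    raw = km.fit_predict(np.asarray(Xo.T.todense()))
    # k-means can leave clusters empty; relabel contiguously like factorize
    used = np.unique(raw)
    remap = np.full(int(used.max()) + 1, -1, dtype=np.int64)
    remap[used] = np.arange(used.size)
    return BucketAssignment(
        bucket_ids=occupied,
        labels=remap[raw],
        n_clusters=used.size,
        component_map={int(c): int(i) for i, c in enumerate(used)},
    )
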