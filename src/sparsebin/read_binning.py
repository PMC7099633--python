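"""Assign raw reads to k-mer clusters by a log-likelihood score.

A read r is decomposed into its distinct LSH buckets; with M(r, c) the
buckets of r assigned to cluster c, the score is

    score(r, c) = sum_{w in M(r, c)} [ log(N_total / c_w) + log(B_occ / |c|) ],

where c_w is the total abundance of bucket w (the first term is an
IDF-style rarity weight: rarer k-mers are stronger evidence), |c| is the
bucket count of cluster c and B_occ the number of occupied buckets (the
second term penalizes hitting a large cluster by chance). Clusters with no
matched bucket score -inf. The read goes to the argmax-finite cluster
provided the match count in that cluster reaches ``min_matches``; ties go
to the smaller cluster id. Mate pairs are scored jointly on the union of
both mates' distinct buckets and receive one shared cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

from .abundance import AbundanceMatrix
from .factorize import BucketAssignment
from .lsh import HyperplaneSet, hash_read, hash_read_batch

__all__ = [
    "ClusterStats",
    "BinAssignment",
    "build_cluster_stats",
    "score_bucket_set",
    "score_read",
    "assign_reads",
]

UNASSIGNED = -1
_CHUNK_READS = 8192


@dataclass
class ClusterStats:
    """Statistics feeding the read score, keyed by occupied buckets only
    (memory scales with observed k-mer diversity, never with 2^n_bits).

    ``occupied`` holds the sorted occupied bucket ids; ``bucket_cluster``
    and ``bucket_counts`` are aligned with it (-1 = unassigned; c_w > 0).
    ``cluster_sizes`` counts buckets per cluster; ``n_total`` is the grand
    k-mer occurrence count and B_occ = ``n_occupied``.
    """

    occupied: np.ndarray
    bucket_cluster: np.ndarray
    bucket_counts: np.ndarray
    cluster_sizes: np.ndarray
    n_total: int

    def __post_init__(self) -> None:
        if not (self.occupied.size == self.bucket_cluster.size == self.bucket_counts.size):
            raise ValueError("occupied/cluster/count arrays must align")

    @property
    def n_occupied(self) -> int:
        return self.occupied.size

    @property
    def n_clusters(self) -> int:
        return self.cluster_sizes.size

    def locate(self, buckets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Positions of bucket ids in ``occupied`` plus a found-mask."""
        buckets = np.asarray(buckets, dtype=np.int64)
        pos = np.searchsorted(self.occupied, buckets)
        pos_clipped = np.minimum(pos, max(self.occupied.size - 1, 0))
        found = (
            (self.occupied.size > 0)
            & (pos < self.occupied.size)
            & (self.occupied[pos_clipped] == buckets)
        )
        return pos_clipped, found

    def contributions(self) -> np.ndarray:
        """Per-occupied-bucket score contribution (0 where unassigned)."""
        contrib = np.zeros(self.occupied.size)
        w = np.flatnonzero(self.bucket_cluster >= 0)
        if w.size:
            c_w = self.bucket_counts[w].astype(float)
            sizes = self.cluster_sizes[self.bucket_cluster[w]].astype(float)
            contrib[w] = np.log(self.n_total / c_w) + np.log(self.n_occupied / sizes)
        return contrib


@dataclass
class BinAssignment:
    """read -> cluster map with score/match-count provenance."""

    entries: dict[str, tuple[int, float, int]] = field(default_factory=dict)

    def add(self, read_id: str, cluster: int, score: float, n_matches: int) -> None:
        self.entries[read_id] = (cluster, score, n_matches)

    def cluster_of(self, read_id: str) -> int:
        return self.entries[read_id][0]

    def to_mapping(self) -> dict[str, int]:
        return {rid: e[0] for rid, e in self.entries.items()}

    def __len__(self) -> int:
        return len(self.entries)

    def save_tsv(self, path: Path | str) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\tcluster\tscore\tn_matches\n")
            for rid, (cluster, score, n) in self.entries.items():
                fh.write(f"{rid}\t{cluster}\t{score:.6f}\t{n}\n")

    @classmethod
    def load_tsv(cls, path: Path | str) -> "BinAssignment":
        out = cls()
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("read_id"):
                raise ValueError("missing assignment header")
            for line in fh:
                rid, cluster, score, n = line.rstrip("\n").split("\t")
                out.add(rid, int(cluster), float(score), int(n))
        return out


def build_cluster_stats(
    matrix: AbundanceMatrix, assignment: BucketAssignment
) -> ClusterStats:
    """Derive scoring statistics from raw counts and a bucket clustering."""
    coo = matrix.counts.tocoo()
    if coo.nnz == 0:
        raise ValueError("empty abundance matrix: no statistics to build")
    occupied, inverse = np.unique(coo.col, return_inverse=True)
    counts = np.bincount(inverse, weights=coo.data.astype(float)).astype(np.int64)
    n_total = int(counts.sum())

    labels = np.full(occupied.size, UNASSIGNED, dtype=np.int64)
    order = np.argsort(assignment.bucket_ids, kind="stable")
    a_buckets = assignment.bucket_ids[order]
    a_labels = assignment.labels[order]
    pos = np.searchsorted(a_buckets, occupied)
    pos_c = np.minimum(pos, max(a_buckets.size - 1, 0))
    found = (pos < a_buckets.size) & (a_buckets[pos_c] == occupied)
    labels[found] = a_labels[pos_c[found]]

    sizes = np.bincount(labels[labels >= 0], minlength=assignment.n_clusters)
    return ClusterStats(
        occupied=occupied,
        bucket_cluster=labels,
        bucket_counts=counts,
        cluster_sizes=sizes,
        n_total=n_total,
    )


def score_bucket_set(buckets: Sequence[int] | np.ndarray, stats: ClusterStats) -> np.ndarray:
    """Per-cluster scores of a set of distinct buckets (-inf = no match).

    Reference scalar implementation of the read score;
    :func:`assign_reads` uses an equivalent vectorized path.
    """
    if stats.n_total == 0:
        raise ValueError("empty cluster statistics")
    scores = np.full(stats.n_clusters, -np.inf)
    uniq = np.unique(np.asarray(buckets, dtype=np.int64))
    pos, found = stats.locate(uniq)
    for p in pos[found]:
        c = stats.bucket_cluster[p]
        if c < 0:
            continue
        term = np.log(stats.n_total / stats.bucket_counts[p]) + np.log(
            stats.n_occupied / stats.cluster_sizes[c]
        )
        scores[c] = term if np.isinf(scores[c]) else scores[c] + term
    return scores


def score_read(
    read,
    hyperplanes: HyperplaneSet,
    stats: ClusterStats,
    use_quality: bool = False,
) -> np.ndarray:
    """Per-cluster scores of one read (-inf where no bucket matched)."""
    buckets = hash_read(read, hyperplanes, use_quality=use_quality)
    return score_bucket_set(buckets, stats)


def _resolve_batch(
    bucket_sets: list[np.ndarray],
    stats: ClusterStats,
    contrib: np.ndarray,
    min_matches: int,
) -> list[tuple[int, float, int]]:
    """Winner (cluster, score, matches) per bucket set; vectorized."""
    results: list[tuple[int, float, int]] = [(UNASSIGNED, float("-inf"), 0)] * len(
        bucket_sets
    )
    lengths = np.array([b.size for b in bucket_sets], dtype=np.int64)
    if lengths.sum() == 0:
        return results
    flat = np.concatenate(bucket_sets)
    rows = np.repeat(np.arange(len(bucket_sets), dtype=np.int64), lengths)
    pos, found = stats.locate(flat)
    labels = np.where(found, stats.bucket_cluster[pos], UNASSIGNED)
    keep = labels >= 0
    if not keep.any():
        return results
    rows, labels, data = rows[keep], labels[keep], contrib[pos[keep]]
    # aggregate duplicates of (row, cluster)
    key = rows * np.int64(stats.n_clusters) + labels
    uniq, inv = np.unique(key, return_inverse=True)
    scores = np.zeros(uniq.size)
    np.add.at(scores, inv, data)
    counts = np.bincount(inv, minlength=uniq.size)
    urows = uniq // stats.n_clusters
    uclusters = uniq % stats.n_clusters
    # per row: max score, ties to smaller cluster id (clusters ascend per row)
    order = np.lexsort((uclusters, -scores, urows))
    first = np.ones(order.size, dtype=bool)
    first[1:] = urows[order][1:] != urows[order][:-1]
    winners = order[first]
    for o in winners:
        r = int(urows[o])
        if counts[o] >= min_matches:
            results[r] = (int(uclusters[o]), float(scores[o]), int(counts[o]))
        else:
            results[r] = (UNASSIGNED, float(scores[o]), int(counts[o]))
    return results


def assign_reads(
    reads: Iterable,
    hyperplanes: HyperplaneSet,
    stats: ClusterStats,
    min_matches: int = 2,
    paired: bool = False,
    use_quality: bool = False,
) -> BinAssignment:
    """Assign a stream of reads (or mated pairs when ``paired``) to clusters.

    In paired mode consecutive mates are pooled: the pair is scored on the
    union of both mates' distinct buckets and both read ids receive the
    joint cluster.
    """
    contrib = stats.contributions()
    assignment = BinAssignment()

    def flush(chunk: list) -> None:
        if not chunk:
            return
        if paired:
            units = [(r1.read_id, r2.read_id) for r1, r2 in chunk]
            hashed = hash_read_batch(
                [r for pair in chunk for r in pair], hyperplanes, use_quality=use_quality
            )
            sets = [
                np.unique(np.concatenate([hashed[2 * i], hashed[2 * i + 1]]))
                for i in range(len(chunk))
            ]
        else:
            units = [(r.read_id,) for r in chunk]
            hashed = hash_read_batch(chunk, hyperplanes, use_quality=use_quality)
            sets = [np.unique(h) for h in hashed]
        for ids, (cluster, score, n) in zip(
            units, _resolve_batch(sets, stats, contrib, min_matches)
        ):
            for rid in ids:
                assignment.add(rid, cluster, score, n)

    chunk: list = []
    if paired:
        it = iter(reads)
        for r1 in it:
            r2 = next(it, None)
            if r2 is None:
                raise ValueError("paired mode requires an even read stream")
            chunk.append((r1, r2))
            if len(chunk) >= _CHUNK_READS // 2:
                flush(chunk)
                chunk = []
    else:
        for r in reads:
            chunk.append(r)
            if len(chunk) >= _CHUNK_READS:
                flush(chunk)
                chunk = []
    flush(chunk)
    return assignment
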