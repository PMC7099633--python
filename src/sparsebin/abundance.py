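"""Streaming construction of the sample x bucket abundance matrix.

Entry (s, b) counts the k-mer occurrences of sample s that hash to LSH
bucket b. The nominal column dimension is 2^n_bits but storage is sparse,
keyed by occupied buckets only, so memory scales with observed k-mer
diversity — the fixed-memory property that makes the scheme usable on
arbitrarily deep data. Rows (samples) are scaled to unit l2 norm before
factorization; raw counts are retained for read-scoring statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .lsh import HyperplaneSet, hash_read_batch
from .seqio import SampleSet

_CHUNK_READS = 4096


@dataclass
class AbundanceMatrix:
    """Sparse S x 2^n_bits k-mer bucket count matrix plus provenance.

    ``counts`` are raw occurrence counts; ``matrix`` is the row-normalized
    (unit l2) float matrix once :func:`normalize_rows` has run.
    """

    counts: sp.csr_matrix
    sample_ids: list[str]
    n_bits: int
    k: int
    seed: int
    use_quality: bool = False
    matrix: Optional[sp.csr_matrix] = None

    def __post_init__(self) -> None:
        if self.counts.shape[0] != len(self.sample_ids):
            raise ValueError("row count != number of sample ids")
        if self.counts.shape[1] != (1 << self.n_bits):
            raise ValueError("column count != 2^n_bits")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def normalized(self) -> bool:
        return self.matrix is not None

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_buckets(self) -> int:
        return self.counts.shape[1]

    def occupied_buckets(self) -> np.ndarray:
        """Sorted indices of buckets with at least one count."""
        return np.unique(self.counts.tocoo().col)


def accumulate_counts(
    samples: SampleSet,
    hyperplanes: HyperplaneSet,
    use_quality: bool = False,
) -> AbundanceMatrix:
    """Hash every k-mer of every sample and accumulate bucket counts."""
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    for s_idx, (sample_id, _) in enumerate(samples):
        try:
            sample_buckets: list[np.ndarray] = []
            chunk: list = []
            for read in samples.iter_sample_reads(sample_id):
                chunk.append(read)
                if len(chunk) >= _CHUNK_READS:
                    sample_buckets.extend(
                        hash_read_batch(chunk, hyperplanes, use_quality=use_quality)
                    )
                    chunk = []
            if chunk:
                sample_buckets.extend(
                    hash_read_batch(chunk, hyperplanes, use_quality=use_quality)
                )
        except OSError as exc:
            raise OSError(f"sample {sample_id!r}: {exc}") from exc
        if sample_buckets:
            flat = np.concatenate(sample_buckets)
        else:
            flat = np.empty(0, dtype=np.int64)
        uniq, counts = np.unique(flat, return_counts=True)
        rows.append(np.full(uniq.size, s_idx, dtype=np.int64))
        cols.append(uniq)
        vals.append(counts.astype(np.int64))
    shape = (len(samples), 1 << hyperplanes.n_bits)
    counts = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols)))
        if rows and sum(v.size for v in vals)
        else (np.empty(0), (np.empty(0, int), np.empty(0, int))),
        shape=shape,
    ).tocsr()
    return AbundanceMatrix(
        counts=counts,
        sample_ids=list(samples.sample_ids),
        n_bits=hyperplanes.n_bits,
        k=hyperplanes.k,
        seed=hyperplanes.seed,
        use_quality=use_quality,
    )


def normalize_rows(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Scale every nonzero row to unit l2 norm (zero rows stay zero)."""
    X = matrix.counts.astype(np.float64).tocsr()
    norms = np.sqrt(np.asarray(X.multiply(X).sum(axis=1)).ravel())
    inv = np.divide(1.0, norms, out=np.zeros_like(norms), where=norms > 0)
    # scale the CSR data in place: keeps memory independent of 2^n_bits
    X.data *= np.repeat(inv, np.diff(X.indptr))
    return replace(matrix, matrix=X)


def bucket_totals(matrix: AbundanceMatrix) -> tuple[np.ndarray, int]:
    """Per-bucket total counts c_w and the grand total N_total.

    Returned c_w is a dense vector of the full nominal length 2^n_bits,
    which is only sensible at modest hash sizes; the read-scoring pipeline
    uses the compact occupied-bucket statistics in
    :mod:`sparsebin.read_binning` instead.
    """
    c_w = np.asarray(matrix.counts.sum(axis=0)).ravel().astype(np.int64)
    return c_w, int(c_w.sum())


def save_matrix(matrix: AbundanceMatrix, path: Path | str) -> None:
    """Persist as MatrixMarket triplets plus a JSON sidecar (<path>.json)."""
    path = Path(path)
    mmwrite(str(path), matrix.counts.tocoo(), field="integer")
    sidecar = {
        "sample_ids": matrix.sample_ids,
        "k": matrix.k,
        "n_bits": matrix.n_bits,
        "seed": matrix.seed,
        "use_quality": matrix.use_quality,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def load_matrix(path: Path | str) -> AbundanceMatrix:
    path = Path(path)
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    counts = sp.csr_matrix(mmread(str(path)), dtype=np.int64)
    B = 1 << int(sidecar["n_bits"])
    if counts.shape[1] != B:  # mmread drops trailing empty columns
        counts.resize((len(sidecar["sample_ids"]), B))
    return AbundanceMatrix(
        counts=counts,
        sample_ids=list(sidecar["sample_ids"]),
        n_bits=int(sidecar["n_bits"]),
        k=int(sidecar["k"]),
        seed=int(sidecar["seed"]),
        use_quality=bool(sidecar["use_quality"]),
    )
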