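"""SimHash locality-sensitive hashing of k-mers.

Each base is mapped onto a complex simplex (A=1, C=i, G=-i, T=-1), so a
k-mer becomes a point in C^k, realized here as a real vector of dimension
2k (the k real parts followed by the k imaginary parts). ``n_bits`` random
hyperplanes with i.i.d. standard-normal coefficients split that space into
2^n_bits buckets; bit ``i`` of a bucket index is 1 iff the projection onto
hyperplane ``i`` is >= 0. Similar k-mers flip few signs and therefore
collide with elevated probability — the classic SimHash angle property.

Base-call confidence can optionally down-weight each position by
``w = 1 - 10**(-Q/10)`` (the probability that the call is correct).

Reverse complements are *not* canonicalized: the complex encoding is
strand-asymmetric and both strands are represented by the reads themselves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "BASE_CODES",
    "HyperplaneSet",
    "make_hyperplanes",
    "encode_kmer",
    "hash_kmer",
    "stream_kmers",
    "hash_read",
    "hash_read_batch",
]

#: The complex simplex base mapping.
BASE_CODES: dict[str, complex] = {"A": 1 + 0j, "C": 0 + 1j, "G": 0 - 1j, "T": -1 + 0j}

# 256-entry lookup tables for vectorized encoding of ASCII byte arrays
_RE_TABLE = np.zeros(256)
_IM_TABLE = np.zeros(256)
_VALID_TABLE = np.zeros(256, dtype=bool)
for _b, _c in BASE_CODES.items():
    _RE_TABLE[ord(_b)] = _c.real
    _IM_TABLE[ord(_b)] = _c.imag
    _VALID_TABLE[ord(_b)] = True


@dataclass(frozen=True)
class HyperplaneSet:
    """Seeded random hyperplanes defining the SimHash over k-mer space.

    ``normals`` has shape (n_bits, 2k): columns 0..k-1 act on real parts,
    columns k..2k-1 on imaginary parts. Regeneration from (n_bits, k, seed)
    is bit-identical, so only the three scalars need to be persisted.
    """

    n_bits: int
    k: int
    seed: int
    normals: np.ndarray

    def __post_init__(self) -> None:
        if self.normals.shape != (self.n_bits, 2 * self.k):
            raise ValueError(
                f"normals shape {self.normals.shape} != ({self.n_bits}, {2 * self.k})"
            )

    @property
    def n_buckets(self) -> int:
        return 1 << self.n_bits

    def to_sidecar(self) -> dict:
        return {"n_bits": self.n_bits, "k": self.k, "seed": self.seed}

    @classmethod
    def from_sidecar(cls, d: dict) -> "HyperplaneSet":
        return make_hyperplanes(int(d["n_bits"]), int(d["k"]), int(d["seed"]))


def make_hyperplanes(n_bits: int, k: int, seed: int) -> HyperplaneSet:
    """Draw ``n_bits`` standard-normal hyperplanes over the 2k-dim encoding."""
    if not 1 <= n_bits <= 62:  # bucket indices are int64
        raise ValueError(f"n_bits must be in [1, 62], got {n_bits}")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    rng = np.random.default_rng(seed)
    normals = rng.standard_normal((n_bits, 2 * k))
    return HyperplaneSet(n_bits=n_bits, k=k, seed=seed, normals=normals)


def _quality_weights(qualities: Sequence[int] | np.ndarray) -> np.ndarray:
    q = np.asarray(qualities, dtype=float)
    return 1.0 - np.power(10.0, -q / 10.0)


def encode_kmer(
    kmer: str,
    qualities: Optional[Sequence[int]] = None,
    use_quality: bool = False,
) -> np.ndarray:
    """Encode a k-mer as a 2k-dim real vector (real parts, then imaginary).

    Position ``j`` contributes ``(Re, Im)`` of ``code(base_j) * w_j`` with
    ``w_j = 1 - 10**(-Q_j/10)`` when ``use_quality`` is on, else 1.
    """
    b = np.frombuffer(kmer.encode("ascii"), dtype=np.uint8)
    if not _VALID_TABLE[b].all():
        bad = sorted(set(kmer) - set(BASE_CODES))
        raise ValueError(f"k-mer contains non-ACGT characters {bad}")
    re, im = _RE_TABLE[b], _IM_TABLE[b]
    if use_quality:
        if qualities is None:
            raise ValueError("use_quality requires qualities")
        if len(qualities) != len(kmer):
            raise ValueError("qualities length != k-mer length")
        w = _quality_weights(qualities)
        re, im = re * w, im * w
    return np.concatenate([re, im])


def hash_kmer(
    kmer: str,
    hyperplanes: HyperplaneSet,
    qualities: Optional[Sequence[int]] = None,
    use_quality: bool = False,
) -> int:
    """Bucket index of one k-mer: bit i = 1 iff <normal_i, encoding> >= 0."""
    if len(kmer) != hyperplanes.k:
        raise ValueError(f"k-mer length {len(kmer)} != k={hyperplanes.k}")
    v = encode_kmer(kmer, qualities, use_quality)
    proj = hyperplanes.normals @ v
    bits = proj >= 0  # ties (measure zero) resolve to 1
    weights = np.left_shift(np.int64(1), np.arange(hyperplanes.n_bits, dtype=np.int64))
    return int(bits @ weights)


def stream_kmers(
    read, k: int
) -> Iterator[tuple[str, Optional[np.ndarray]]]:
    """Yield all k-length windows of a read in order, skipping windows with N.

    Accepts a :class:`~sparsebin.seqio.SequenceRead` or a plain string.
    """
    seq = read if isinstance(read, str) else read.sequence
    quals = None if isinstance(read, str) else read.qualities
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        if "N" in window:
            continue
        yield window, (None if quals is None else quals[i : i + k])


def hash_read(
    read,
    hyperplanes: HyperplaneSet,
    use_quality: bool = False,
) -> np.ndarray:
    """Bucket indices of all valid (N-free) k-mer windows of one read."""
    return hash_read_batch([read], hyperplanes, use_quality=use_quality)[0]


def _read_fields(read) -> tuple[str, Optional[np.ndarray]]:
    if isinstance(read, str):
        return read, None
    return read.sequence, read.qualities


def hash_read_batch(
    reads: Sequence,
    hyperplanes: HyperplaneSet,
    use_quality: bool = False,
    chunk_size: int = 4096,
) -> list[np.ndarray]:
    """Vectorized :func:`hash_read` over many reads.

    Reads are grouped by length and processed as sliding-window GEMMs, which
    is what makes desk-scale hashing of ~10^6 reads practical. Results are
    identical to the per-k-mer scalar path.
    """
    k, n_bits = hyperplanes.k, hyperplanes.n_bits
    nre = np.ascontiguousarray(hyperplanes.normals[:, :k].T)  # (k, n_bits)
    nim = np.ascontiguousarray(hyperplanes.normals[:, k:].T)
    weights = np.left_shift(np.int64(1), np.arange(n_bits, dtype=np.int64))

    out: list[np.ndarray] = [None] * len(reads)  # type: ignore[list-item]
    by_len: dict[int, list[int]] = {}
    for i, r in enumerate(reads):
        seq, _ = _read_fields(r)
        by_len.setdefault(len(seq), []).append(i)

    empty = np.empty(0, dtype=np.int64)
    for L, idxs in by_len.items():
        n_win = L - k + 1
        if n_win <= 0:
            for i in idxs:
                out[i] = empty
            continue
        for start in range(0, len(idxs), chunk_size):
            chunk = idxs[start : start + chunk_size]
            raw = np.empty((len(chunk), L), dtype=np.uint8)
            for row, i in enumerate(chunk):
                seq, _ = _read_fields(reads[i])
                raw[row] = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            invalid = ~_VALID_TABLE[raw]
            has_n = raw == ord("N")
            if invalid.any() and (invalid & ~has_n).any():
                bad_row = int(np.nonzero((invalid & ~has_n).any(axis=1))[0][0])
                raise ValueError(
                    f"read {reads[chunk[bad_row]]!r}: non-ACGTN character"
                )
            re = _RE_TABLE[raw]
            im = _IM_TABLE[raw]
            if use_quality:
                w = np.empty((len(chunk), L))
                for row, i in enumerate(chunk):
                    _, quals = _read_fields(reads[i])
                    if quals is None:
                        raise ValueError("use_quality requires qualities on reads")
                    w[row] = _quality_weights(quals)
                re = re * w
                im = im * w
            win_re = np.lib.stride_tricks.sliding_window_view(re, k, axis=1)
            win_im = np.lib.stride_tricks.sliding_window_view(im, k, axis=1)
            proj = win_re.reshape(-1, k) @ nre + win_im.reshape(-1, k) @ nim
            buckets = ((proj >= 0) @ weights).reshape(len(chunk), n_win)
            # windows touching an N are dropped
            n_in_win = np.lib.stride_tricks.sliding_window_view(
                has_n, k, axis=1
            ).any(axis=2)
            for row, i in enumerate(chunk):
                out[i] = buckets[row][~n_in_win[row]]
    return out
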