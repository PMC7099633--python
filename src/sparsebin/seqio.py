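"""Streaming FASTQ/FASTA input and per-bin partition output.

Readers are thin, validating wrappers around Biopython's fast low-level
parsers (:func:`SimpleFastaParser`, :func:`FastqGeneralIterator`). Gzip is
handled transparently; qualities are Sanger Phred+33. Reads containing
characters outside ``{A, C, G, T, N}`` are rejected so the downstream
hashing alphabet stays closed.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional, Sequence

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

_VALID_BASES = frozenset("ACGTN")
# translation table uppercasing acgtn only; anything else is left for validation
_UPPER = str.maketrans("acgtn", "ACGTN")


class SequenceFormatError(ValueError):
    """Raised for malformed FASTA/FASTQ records."""


@dataclass
class SequenceRead:
    """A single sequencing read.

    ``qualities`` (when present) are integer Phred scores of the same length
    as ``sequence``; ``mate`` optionally links the other read of a pair.
    """

    read_id: str
    sequence: str
    qualities: Optional[np.ndarray] = None
    sample_id: str = ""
    mate: Optional["SequenceRead"] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise SequenceFormatError(f"read {self.read_id!r}: empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise SequenceFormatError(
                f"read {self.read_id!r}: quality length {len(self.qualities)} "
                f"!= sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SampleSet:
    """Ordered mapping sample_id -> one (single-end) or two (paired) files.

    The order of ``samples`` is fixed and defines the row order of the
    abundance matrix.
    """

    samples: list[tuple[str, tuple[Path, ...]]]

    def __post_init__(self) -> None:
        ids = [sid for sid, _ in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample ids must be unique")
        for sid, paths in self.samples:
            if len(paths) not in (1, 2):
                raise ValueError(f"sample {sid!r}: expected 1 or 2 files")

    @property
    def sample_ids(self) -> list[str]:
        return [sid for sid, _ in self.samples]

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[tuple[str, tuple[Path, ...]]]:
        return iter(self.samples)

    def iter_sample_reads(self, sample_id: str) -> Iterator[SequenceRead]:
        """Stream reads of one sample (both files of a pair, mated)."""
        for sid, paths in self.samples:
            if sid != sample_id:
                continue
            if len(paths) == 1:
                for read in read_sequences(paths[0]):
                    read.sample_id = sid
                    yield read
            else:
                for r1, r2 in pair_reads(read_sequences(paths[0]), read_sequences(paths[1])):
                    r1.sample_id = sid
                    r2.sample_id = sid
                    yield r1
                    yield r2
            return
        raise KeyError(sample_id)


def _open_text(path: os.PathLike | str, mode: str = "rt") -> IO[str]:
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, mode)
    return open(path, mode)


def _open_out(path: Path) -> IO[str]:
    if path.suffix == ".gz":
        return gzip.open(path, "wt")
    return open(path, "wt")


def _validate_sequence(seq: str, record_no: int, name: str) -> str:
    seq = seq.translate(_UPPER)
    if not set(seq) <= _VALID_BASES:
        bad = sorted(set(seq) - _VALID_BASES)
        raise SequenceFormatError(
            f"record {record_no} ({name!r}): invalid characters {bad}; "
            "only A/C/G/T/N are accepted"
        )
    if not seq:
        raise SequenceFormatError(f"record {record_no} ({name!r}): empty sequence")
    return seq


def _decode_phred(qual: str, record_no: int, name: str) -> np.ndarray:
    scores = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int16) - 33
    if scores.size and (scores.min() < 0 or scores.max() > 93):
        raise SequenceFormatError(
            f"record {record_no} ({name!r}): quality characters outside the "
            "Sanger Phred+33 range"
        )
    return scores


def detect_format(path: os.PathLike | str) -> str:
    """Peek at the first non-blank character: '>' FASTA, '@' FASTQ."""
    with _open_text(path) as fh:
        for line in fh:
            if line.strip():
                first = line[0]
                if first == ">":
                    return "fasta"
                if first == "@":
                    return "fastq"
                raise SequenceFormatError(
                    f"{path}: cannot detect format (first character {first!r})"
                )
    return "fasta"  # empty file: arbitrary, both parsers yield nothing


def read_sequences(
    path: os.PathLike | str, format: str = "auto"
) -> Iterator[SequenceRead]:
    """Stream :class:`SequenceRead` records from a FASTA/FASTQ file.

    Gzip compression is detected from the file's magic bytes. FASTQ
    qualities are decoded as Sanger Phred+33.
    """
    if format == "auto":
        format = detect_format(path)
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unknown format {format!r}")
    with _open_text(path) as fh:
        if format == "fasta":
            for i, (title, seq) in enumerate(SimpleFastaParser(fh), start=1):
                name = title.split()[0] if title.split() else title
                yield SequenceRead(name, _validate_sequence(seq, i, name))
        else:
            it = FastqGeneralIterator(fh)
            i = 0
            while True:
                i += 1
                try:
                    title, seq, qual = next(it)
                except StopIteration:
                    break
                except ValueError as exc:
                    raise SequenceFormatError(f"record {i}: {exc}") from exc
                name = title.split()[0] if title.split() else title
                seq = _validate_sequence(seq, i, name)
                quals = _decode_phred(qual, i, name)
                if len(quals) != len(seq):
                    raise SequenceFormatError(
                        f"record {i} ({name!r}): quality length {len(quals)} "
                        f"!= sequence length {len(seq)}"
                    )
                yield SequenceRead(name, seq, quals)


def pair_key(read_id: str) -> str:
    """Normalize a read id to its pair key (strip '/1', '/2', comments)."""
    key = read_id.split()[0] if read_id.split() else read_id
    if key.endswith("/1") or key.endswith("/2"):
        key = key[:-2]
    return key


def pair_reads(
    stream1: Iterable[SequenceRead], stream2: Iterable[SequenceRead]
) -> Iterator[tuple[SequenceRead, SequenceRead]]:
    """Mate two read streams positionally, reconciling /1 and /2 id suffixes."""
    it1, it2 = iter(stream1), iter(stream2)
    n = 0
    while True:
        r1 = next(it1, None)
        r2 = next(it2, None)
        if r1 is None and r2 is None:
            return
        if r1 is None or r2 is None:
            raise SequenceFormatError(
                f"paired files differ in length (mismatch after {n} pairs)"
            )
        n += 1
        k1, k2 = pair_key(r1.read_id), pair_key(r2.read_id)
        if k1 != k2:
            raise SequenceFormatError(
                f"pair {n}: mate ids {r1.read_id!r} and {r2.read_id!r} do not "
                "reconcile to the same key"
            )
        r1.mate = r2
        r2.mate = r1
        yield r1, r2


def _format_record(read: SequenceRead, fmt: str) -> str:
    if fmt == "fasta":
        return f">{read.read_id}\n{read.sequence}\n"
    if read.qualities is None:
        qual = "I" * len(read.sequence)  # Q40 placeholder for quality-less input
    else:
        qual = (read.qualities.astype(np.uint8) + 33).tobytes().decode("ascii")
    return f"@{read.read_id}\n{read.sequence}\n+\n{qual}\n"


def write_partitions(
    reads: Iterable[SequenceRead],
    assignment,
    outdir: os.PathLike | str,
    fmt: str = "fastq",
    gz: bool = False,
) -> dict[str, int]:
    """Write one file per cluster plus an ``unassigned`` file.

    ``assignment`` maps read ids (or pair keys) to cluster ids; anything not
    mapped, or mapped to a negative id, goes to ``unassigned``. Mates share
    their pair's cluster because upstream read assignment emits one joint
    cluster per pair. Returns per-file read counts.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if hasattr(assignment, "to_mapping"):
        assignment = assignment.to_mapping()
    suffix = ".%s%s" % (fmt, ".gz" if gz else "")
    handles: dict[str, IO[str]] = {}
    counts: dict[str, int] = {}
    try:
        for read in reads:
            cluster = assignment.get(read.read_id)
            if cluster is None:
                cluster = assignment.get(pair_key(read.read_id))
            name = "unassigned" if cluster is None or cluster < 0 else f"bin_{cluster}"
            fh = handles.get(name)
            if fh is None:
                fh = _open_out(outdir / (name + suffix))
                handles[name] = fh
                counts[name] = 0
            fh.write(_format_record(read, fmt))
            counts[name] += 1
    finally:
        for fh in handles.values():
            fh.close()
    return counts


def write_fastq(reads: Iterable[SequenceRead], path: os.PathLike | str) -> int:
    """Write reads to a single FASTQ file (gz if the path ends in .gz)."""
    n = 0
    with _open_out(Path(path)) as fh:
        for read in reads:
            fh.write(_format_record(read, "fastq"))
            n += 1
    return n
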