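import numpy as np
import pytest

from sparsebin.lsh import make_hyperplanes
from sparsebin.seqio import SampleSet, SequenceRead


@pytest.fixture
def small_planes():
    return make_hyperplanes(n_bits=8, k=5, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_kmer(rng, k):
    return "".join(rng.choice(list("ACGT"), size=k))


@pytest.fixture
def fastq_file(tmp_path):
    """Two-record FASTQ with distinct qualities."""
    text = (
        "@read1 comment\nACGTA\n+\nIIII5\n"
        "@read2\nTTGCA\n+\n!!!!!\n"
    )
    p = tmp_path / "two.fastq"
    p.write_text(text)
    return p


def make_reads(seqs, prefix="r", sample_id="s"):
    return [
        SequenceRead(f"{prefix}{i}", s, sample_id=sample_id) for i, s in enumerate(seqs)
    ]


def write_sample_fastq(path, reads):
    from sparsebin.seqio import write_fastq

    write_fastq(reads, path)
    return path


@pytest.fixture
def two_sample_set(tmp_path):
    """Two tiny single-end samples sharing one read sequence."""
    from sparsebin.seqio import write_fastq

    a = tmp_path / "a.fastq"
    b = tmp_path / "b.fastq"
    write_fastq(make_reads(["ACGTACGT", "TTTTCCCC"], prefix="a", sample_id="a"), a)
    write_fastq(make_reads(["ACGTACGT"], prefix="b", sample_id="b"), b)
    return SampleSet([("a", (a,)), ("b", (b,))])
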