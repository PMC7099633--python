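"""Synthetic multi-sample communities with known read -> genome truth.

Two designs are emulated, without any external downloads:

* a virtual cohort of S samples, each mixing g of G pool genomes drawn
  under a power-law abundance distribution (rank i gets weight i**-alpha),
  sequenced to a target mean depth with i.i.d. substitution errors;
* a spiked low-abundance target: every sample carries a background
  community, and a subset of samples additionally receives a fixed small
  number of read pairs from a short target replicon — the regime where
  per-sample assembly fails but cross-sample covariance binning succeeds.

Genomes are i.i.d. uniform random DNA, so inter-genome k-mer sharing is
essentially zero; this isolates the abundance-covariance signal that the
binning method actually exploits. All randomness flows from explicit
seeds, and FASTQ output is byte-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .seqio import SampleSet, SequenceRead

__all__ = [
    "CommunitySpec",
    "SpikeSpec",
    "simulate_genomes",
    "sample_abundances",
    "simulate_reads",
    "simulate_cohort",
    "make_spiked_dataset",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP[_a] = _b

#: constant Phred quality written to simulated FASTQ
_SIM_QUALITY = 30


@dataclass
class CommunitySpec:
    """Design of a virtual cohort sample set."""

    n_genomes: int = 12
    genome_length: int = 100_000
    n_samples: int = 12
    genomes_per_sample: int = 8
    alpha: float = 1.0
    depth: float = 10.0
    read_length: int = 100
    paired: bool = True  # the emulated control libraries are Illumina paired-end
    insert_size: int = 300
    error_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genomes_per_sample > self.n_genomes:
            raise ValueError("genomes_per_sample must be <= n_genomes")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        for name in ("n_genomes", "genome_length", "n_samples",
                     "genomes_per_sample", "read_length", "insert_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    @property
    def reads_per_sample(self) -> int:
        """Read count giving the requested mean depth over a sample's mixture."""
        total_bases = self.depth * self.genomes_per_sample * self.genome_length
        n = int(round(total_bases / self.read_length))
        return n - n % 2 if self.paired else n


@dataclass
class SpikeSpec:
    """Design of the spiked low-abundance target experiment."""

    n_samples: int = 18
    background_reads: int = 20_000
    n_spiked_samples: int = 14
    spiked_pairs: int = 100
    target_length: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_spiked_samples > self.n_samples:
            raise ValueError("n_spiked_samples must be <= n_samples")


def simulate_genomes(
    n_genomes: int, length: int, seed: int, prefix: str = "genome"
) -> list[tuple[str, str]]:
    """i.i.d. uniform ACGT genomes with distinct labels; seeded."""
    rng = np.random.default_rng(seed)
    out = []
    for g in range(n_genomes):
        seq = _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")
        out.append((f"{prefix}_{g:03d}", seq))
    return out


def sample_abundances(
    g: int, alpha: float, rng: np.random.Generator | int
) -> np.ndarray:
    """Power-law relative abundances: rank i (1-based, after a seeded
    permutation of the drawn genomes) gets weight i**-alpha, normalized."""
    if g < 1:
        raise ValueError("g must be >= 1")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    weights = np.arange(1, g + 1, dtype=float) ** -alpha
    weights /= weights.sum()
    ranks = rng.permutation(g)  # which genome takes which rank
    return weights[ranks]


def _mutate(reads: np.ndarray, error_rate: float, rng: np.random.Generator) -> np.ndarray:
    """i.i.d. substitutions to a uniformly random *other* base."""
    if error_rate <= 0:
        return reads
    mask = rng.random(reads.shape) < error_rate
    if not mask.any():
        return reads
    shift = rng.integers(1, 4, size=int(mask.sum()))
    base_idx = np.searchsorted(_BASES, reads[mask])
    reads[mask] = _BASES[(base_idx + shift) % 4]
    return reads


def _extract(genome_arr: np.ndarray, starts: np.ndarray, length: int) -> np.ndarray:
    return genome_arr[starts[:, None] + np.arange(length)[None, :]]


def simulate_reads(
    genomes: list[tuple[str, str]],
    abundances: np.ndarray,
    n_reads: int,
    read_length: int,
    rng: np.random.Generator | int,
    paired: bool = False,
    insert_size: int = 300,
    error_rate: float = 0.0,
    sample_id: str = "sample",
) -> tuple[list[SequenceRead], dict[str, str]]:
    """Draw reads by genome abundance, uniform start, substitution errors.

    In paired mode ``n_reads`` counts individual reads (two per fragment);
    mate 2 is the reverse complement of the window ``insert_size`` from the
    fragment start. Returns the reads and their truth table.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if len(genomes) != len(abundances):
        raise ValueError("genomes/abundances length mismatch")
    span = insert_size if paired else read_length
    for label, seq in genomes:
        if len(seq) < span:
            raise ValueError(f"genome {label!r} shorter than read span {span}")
    n_frags = n_reads // 2 if paired else n_reads
    if paired and n_reads % 2:
        raise ValueError("paired mode needs an even n_reads")
    counts = rng.multinomial(n_frags, np.asarray(abundances, dtype=float))
    quals = np.full(read_length, _SIM_QUALITY, dtype=np.int16)
    reads: list[SequenceRead] = []
    truth: dict[str, str] = {}
    frag_no = 0
    for (label, seq), n_g in zip(genomes, counts):
        if n_g == 0:
            continue
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        starts = rng.integers(0, len(arr) - span + 1, size=n_g)
        fwd = _mutate(_extract(arr, starts, read_length).copy(), error_rate, rng)
        if paired:
            rev_win = _extract(arr, starts + insert_size - read_length, read_length)
            rev = _COMP[rev_win[:, ::-1]].copy()
            rev = _mutate(rev, error_rate, rng)
        for i in range(n_g):
            base_id = f"{sample_id}:f{frag_no:07d}"
            frag_no += 1
            if paired:
                r1 = SequenceRead(base_id + "/1", fwd[i].tobytes().decode("ascii"),
                                  quals.copy(), sample_id)
                r2 = SequenceRead(base_id + "/2", rev[i].tobytes().decode("ascii"),
                                  quals.copy(), sample_id)
                r1.mate, r2.mate = r2, r1
                reads.extend((r1, r2))
                truth[r1.read_id] = label
                truth[r2.read_id] = label
            else:
                r = SequenceRead(base_id, fwd[i].tobytes().decode("ascii"),
                                 quals.copy(), sample_id)
                reads.append(r)
                truth[r.read_id] = label
    return reads, truth


def _write_sample(reads, sample_dir: Path, sample_id: str, paired: bool) -> tuple[Path, ...]:
    from .seqio import write_fastq

    if paired:
        p1 = sample_dir / f"{sample_id}_R1.fastq"
        p2 = sample_dir / f"{sample_id}_R2.fastq"
        write_fastq((r for r in reads if r.read_id.endswith("/1")), p1)
        write_fastq((r for r in reads if r.read_id.endswith("/2")), p2)
        return (p1, p2)
    p = sample_dir / f"{sample_id}.fastq"
    write_fastq(reads, p)
    return (p,)


def _write_truth(truth: dict[str, str], path: Path) -> None:
    with open(path, "w") as fh:
        for rid, genome in truth.items():
            fh.write(f"{rid}\t{genome}\n")


def simulate_cohort(
    spec: CommunitySpec, outdir: Path | str
) -> tuple[SampleSet, Path]:
    """Materialize a virtual cohort: per-sample FASTQ, truth.tsv, spec.json.

    Each sample draws ``genomes_per_sample`` genomes from the pool without
    replacement and ranks them under the power law independently.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(spec.seed)
    genome_seed, *sample_seeds = root.spawn(spec.n_samples + 1)
    genomes = simulate_genomes(
        spec.n_genomes, spec.genome_length,
        int(genome_seed.generate_state(1)[0] % (2**31)),
    )
    truth: dict[str, str] = {}
    samples: list[tuple[str, tuple[Path, ...]]] = []
    for s, ss in enumerate(sample_seeds):
        rng = np.random.default_rng(ss)
        sample_id = f"sample_{s:02d}"
        drawn = rng.choice(spec.n_genomes, size=spec.genomes_per_sample, replace=False)
        abund = sample_abundances(spec.genomes_per_sample, spec.alpha, rng)
        reads, t = simulate_reads(
            [genomes[i] for i in drawn], abund, spec.reads_per_sample,
            spec.read_length, rng, paired=spec.paired,
            insert_size=spec.insert_size, error_rate=spec.error_rate,
            sample_id=sample_id,
        )
        truth.update(t)
        samples.append((sample_id, _write_sample(reads, outdir, sample_id, spec.paired)))
    truth_path = outdir / "truth.tsv"
    _write_truth(truth, truth_path)
    (outdir / "spec.json").write_text(json.dumps(asdict(spec), indent=1))
    return SampleSet(samples), truth_path


def make_spiked_dataset(
    spec: SpikeSpec,
    background: Optional[CommunitySpec] = None,
    outdir: Path | str = ".",
) -> tuple[SampleSet, Path]:
    """Materialize the spiked-target design.

    Every sample gets ``background_reads`` single-end reads from its own
    background mixture; the first ``n_spiked_samples`` samples additionally
    receive ``spiked_pairs`` read pairs from the target replicon. Truth
    labels background genomes by pool label and target reads as "target".
    """
    if background is None:
        background = CommunitySpec(n_genomes=20, genome_length=100_000,
                                   n_samples=spec.n_samples, genomes_per_sample=10,
                                   seed=spec.seed)
    if background.n_samples != spec.n_samples:
        raise ValueError("background n_samples must match spike n_samples")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(spec.seed)
    genome_seed, target_seed, *sample_seeds = root.spawn(spec.n_samples + 2)
    pool = simulate_genomes(
        background.n_genomes, background.genome_length,
        int(genome_seed.generate_state(1)[0] % (2**31)), prefix="background",
    )
    (target,) = simulate_genomes(
        1, spec.target_length,
        int(target_seed.generate_state(1)[0] % (2**31)), prefix="plasmid",
    )
    target = ("target", target[1])
    truth: dict[str, str] = {}
    samples: list[tuple[str, tuple[Path, ...]]] = []
    for s, ss in enumerate(sample_seeds):
        rng = np.random.default_rng(ss)
        sample_id = f"sample_{s:02d}"
        drawn = rng.choice(background.n_genomes,
                           size=background.genomes_per_sample, replace=False)
        abund = sample_abundances(background.genomes_per_sample, background.alpha, rng)
        reads, t = simulate_reads(
            [pool[i] for i in drawn], abund, spec.background_reads,
            background.read_length, rng, paired=False,
            error_rate=background.error_rate, sample_id=sample_id,
        )
        if s < spec.n_spiked_samples:
            spike_reads, spike_t = simulate_reads(
                [target], np.array([1.0]), 2 * spec.spiked_pairs,
                background.read_length, rng, paired=True,
                insert_size=background.insert_size,
                error_rate=background.error_rate,
                sample_id=f"{sample_id}:spike",
            )
            reads.extend(spike_reads)
            t.update(spike_t)
        truth.update(t)
        samples.append((sample_id, _write_sample(reads, outdir, sample_id, False)))
    truth_path = outdir / "truth.tsv"
    _write_truth(truth, truth_path)
    (outdir / "spec.json").write_text(
        json.dumps({"spike": asdict(spec), "background": asdict(background)}, indent=1)
    )
    return SampleSet(samples), truth_path
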