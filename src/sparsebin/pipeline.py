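"""Orchestration: hash-count -> cluster buckets -> assign reads -> evaluate.

One :class:`PipelineConfig` drives every stage; each stage's artifact is
written under the run directory and individually re-runnable from the CLI.
The hashed matrix is cached by its parameter fingerprint so switching the
clustering method does not re-hash. Reruns with identical config and seed
reproduce the assignment files byte for byte (timings live in a separate
log, never in result artifacts).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import abundance, baselines, evaluation, factorize, read_binning, seqio
from .lsh import make_hyperplanes

logger = logging.getLogger("sparsebin")

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Validated parameters for a full run.

    ``method`` selects the bucket clustering: ``sparse`` (dictionary
    learning), ``lsa`` (SVD + cosine leader clustering) or ``kmeans``.
    """

    k: int = 31
    n_bits: int = 30
    seed: int = 0
    method: str = "sparse"
    components: int = 100
    l1: float = 0.1
    l2: float = 0.01
    gamma1: float = 0.0
    gamma2: float = 0.0
    batch_size: int = 512
    epochs: int = 5
    nonneg_dict: bool = True
    nonneg_code: bool = True
    min_matches: int = 2
    rank: Optional[int] = None  # lsa: defaults to min(S-1, components)
    cos_threshold: float = 0.7
    n_clusters: int = 1000
    use_quality: bool = False
    paired_assignment: bool = False
    write_partitions: bool = False

    def __post_init__(self) -> None:
        if self.method not in ("sparse", "lsa", "kmeans"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.k < 1 or self.n_bits < 1:
            raise ValueError("k and n_bits must be >= 1")
        if self.components < 1:
            raise ValueError("components must be >= 1")
        if min(self.l1, self.l2, self.gamma1, self.gamma2) < 0:
            raise ValueError("penalties must be non-negative")
        if not 0 < self.cos_threshold <= 1:
            raise ValueError("cos_threshold must be in (0, 1]")

    def matrix_fingerprint(self, sample_ids: list[str]) -> str:
        key = json.dumps(
            {"k": self.k, "n_bits": self.n_bits, "seed": self.seed,
             "use_quality": self.use_quality, "samples": sample_ids},
            sort_keys=True,
        )
        return hashlib.sha256(key.encode()).hexdigest()[:16]


def load_config(path: Path | str) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def _cluster_buckets(
    config: PipelineConfig, matrix, outdir: Path
) -> factorize.BucketAssignment:
    if config.method == "sparse":
        dictionary, code, assignment = factorize.factorize_matrix(
            matrix, config.components, l1=config.l1, l2=config.l2,
            gamma1=config.gamma1, gamma2=config.gamma2,
            batch_size=config.batch_size, epochs=config.epochs,
            seed=config.seed, nonneg_dict=config.nonneg_dict,
            nonneg_code=config.nonneg_code,
        )
        factorize.save_model(outdir / "model", dictionary, code, assignment)
        return assignment
    if config.method == "lsa":
        rank = config.rank
        if rank is None:
            rank = min(len(matrix.sample_ids) - 1, config.components)
        return baselines.lsa_baseline(matrix, rank, config.cos_threshold,
                                      seed=config.seed)
    return baselines.kmeans_baseline(matrix, config.n_clusters, seed=config.seed)


def run_pipeline(
    config: PipelineConfig,
    samples: seqio.SampleSet,
    outdir: Path | str,
    truth_path: Optional[Path | str] = None,
) -> dict:
    """Run every stage; returns the run summary (also written as run.json)."""
    if len(samples) < 2:
        raise ValueError("need >= 2 samples: covariance requires multiple profiles")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    artifacts: dict[str, str] = {}

    def stage(name):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = time.perf_counter() - self_inner.t0
                if exc is not None:
                    logger.error("stage %s failed: %s", name, exc)
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
                logger.info("stage %s: %.2fs", name, timings[name])

        return _Timer()

    planes = make_hyperplanes(config.n_bits, config.k, config.seed)
    matrix_path = outdir / f"matrix_{config.matrix_fingerprint(samples.sample_ids)}.mtx"
    with stage("hash_count"):
        if matrix_path.exists():
            logger.info("reusing cached matrix %s", matrix_path.name)
            matrix = abundance.load_matrix(matrix_path)
        else:
            matrix = abundance.accumulate_counts(samples, planes,
                                                 use_quality=config.use_quality)
            abundance.save_matrix(matrix, matrix_path)
        matrix = abundance.normalize_rows(matrix)
    artifacts["matrix"] = str(matrix_path)

    with stage("cluster_buckets"):
        bucket_assignment = _cluster_buckets(config, matrix, outdir)
        bucket_path = outdir / "buckets.tsv"
        bucket_assignment.save_tsv(bucket_path)
    artifacts["buckets"] = str(bucket_path)

    with stage("assign_reads"):
        stats = read_binning.build_cluster_stats(matrix, bucket_assignment)

        def all_reads():
            for sid, _ in samples:
                yield from samples.iter_sample_reads(sid)

        assignment = read_binning.assign_reads(
            all_reads(), planes, stats,
            min_matches=config.min_matches,
            paired=config.paired_assignment,
            use_quality=config.use_quality,
        )
        assignment_path = outdir / "assignments.tsv"
        assignment.save_tsv(assignment_path)
    artifacts["assignments"] = str(assignment_path)

    if config.write_partitions:
        with stage("partition"):
            part_dir = outdir / "partitions"
            mapping = assignment.to_mapping()
            counts = seqio.write_partitions(all_reads(), mapping, part_dir)
        artifacts["partitions"] = str(part_dir)
        logger.info("partition counts: %s", counts)

    report = None
    if truth_path is not None:
        with stage("evaluate"):
            truth = evaluation.read_truth(truth_path)
            report = evaluation.evaluate(assignment, truth)
            report_path = outdir / "report.json"
            report_path.write_text(json.dumps(report.to_dict(), indent=1, sort_keys=True))
        artifacts["report"] = str(report_path)

    cluster_sizes = np.bincount(
        bucket_assignment.labels[bucket_assignment.labels >= 0],
        minlength=bucket_assignment.n_clusters,
    )
    summary = {
        "config": asdict(config),
        "sample_ids": samples.sample_ids,
        "n_kmers_total": int(stats.n_total),
        "n_occupied_buckets": int(stats.n_occupied),
        "n_clusters": int(bucket_assignment.n_clusters),
        "cluster_bucket_sizes": cluster_sizes.tolist(),
        "artifacts": {k: _sha256(Path(v)) for k, v in artifacts.items()
                      if Path(v).is_file()},
    }
    if report is not None:
        summary["evaluation"] = report.to_dict()
    (outdir / "run.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    (outdir / "log.json").write_text(json.dumps({"timings_s": timings}, indent=1))
    return summary
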