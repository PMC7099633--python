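"""Weighted precision, recall and F-value against a read -> genome truth.

Every cluster x is mapped to its most read-abundant genome; with X the
set of clusters and Y the set of genomes,

    p = sum_x max_y |x n y| / sum_x |x|        (purity of the bins)
    r = sum_y max_x |x n y| / sum_y |y|        (completeness of the genomes)

so larger bins carry proportionally more weight. Unassigned reads are
excluded from the precision denominator but still count in the recall
denominator: a read left out of every bin hurts completeness, not purity.
F is the harmonic mean 2pr/(p + r).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

__all__ = ["GroundTruth", "EvalReport", "read_truth", "evaluate"]


@dataclass
class GroundTruth:
    """read_id -> genome label."""

    labels: dict[str, str]

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValueError("ground truth is empty")
        if any(not g for g in self.labels.values()):
            raise ValueError("empty genome label in ground truth")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class EvalReport:
    precision: float
    recall: float
    f_value: float
    cluster_mapping: dict[int, str]
    contingency: dict[int, dict[str, int]]
    n_assigned: int
    n_reads: int

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f_value": self.f_value,
            "n_assigned": self.n_assigned,
            "n_reads": self.n_reads,
            "cluster_mapping": {str(c): g for c, g in sorted(self.cluster_mapping.items())},
        }


def read_truth(path: Path | str) -> GroundTruth:
    """Parse a two-column TSV ``read_id<TAB>genome``."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise ValueError(f"line {lineno}: expected 'read_id<TAB>genome'")
            rid, genome = parts
            if rid in labels:
                raise ValueError(f"line {lineno}: duplicate read id {rid!r}")
            labels[rid] = genome
    return GroundTruth(labels)


def evaluate(assignment, truth: GroundTruth) -> EvalReport:
    """Score a read clustering against the ground truth.

    ``assignment`` is a :class:`~sparsebin.read_binning.BinAssignment` or a
    plain mapping read_id -> cluster id (negative/None = unassigned). Every
    read of the assignment must be covered by the truth; truth reads absent
    from the assignment count as unassigned.
    """
    if hasattr(assignment, "to_mapping"):
        assignment = assignment.to_mapping()
    contingency: dict[int, Counter] = defaultdict(Counter)
    n_assigned = 0
    for rid, cluster in assignment.items():
        genome = truth.labels.get(rid)
        if genome is None:
            raise KeyError(f"assigned read {rid!r} missing from ground truth")
        if cluster is None or cluster < 0:
            continue
        contingency[cluster][genome] += 1
        n_assigned += 1

    sum_x = sum(sum(c.values()) for c in contingency.values())
    mapping: dict[int, str] = {}
    tp = 0
    for cluster, counts in contingency.items():
        best_count = max(counts.values())
        # ties -> lexicographically smaller genome label
        mapping[cluster] = min(g for g, n in counts.items() if n == best_count)
        tp += best_count
    precision = tp / sum_x if sum_x else 0.0

    genome_totals = Counter(truth.labels.values())
    best_per_genome: dict[str, int] = defaultdict(int)
    for counts in contingency.values():
        for genome, n in counts.items():
            if n > best_per_genome[genome]:
                best_per_genome[genome] = n
    sum_y = sum(genome_totals.values())
    recall = sum(best_per_genome.values()) / sum_y if sum_y else 0.0

    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return EvalReport(
        precision=precision,
        recall=recall,
        f_value=f,
        cluster_mapping=mapping,
        contingency={c: dict(cnt) for c, cnt in contingency.items()},
        n_assigned=n_assigned,
        n_reads=len(truth),
    )
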