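import numpy as np
import pytest

from sparsebin.abundance import accumulate_counts
from sparsebin.factorize import BucketAssignment
from sparsebin.lsh import hash_read_batch, make_hyperplanes
from sparsebin.read_binning import (
    BinAssignment,
    ClusterStats,
    assign_reads,
    build_cluster_stats,
    score_bucket_set,
    score_read,
)
from sparsebin.seqio import SampleSet, SequenceRead
from sparsebin.synthetic import simulate_genomes, simulate_reads

from conftest import make_reads, write_sample_fastq


def toy_stats():
    """B_occ=4, N_total=8, clusters c0={w0,w1}, c1={w2}; counts (2,2,4)."""
    return ClusterStats(
        occupied=np.arange(4),
        bucket_cluster=np.array([0, 0, 1, -1]),
        bucket_counts=np.array([2, 2, 4, 0]),
        cluster_sizes=np.array([2, 1]),
        n_total=8,
    )


class TestScore:
    def test_toy_arithmetic(self):
        scores = score_bucket_set([0, 2], toy_stats())
        assert scores[0] == pytest.approx(np.log(8 / 2) + np.log(4 / 2))
        assert scores[1] == pytest.approx(np.log(8 / 4) + np.log(4 / 1))

    def test_no_match_all_minus_inf(self):
        scores = score_bucket_set([3], toy_stats())
        assert np.all(np.isinf(scores)) and np.all(scores < 0)

    def test_single_cluster_unique_finite_max(self):
        scores = score_bucket_set([0, 1], toy_stats())
        assert np.isfinite(scores[0]) and np.isinf(scores[1])

    def test_additivity_against_direct_sum(self, rng):
        stats = toy_stats()
        for _ in range(20):
            buckets = np.unique(rng.integers(0, 4, size=rng.integers(1, 5)))
            scores = score_bucket_set(buckets, stats)
            for c in range(2):
                terms = [
                    np.log(stats.n_total / stats.bucket_counts[w])
                    + np.log(stats.n_occupied / stats.cluster_sizes[c])
                    for w in buckets
                    if stats.bucket_cluster[w] == c
                ]
                if terms:
                    assert scores[c] == pytest.approx(sum(terms))
                else:
                    assert scores[c] == -np.inf

    def test_adding_rare_bucket_never_decreases(self):
        stats = ClusterStats(
            occupied=np.arange(3),
            bucket_cluster=np.array([0, 0, 0]),
            bucket_counts=np.array([1, 5, 10]),
            cluster_sizes=np.array([3]),
            n_total=16,
        )
        base = score_bucket_set([1], stats)[0]
        assert score_bucket_set([1, 0], stats)[0] >= base

    def test_score_read_uses_hashing(self, small_planes):
        # build stats over the read's own buckets; its score must be finite
        read = SequenceRead("r", "ACGTACGTA")
        buckets = np.unique(hash_read_batch([read], small_planes)[0])
        stats = ClusterStats(
            occupied=buckets,
            bucket_cluster=np.zeros(buckets.size, dtype=np.int64),
            bucket_counts=np.ones(buckets.size, dtype=np.int64),
            cluster_sizes=np.array([buckets.size]),
            n_total=buckets.size,
        )
        scores = score_read(read, small_planes, stats)
        assert np.isfinite(scores[0])

    def test_empty_stats_error(self):
        stats = ClusterStats(
            occupied=np.array([0]), bucket_cluster=np.array([-1]),
            bucket_counts=np.array([0]), cluster_sizes=np.array([], dtype=int),
            n_total=0,
        )
        with pytest.raises(ValueError, match="empty"):
            score_bucket_set([0], stats)


class FakeRead:
    def __init__(self, read_id, buckets):
        self.read_id = read_id
        self.buckets = buckets


def assign_from_buckets(bucket_sets, stats, min_matches=2):
    """Drive the vectorized resolver directly from bucket sets."""
    from sparsebin.read_binning import _resolve_batch

    contrib = stats.contributions()
    sets = [np.unique(np.asarray(b, dtype=np.int64)) for b in bucket_sets]
    return _resolve_batch(sets, stats, contrib, min_matches)


class TestAssign:
    def test_min_matches_unassigned(self):
        (res,) = assign_from_buckets([[0]], toy_stats(), min_matches=2)
        assert res[0] == -1

    def test_two_matches_assigned(self):
        (res,) = assign_from_buckets([[0, 1]], toy_stats(), min_matches=2)
        assert res[0] == 0 and res[2] == 2

    def test_tie_breaks_to_smaller_cluster(self):
        stats = ClusterStats(
            occupied=np.arange(4),
            bucket_cluster=np.array([0, 0, 1, 1]),
            bucket_counts=np.array([2, 2, 2, 2]),
            cluster_sizes=np.array([2, 2]),
            n_total=8,
        )
        # read hits one bucket of each cluster: identical scores
        (res,) = assign_from_buckets([[0, 2]], stats, min_matches=1)
        assert res[0] == 0

    def test_resolver_matches_scalar_scores(self, rng):
        stats = toy_stats()
        sets = [rng.integers(0, 4, size=rng.integers(1, 6)) for _ in range(50)]
        results = assign_from_buckets(sets, stats, min_matches=1)
        for buckets, (cluster, score, _) in zip(sets, results):
            scores = score_bucket_set(buckets, stats)
            if np.all(np.isinf(scores)):
                assert cluster == -1
            else:
                assert cluster == int(np.argmax(scores))
                assert score == pytest.approx(scores[cluster])

    def test_paired_reads_jointly_assigned(self, tmp_path, small_planes):
        # mates whose buckets individually miss min_matches but jointly pass
        r1 = SequenceRead("f/1", "ACGTA")
        r2 = SequenceRead("f/2", "TTGCA")
        p1 = write_sample_fastq(tmp_path / "r1.fastq", [r1])
        p2 = write_sample_fastq(tmp_path / "r2.fastq", [r2])
        samples = SampleSet([("s", (p1, p2))])
        matrix = accumulate_counts(samples, small_planes)
        occ = matrix.occupied_buckets()
        assignment = BucketAssignment(
            bucket_ids=occ, labels=np.zeros(occ.size, dtype=np.int64),
            n_clusters=1, component_map={0: 0},
        )
        stats = build_cluster_stats(matrix, assignment)
        reads = list(samples.iter_sample_reads("s"))
        out = assign_reads(reads, small_planes, stats, min_matches=2, paired=True)
        assert out.cluster_of("f/1") == out.cluster_of("f/2") == 0

    def test_tsv_roundtrip(self, tmp_path):
        a = BinAssignment()
        a.add("r1", 0, 1.5, 3)
        a.add("r2", -1, float("-inf"), 0)
        a.save_tsv(tmp_path / "a.tsv")
        back = BinAssignment.load_tsv(tmp_path / "a.tsv")
        assert back.entries["r1"][0] == 0
        assert back.entries["r2"][0] == -1


def test_stats_fixed_memory_at_nominal_hash_size():
    """Scoring statistics must scale with occupied buckets, not 2^n_bits:
    a 2^30-bucket matrix with 3 occupied buckets stays tiny."""
    import scipy.sparse as sp

    from sparsebin.abundance import AbundanceMatrix

    counts = sp.coo_matrix(
        (np.array([3, 4, 3], dtype=np.int64),
         (np.array([0, 0, 1]), np.array([123, 999, 2**30 - 1]))),
        shape=(2, 2**30),
    ).tocsr()
    m = AbundanceMatrix(counts=counts, sample_ids=["a", "b"], n_bits=30, k=31, seed=0)
    a = BucketAssignment(
        bucket_ids=np.array([123, 999, 2**30 - 1]),
        labels=np.array([0, 0, 1]), n_clusters=2, component_map={0: 0, 1: 1},
    )
    stats = build_cluster_stats(m, a)
    assert stats.n_occupied == 3 and stats.n_total == 10
    scores = score_bucket_set([123, 2**30 - 1, 555], stats)  # 555 unoccupied
    assert scores[0] == pytest.approx(np.log(10 / 3) + np.log(3 / 2))
    assert scores[1] == pytest.approx(np.log(10 / 3) + np.log(3 / 1))


class TestEndToEndPlanted:
    def test_two_genome_community_reads_follow_their_genome(self, tmp_path):
        # disjoint k-mer content (random genomes), distinct abundance
        # profiles; buckets labeled by hashing the genomes themselves
        k, n_bits = 31, 16
        hp = make_hyperplanes(n_bits, k, seed=4)
        genomes = simulate_genomes(2, 20_000, seed=9)
        profiles = [[0.9, 0.1], [0.2, 0.8], [0.85, 0.15], [0.25, 0.75]]
        files = []
        all_reads = {}
        for s, ab in enumerate(profiles):
            reads, truth = simulate_reads(
                genomes, np.array(ab), 2000, 100, np.random.default_rng(100 + s),
                paired=False, error_rate=0.0, sample_id=f"s{s}",
            )
            path = write_sample_fastq(tmp_path / f"s{s}.fastq", reads)
            files.append((f"s{s}", (path,)))
            all_reads.update(truth)
        samples = SampleSet(files)
        matrix = accumulate_counts(samples, hp)

        comp = str.maketrans("ACGT", "TGCA")
        bucket_sets = []
        for _, seq in genomes:
            both = np.concatenate(
                hash_read_batch([seq, seq.translate(comp)[::-1]], hp)
            )
            bucket_sets.append(np.unique(both))
        contested = np.intersect1d(bucket_sets[0], bucket_sets[1])
        table = np.full(1 << n_bits, -1, dtype=np.int64)
        for gi, buckets in enumerate(bucket_sets):
            table[buckets] = gi
        table[contested] = -1  # shared buckets carry no genome signal
        occ = matrix.occupied_buckets()
        assignment = BucketAssignment(
            bucket_ids=occ, labels=table[occ], n_clusters=2,
            component_map={0: 0, 1: 1},
        )
        stats = build_cluster_stats(matrix, assignment)

        def reads():
            for sid, _ in samples:
                yield from samples.iter_sample_reads(sid)

        out = assign_reads(reads(), hp, stats)
        correct = total = 0
        for rid, (cluster, _, _) in out.entries.items():
            total += 1
            genome_idx = int(all_reads[rid].split("_")[-1])
            correct += cluster == genome_idx
        assert total == 8000
        assert correct / total >= 0.95
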