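"""Genome registry, two-tier counting, partition routing and run_count."""

import random

import pytest

from mafkmers.block_counter import ExtractionOptions, KmerGroup
from mafkmers.count_store import (
    CounterPartition,
    GenomeRegistry,
    add_count,
    merge_group,
    partition_index,
    run_count,
)
from mafkmers.errors import CapacityError
from mafkmers.kmer_codec import KmerCode, NUCLEOTIDE, encode


class TestGenomeRegistry:
    def test_first_seen_order_and_idempotence(self):
        reg = GenomeRegistry()
        assert reg.register("hg38") == 0
        assert reg.register("mm39") == 1
        assert reg.register("hg38") == 0
        assert reg.names == ("hg38", "mm39")

    def test_default_capacity_is_256(self):
        reg = GenomeRegistry()
        for i in range(256):
            assert reg.register(f"g{i}") == i
        with pytest.raises(CapacityError, match="large"):
            reg.register("g256")

    def test_large_mode_raises_capacity(self):
        reg = GenomeRegistry(large=True)
        for i in range(300):
            assert reg.register(f"g{i}") == i


class TestAddCount:
    KEY = (0, encode("ACGT"))

    def test_first_occurrence_is_implicit_singleton(self):
        p = CounterPartition()
        add_count(p, self.KEY, 1)
        assert self.KEY in p.singletons and self.KEY not in p.counted
        assert p.effective_count(self.KEY) == 1

    def test_reoccurrence_promotes_to_count_two(self):
        p = CounterPartition()
        add_count(p, self.KEY, 1)
        add_count(p, self.KEY, 1)
        assert self.KEY not in p.singletons
        assert p.counted[self.KEY] == 2

    def test_bulk_first_insert_goes_straight_to_counted(self):
        p = CounterPartition()
        add_count(p, self.KEY, 5)
        assert p.counted[self.KEY] == 5

    def test_saturation_at_cap_is_reported_not_wrapped(self):
        p = CounterPartition(count_cap=255)
        add_count(p, self.KEY, 255)
        add_count(p, self.KEY, 1)
        assert p.counted[self.KEY] == 255
        assert self.KEY in p.overflowed

    def test_tiers_match_plain_counter_on_fuzzed_sequences(self):
        """The singleton/counted split is unobservable vs a plain map."""
        rng = random.Random(7)
        for cap in (255, 4294967295):
            p = CounterPartition(count_cap=cap)
            reference: dict = {}
            keys = [(g, encode("ACG")) for g in range(3)] + [
                (0, KmerCode(v, 3, NUCLEOTIDE)) for v in range(10)
            ]
            for _ in range(2000):
                key = rng.choice(keys)
                n = rng.choice([1, 1, 1, 2, 5, 100])
                add_count(p, key, n)
                reference[key] = min(cap, reference.get(key, 0) + n)
            for key in keys:
                assert p.effective_count(key) == reference.get(key, 0)
            assert p.singletons.isdisjoint(p.counted)

    def test_nonpositive_n_rejected(self):
        with pytest.raises(ValueError):
            add_count(CounterPartition(), self.KEY, 0)


class TestPartitionIndex:
    def test_single_merger_takes_everything(self):
        assert partition_index(encode("ACGT"), 1) == 0

    def test_deterministic(self):
        code = encode("ACGTACGTACGTACG")
        assert len({partition_index(code, 8) for _ in range(10_000)}) == 1

    def test_near_uniform_occupancy(self):
        rng = random.Random(1)
        buckets = [0] * 8
        for _ in range(100_000):
            code = KmerCode(rng.getrandbits(30), 15, NUCLEOTIDE)
            buckets[partition_index(code, 8)] += 1
        assert all(b > 0 for b in buckets)
        assert max(buckets) < 2 * min(buckets)

    def test_invalid_merger_count(self):
        with pytest.raises(ValueError):
            partition_index(encode("A"), 0)


class TestMergeGroup:
    def test_entry_lands_in_exactly_one_partition(self):
        parts = [CounterPartition() for _ in range(4)]
        group = KmerGroup(0, {(0, encode("AC")): 3})
        merge_group(parts, group)
        holders = [p for p in parts if p.effective_count((0, encode("AC")))]
        assert len(holders) == 1
        assert holders[0].effective_count((0, encode("AC"))) == 3

    def test_partition_count_does_not_change_totals(self):
        rng = random.Random(3)
        group = KmerGroup(
            0,
            {
                (rng.randrange(3), KmerCode(v, 4, NUCLEOTIDE)): rng.randint(1, 9)
                for v in rng.sample(range(256), 40)
            },
        )
        totals = {}
        for n_parts in (1, 8):
            parts = [CounterPartition() for _ in range(n_parts)]
            merge_group(parts, group)
            merged = {}
            for p in parts:
                for key in p.singletons:
                    merged[key] = 1
                merged.update(p.counted)
            totals[n_parts] = merged
        assert totals[1] == totals[8]

    def test_empty_group_is_noop(self):
        parts = [CounterPartition()]
        merge_group(parts, KmerGroup(0, {}))
        assert not parts[0].singletons and not parts[0].counted


class TestRunCount:
    MAF = "a\ns g1.chr1 0 8 + 100 ACGTACGT\n"

    def test_window_counts_match_enumeration(self, write_maf):
        path = write_maf(self.MAF)
        result = run_count(path, ExtractionOptions(k=4))
        assert result.string_tables() == {
            "g1": {"ACGT": 2, "CGTA": 1, "GTAC": 1, "TACG": 1}
        }
        assert result.report.total_kmers == 5
        assert result.report.distinct_per_genome == {"g1": 4}

    @pytest.mark.parametrize("n_workers", [2, 3, 8])
    def test_worker_count_invariance(self, write_maf, n_workers):
        path = write_maf(self.MAF)
        baseline = run_count(path, ExtractionOptions(k=4), n_workers=1)
        other = run_count(path, ExtractionOptions(k=4), n_workers=n_workers)
        assert other.per_genome == baseline.per_genome
        assert other.report == baseline.report

    def test_identical_sequences_give_identical_tables(self, write_maf):
        maf = "a\ns g1.chr1 0 6 + 100 ACGTAC\ns g2.chr1 0 6 + 100 ACGTAC\n"
        result = run_count(write_maf(maf), ExtractionOptions(k=3))
        tables = result.string_tables()
        assert tables["g1"] == tables["g2"] != {}

    def test_canonical_pools_reverse_complements(self, write_maf):
        maf = "a\ns g1.chr1 0 3 + 100 TTG\ns g1.chr2 0 3 + 100 CAA\n"
        plain = run_count(write_maf(maf), ExtractionOptions(k=3)).string_tables()
        can = run_count(write_maf(maf), ExtractionOptions(k=3, canonical=True)).string_tables()
        assert plain["g1"] == {"TTG": 1, "CAA": 1}
        assert can["g1"] == {"CAA": 2}

    def test_capacity_error_propagates_with_hint(self, write_maf):
        lines = ["a"] + [f"s g{i}.c 0 2 + 10 AC" for i in range(257)]
        path = write_maf("\n".join(lines) + "\n")
        with pytest.raises(CapacityError, match="large"):
            run_count(path, ExtractionOptions(k=2))
        result = run_count(path, ExtractionOptions(k=2), large_genomes=True)
        assert result.report.n_records == 257
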