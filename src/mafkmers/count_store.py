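"""Global k-mer counting: genome registry, two-tier store, partitioned merge.

The counting strategy exploits the fact that, especially at large k, most
k-mers occur exactly once per genome.  A first occurrence therefore enters
a plain *singleton set* with no stored count; only on a second occurrence
does the key move into a *counted map* with value two or more.  The two
tiers together behave exactly like an ordinary counter (a property the
tests verify), while halving the memory cost of singleton-dominated
tables in a native implementation.

Parallel merging is expressed as a contract, not a mechanism: k-mer codes
are routed to one of N partitions by a fixed 64-bit avalanche mixer
(splitmix64 finalizer) modulo N, so a given k-mer is only ever touched in
one partition, per-key updates commute, and the union of partitions is
independent of N.  Any worker scheme — thread pool, processes or a serial
loop — conforms as long as its result matches a single-worker run, which
:func:`run_count` guarantees by construction.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

from .block_counter import ExtractionOptions, KmerGroup, build_kmer_group
from .errors import CapacityError
from .kmer_codec import KmerCode, decode
from .maf_io import genome_of, read_blocks, split_into_chunks

__all__ = [
    "GenomeRegistry",
    "CounterPartition",
    "RunReport",
    "CountResult",
    "add_count",
    "partition_index",
    "merge_group",
    "run_count",
    "DEFAULT_COUNT_CAP",
    "COUNT_CAPS",
]

#: Selectable per-key count caps (8-, 16- and 32-bit unsigned maxima).
COUNT_CAPS = (255, 65535, 4294967295)
DEFAULT_COUNT_CAP = 4294967295


class GenomeRegistry:
    """First-seen-order mapping of genome names to small integer ids.

    The default capacity of 256 ids keeps genome identifiers byte-sized,
    which suits the vast majority of alignments; large-genome mode raises
    the ceiling to 65536.  Registration beyond capacity fails loudly with a
    remediation hint rather than silently dropping genomes.
    """

    DEFAULT_CAPACITY = 256
    LARGE_CAPACITY = 65536

    def __init__(self, large: bool = False):
        self.capacity = self.LARGE_CAPACITY if large else self.DEFAULT_CAPACITY
        self._name_to_id: dict[str, int] = {}
        self._names: list[str] = []

    def register(self, name: str) -> int:
        """Return the id for *name*, assigning the next free id if new."""
        if not name:
            raise ValueError("genome name must be non-empty")
        existing = self._name_to_id.get(name)
        if existing is not None:
            return existing
        if len(self._names) >= self.capacity:
            raise CapacityError(
                f"more than {self.capacity} distinct genomes; "
                "enable large-genome mode (--large_genome_count) to raise "
                "the limit to 65536"
            )
        new_id = len(self._names)
        self._name_to_id[name] = new_id
        self._names.append(name)
        return new_id

    def name_of(self, genome_id: int) -> str:
        return self._names[genome_id]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self._names)

    def __len__(self) -> int:
        return len(self._names)

    def __contains__(self, name: str) -> bool:
        return name in self._name_to_id


@dataclass
class CounterPartition:
    """One merger's share of the global table: singleton set + counted map.

    A key is in at most one tier; its effective count is 1 in the singleton
    set, the stored value (≥ 2) in the counted map, else 0.  Values saturate
    at ``count_cap``; saturated keys are recorded for the run report instead
    of wrapping.
    """

    count_cap: int = DEFAULT_COUNT_CAP
    singletons: set[tuple[int, KmerCode]] = field(default_factory=set)
    counted: dict[tuple[int, KmerCode], int] = field(default_factory=dict)
    overflowed: set[tuple[int, KmerCode]] = field(default_factory=set)

    def effective_count(self, key: tuple[int, KmerCode]) -> int:
        if key in self.singletons:
            return 1
        return self.counted.get(key, 0)


def add_count(partition: CounterPartition, key: tuple[int, KmerCode], n: int = 1) -> None:
    """Add *n* occurrences of *key* to *partition*.

    A fresh key with n=1 enters the singleton set without a stored count; a
    reoccurrence promotes it to the counted map starting at two.  Accepting
    n > 1 lets a whole block-level aggregate merge in one operation per key.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cap = partition.count_cap
    if key in partition.counted:
        total = partition.counted[key] + n
    elif key in partition.singletons:
        partition.singletons.discard(key)
        total = 1 + n
    elif n == 1:
        partition.singletons.add(key)
        return
    else:
        total = n
    if total > cap:
        total = cap
        partition.overflowed.add(key)
    partition.counted[key] = total


_MASK64 = (1 << 64) - 1


def _mix64(x: int) -> int:
    # splitmix64 finalizer: a fixed, well-dispersing 64-bit avalanche mixer,
    # chosen so partition routing is reproducible across runs and platforms.
    x &= _MASK64
    x = ((x ^ (x >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    x = ((x ^ (x >> 27)) * 0x94D049BB133111EB) & _MASK64
    return x ^ (x >> 31)


def partition_index(code: KmerCode, n_mergers: int) -> int:
    """Deterministic partition for *code* among ``n_mergers`` mergers.

    Codes wider than 64 bits are folded by XOR of 64-bit halves before
    mixing.  Pure function of ``(code.value, n_mergers)``.
    """
    if n_mergers < 1:
        raise ValueError("n_mergers must be >= 1")
    x = code.value
    while x > _MASK64:
        x = (x & _MASK64) ^ (x >> 64)
    return _mix64(x) % n_mergers


def merge_group(partitions: list[CounterPartition], group: KmerGroup) -> None:
    """Route each entry of *group* to its partition and add its count."""
    n = len(partitions)
    for (genome_id, code), count in group.counts.items():
        add_count(partitions[partition_index(code, n)], (genome_id, code), count)


@dataclass
class RunReport:
    """Summary totals plus the list of count-cap overflows."""

    n_blocks: int
    n_records: int
    total_kmers: int
    distinct_per_genome: dict[str, int]
    count_cap: int
    overflows: list[tuple[str, str, int]]  # (genome, k-mer string, cap)


@dataclass
class CountResult:
    """Final per-genome k-mer tables and the run report."""

    per_genome: dict[str, dict[KmerCode, int]]
    report: RunReport

    def string_tables(self) -> dict[str, dict[str, int]]:
        """Tables with k-mers decoded to strings (for output and oracles)."""
        return {
            genome: {decode(code): count for code, count in table.items()}
            for genome, table in self.per_genome.items()
        }


def run_count(
    maf_path: str | Path,
    opts: ExtractionOptions,
    n_workers: int = 1,
    large_genomes: bool = False,
    count_cap: int = DEFAULT_COUNT_CAP,
) -> CountResult:
    """Count k-mers per genome across all alignment blocks of a MAF file.

    The file is split into ``n_workers`` chunks of whole blocks; producers
    build per-block :class:`~mafkmers.block_counter.KmerGroup` aggregates
    (in a thread pool when ``n_workers > 1``) and each aggregate merges into
    ``n_workers`` disjoint partitions keyed by :func:`partition_index`.
    Genome ids are assigned in file order before production starts, so the
    result is identical for every ``n_workers`` ≥ 1.
    """
    if n_workers < 1:
        raise ValueError("n_workers must be >= 1")
    if count_cap not in COUNT_CAPS:
        raise ValueError(f"count_cap must be one of {COUNT_CAPS}")

    blocks = list(read_blocks(maf_path))
    registry = GenomeRegistry(large=large_genomes)
    for block in blocks:
        for record in block.records:
            registry.register(genome_of(record.src))

    plan = split_into_chunks(len(blocks), n_workers)

    def produce(chunk: tuple[int, int]) -> list[KmerGroup]:
        start, stop = chunk
        return [
            build_kmer_group(blocks[i], opts, registry, block_index=i)
            for i in range(start, stop)
        ]

    if n_workers == 1:
        chunk_groups = [produce(chunk) for chunk in plan.assignments]
    else:
        with ThreadPoolExecutor(max_workers=n_workers) as pool:
            chunk_groups = list(pool.map(produce, plan.assignments))

    partitions = [CounterPartition(count_cap=count_cap) for _ in range(n_workers)]
    total_kmers = 0
    for groups in chunk_groups:
        for group in groups:
            total_kmers += group.total_kmers()
            merge_group(partitions, group)

    per_genome: dict[str, dict[KmerCode, int]] = {name: {} for name in registry.names}
    overflow_keys: set[tuple[int, KmerCode]] = set()
    for partition in partitions:
        for genome_id, code in partition.singletons:
            per_genome[registry.name_of(genome_id)][code] = 1
        for (genome_id, code), count in partition.counted.items():
            per_genome[registry.name_of(genome_id)][code] = count
        overflow_keys |= partition.overflowed

    overflows = sorted(
        (registry.name_of(genome_id), decode(code), count_cap)
        for genome_id, code in overflow_keys
    )
    report = RunReport(
        n_blocks=len(blocks),
        n_records=sum(len(b.records) for b in blocks),
        total_kmers=total_kmers,
        distinct_per_genome={g: len(t) for g, t in per_genome.items()},
        count_cap=count_cap,
        overflows=overflows,
    )
    return CountResult(per_genome=per_genome, report=report)
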