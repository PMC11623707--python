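"""Sliding-window k-mer extraction and per-block aggregation.

K-mers are substrings of the original (ungapped) sequences, so gap
characters are removed before the window slides; the window continues
across former gap positions.  Windows containing any character outside the
alphabet (e.g. N in DNA, ``*`` in protein) are skipped individually — the
window still advances by one.  Minus-strand records are counted from the
text exactly as stored (MAF already stores the reverse-complemented
sequence for ``-`` strand); the canonical flag is the mechanism for
unifying strands when that is wanted.

Aggregating counts per block before touching the global tables exploits the
high similarity of sequences within an alignment block: repeated k-mers
collapse to a single update per block downstream.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterator

from .errors import UnsupportedOperationError
from .kmer_codec import Alphabet, KmerCode, NUCLEOTIDE, symbol_index, width_class
from .maf_io import AlignmentBlock, GAP_CHARS, genome_of

__all__ = ["ExtractionOptions", "KmerGroup", "ungap", "extract_kmers", "build_kmer_group"]


@dataclass(frozen=True)
class ExtractionOptions:
    """K-mer length, alphabet and canonical (reverse-complement) flag."""

    k: int
    alphabet: Alphabet = NUCLEOTIDE
    canonical: bool = False

    def __post_init__(self):
        width_class(self.k, self.alphabet)  # validates k range
        if self.canonical and self.alphabet.kind != "nucleotide":
            raise UnsupportedOperationError(
                "canonical aggregation requires the nucleotide alphabet"
            )


@dataclass(frozen=True)
class KmerGroup:
    """Per-block aggregate: (genome-id, k-mer code) → within-block count."""

    block_index: int
    counts: dict[tuple[int, KmerCode], int]

    def total_kmers(self) -> int:
        return sum(self.counts.values())


def ungap(text: str) -> str:
    """Remove gap characters and uppercase an aligned sequence string."""
    for gap in GAP_CHARS:
        text = text.replace(gap, "")
    return text.upper()


def extract_kmers(sequence: str, opts: ExtractionOptions) -> Iterator[KmerCode]:
    """Yield one code per valid length-k window of an ungapped sequence.

    Uses a rolling encoder: each step shifts the previous code left by one
    symbol and masks, so the cost per window is O(1) regardless of k.  When
    ``opts.canonical`` is set a reverse-complement register is rolled in the
    opposite direction and the numerically (= lexicographically) smaller of
    the two codes is emitted.
    """
    k = opts.k
    alphabet = opts.alphabet
    bits = alphabet.bits_per_symbol
    mask = (1 << (bits * k)) - 1
    hi_shift = bits * (k - 1)
    index = symbol_index(alphabet)
    use_canonical = opts.canonical

    code = 0
    rc = 0
    run = 0  # length of the current run of in-alphabet characters
    for ch in sequence.upper():
        sym = index.get(ch)
        if sym is None:
            run = 0
            code = 0
            rc = 0
            continue
        code = ((code << bits) | sym) & mask
        if use_canonical:
            rc = (rc >> bits) | ((3 - sym) << hi_shift)
        run += 1
        if run >= k:
            value = min(code, rc) if use_canonical else code
            yield KmerCode(value, k, alphabet)


def build_kmer_group(
    block: AlignmentBlock, opts: ExtractionOptions, registry, block_index: int = 0
) -> KmerGroup:
    """Aggregate the k-mers of one alignment block into a :class:`KmerGroup`.

    Records from the same genome pool into the same (genome, k-mer) entries;
    records whose ungapped length is below k contribute nothing.  Genome
    names are resolved to small integer ids through *registry* (a
    :class:`~mafkmers.count_store.GenomeRegistry`), which must therefore be
    populated or populating as blocks stream through.
    """
    counts: Counter[tuple[int, KmerCode]] = Counter()
    for record in block.records:
        genome_id = registry.register(genome_of(record.src))
        for code in extract_kmers(ungap(record.text), opts):
            counts[(genome_id, code)] += 1
    return KmerGroup(block_index=block_index, counts=dict(counts))
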