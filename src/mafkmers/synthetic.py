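"""Synthetic MAF generation and an independent brute-force counting oracle.

The generator writes well-formed MAF text with controlled structure: each
block derives every genome's row from a shared random ancestral sequence,
so rows within a block are highly similar — exactly the redundancy the
block-level aggregation path is designed to exploit.  Per-column mutation
events add substitutions, deletions (gap columns), ambiguous characters
(N for DNA, ``*`` for protein) and soft-masking; records may be flagged as
minus-strand.  Alongside the text it returns the per-genome ungapped record
strings as ground truth, so the oracle never shares the gap-removal code
under test.

:func:`oracle_count` is a deliberately naive string-window counter with no
integer codec, no partitioning and no two-tier store; it is the equivalence
reference for the whole pipeline.

What this emulates — and what it does not: block structure, gaps, ambiguity,
masking and strand flags of real multiz output are covered; realistic indel
length distributions, rate heterogeneity and genuine phylogenetic structure
are not, so passing tests demonstrate counting correctness, not biological
realism.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .kmer_codec import Alphabet, NUCLEOTIDE

__all__ = ["GeneratorSpec", "generate_maf", "oracle_count"]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of one synthetic MAF.

    Rates are per-column (or per-record for ``minus_strand_rate``)
    probabilities in [0, 1].  The same seed always reproduces the same
    bytes.  Defaults describe a small primate-like alignment: a handful of
    genomes, blocks of 50–200 columns, ~5% divergence, sparse gaps and Ns.
    """

    n_blocks: int = 10
    genomes: tuple[str, ...] = ("hg38", "panTro6", "gorGor6")
    block_len_range: tuple[int, int] = (50, 200)
    substitution_rate: float = 0.05
    gap_rate: float = 0.05
    n_rate: float = 0.01
    softmask_rate: float = 0.05
    minus_strand_rate: float = 0.2
    alphabet: Alphabet = field(default=NUCLEOTIDE)
    seed: int = 0

    def __post_init__(self):
        for name in ("substitution_rate", "gap_rate", "n_rate", "softmask_rate",
                     "minus_strand_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {rate}")
        if self.n_blocks < 0:
            raise ValueError("n_blocks must be >= 0")
        if not self.genomes:
            raise ValueError("at least one genome is required")
        lo, hi = self.block_len_range
        if not 1 <= lo <= hi:
            raise ValueError("block_len_range must satisfy 1 <= min <= max")


def generate_maf(spec: GeneratorSpec) -> tuple[str, dict[str, list[str]]]:
    """Generate MAF text plus ground-truth ungapped record strings.

    Returns ``(maf_text, truth)`` where ``truth[genome]`` lists, in file
    order, the ungapped (gap characters removed, case preserved) sequence of
    each of that genome's records.  The ``s``-line size fields are computed
    from the emitted text, so generated files always satisfy the MAF
    size/text consistency invariant.
    """
    rng = random.Random(spec.seed)
    symbols = spec.alphabet.symbols
    ambiguous = "N" if spec.alphabet.kind == "nucleotide" else "*"
    lines = ["##maf version=1 scoring=synthetic", ""]
    truth: dict[str, list[str]] = {g: [] for g in spec.genomes}
    offsets = {g: 0 for g in spec.genomes}

    for _ in range(spec.n_blocks):
        n_cols = rng.randint(*spec.block_len_range)
        ancestral = "".join(rng.choice(symbols) for _ in range(n_cols))
        lines.append(f"a score={rng.randint(0, 10000)}.0")
        for genome in spec.genomes:
            row = []
            for ch in ancestral:
                if rng.random() < spec.gap_rate:
                    row.append("-")
                    continue
                if rng.random() < spec.substitution_rate:
                    ch = rng.choice(symbols)
                if rng.random() < spec.n_rate:
                    ch = ambiguous
                if rng.random() < spec.softmask_rate:
                    ch = ch.lower()
                row.append(ch)
            text = "".join(row)
            ungapped = text.replace("-", "")
            strand = "-" if rng.random() < spec.minus_strand_rate else "+"
            start = offsets[genome]
            offsets[genome] += len(ungapped)
            lines.append(
                f"s {genome}.chr1 {start} {len(ungapped)} {strand} "
                f"100000000 {text}"
            )
            truth[genome].append(ungapped)
        lines.append("")
    return "\n".join(lines) + "\n", truth


def oracle_count(
    records_by_genome: dict[str, list[str]],
    k: int,
    alphabet: Alphabet = NUCLEOTIDE,
    canonical: bool = False,
) -> dict[str, dict[str, int]]:
    """Naive per-genome k-mer counting on plain strings.

    Slides a character window over each uppercased record, skips windows
    containing any out-of-alphabet character, and (when *canonical*) keeps
    the lexicographic minimum of the window and its string reverse
    complement.  Implemented without the codec, partitions or two-tier
    store so it can serve as an independent reference.
    """
    valid = frozenset(alphabet.symbols)
    tables: dict[str, dict[str, int]] = {}
    for genome, records in records_by_genome.items():
        table: dict[str, int] = {}
        for record in records:
            seq = record.upper()
            for i in range(len(seq) - k + 1):
                window = seq[i : i + k]
                if not valid.issuperset(window):
                    continue
                if canonical:
                    rc = window.translate(_COMPLEMENT)[::-1]
                    if rc < window:
                        window = rc
                table[window] = table.get(window, 0) + 1
        tables[genome] = table
    return tables
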