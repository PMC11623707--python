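"""MAF parsing and block-level chunking.

A MAF file is a sequence of alignment blocks.  Each block starts with an
``a`` line and carries one ``s`` line per aligned sequence::

    a score=23262.0
    s hg38.chr7    27578828 38 + 158545518 AAA-GGGAATGTTAACCAAATGA---ATTGTCTCTTACGGTG
    s panTro6.chr6 28741140 38 + 161576975 AAA-GGGAATGTTAACCAAATGA---GTTGTCTCTTATGGTG

``#`` comment lines, ``i``/``e``/``q`` annotation lines and ``track`` lines
are tolerated and ignored.  Blocks end at a blank line, at the next ``a``
line, or at end of file.  Gzip-compressed input is detected by magic bytes.

Chunking assigns contiguous runs of whole blocks to workers so that any two
chunks differ in size by at most one block; a block never spans chunks.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from .errors import MafParseError

__all__ = [
    "SequenceRecord",
    "AlignmentBlock",
    "ChunkPlan",
    "parse_blocks",
    "read_blocks",
    "open_maf",
    "split_into_chunks",
    "genome_of",
]

#: Characters treated as alignment gaps in the text column.
GAP_CHARS = "-."


@dataclass(frozen=True)
class SequenceRecord:
    """One MAF ``s`` line.

    ``start``/``size`` are ungapped, 0-based, strand-relative coordinates as
    stored in the file; counting uses only ``src``, ``strand`` and ``text``.
    """

    src: str
    start: int
    size: int
    strand: str
    src_size: int
    text: str

    def validate(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        ungapped = sum(1 for ch in self.text if ch not in GAP_CHARS)
        if ungapped != self.size:
            raise ValueError(
                f"size field is {self.size} but text has {ungapped} "
                "non-gap characters"
            )
        if self.start < 0 or self.size < 0 or self.src_size <= 0:
            raise ValueError("coordinates must be non-negative, srcSize positive")


@dataclass(frozen=True)
class AlignmentBlock:
    """One ``a`` block: an ordered list of aligned sequence records."""

    records: tuple[SequenceRecord, ...]

    def __post_init__(self):
        if not self.records:
            raise ValueError("alignment block must contain at least one record")
        width = len(self.records[0].text)
        if any(len(r.text) != width for r in self.records):
            raise ValueError("records in a block must have equal text length")


@dataclass(frozen=True)
class ChunkPlan:
    """Partition of block indices 0..n−1 into contiguous half-open ranges."""

    assignments: tuple[tuple[int, int], ...]
    n_chunks: int


def genome_of(src: str) -> str:
    """Genome name from a MAF ``src`` field: the prefix before the first dot.

    MAF convention writes ``src`` as ``<assembly>.<sequence>`` (for example
    ``hg38.chr1``); a ``src`` with no dot is returned unchanged.  This
    prefix rule is a convention of this package, documented for users.
    """
    if not src:
        raise ValueError("src field must be non-empty")
    return src.split(".", 1)[0]


def _finish_block(records: list[SequenceRecord]) -> AlignmentBlock | None:
    return AlignmentBlock(tuple(records)) if records else None


def parse_blocks(stream: Iterable[str]) -> Iterator[AlignmentBlock]:
    """Lazily parse alignment blocks from an iterable of MAF text lines.

    Yields blocks in file order.  Malformed ``s`` lines (wrong field count,
    non-integer coordinates, size/text mismatch) and ``s`` lines outside any
    block raise :class:`MafParseError` naming the 1-based line number.
    """
    records: list[SequenceRecord] | None = None
    for lineno, raw in enumerate(stream, 1):
        line = raw.strip()
        if not line:
            if records:
                yield AlignmentBlock(tuple(records))
            records = None
            continue
        if line.startswith("#"):
            continue
        tag = line.split(None, 1)[0]
        if tag == "a":
            if records:
                yield AlignmentBlock(tuple(records))
            records = []
        elif tag == "s":
            if records is None:
                raise MafParseError("'s' line outside any alignment block", lineno)
            fields = line.split()
            if len(fields) != 7:
                raise MafParseError(
                    f"'s' line has {len(fields)} fields, expected 7", lineno
                )
            _, src, start, size, strand, src_size, text = fields
            try:
                record = SequenceRecord(
                    src=src,
                    start=int(start),
                    size=int(size),
                    strand=strand,
                    src_size=int(src_size),
                    text=text,
                )
            except ValueError as exc:
                raise MafParseError(f"malformed 's' line: {exc}", lineno) from exc
            try:
                record.validate()
            except ValueError as exc:
                raise MafParseError(str(exc), lineno) from exc
            records.append(record)
        # 'i', 'e', 'q', 'track' and other annotation lines are ignored.
    if records:
        yield AlignmentBlock(tuple(records))


def open_maf(path: str | Path) -> io.TextIOBase:
    """Open a MAF file for text reading, transparently handling gzip."""
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_blocks(path: str | Path) -> Iterator[AlignmentBlock]:
    """Parse blocks from a (possibly gzipped) MAF file on disk."""
    with open_maf(path) as handle:
        yield from parse_blocks(handle)


def split_into_chunks(n_blocks: int, n_chunks: int) -> ChunkPlan:
    """Balanced partition of ``n_blocks`` block indices into ``n_chunks``.

    The first ``n_blocks % n_chunks`` chunks receive one extra block, so any
    two chunks differ in size by at most 1; surplus chunks are empty ranges.
    """
    if n_chunks < 1:
        raise ValueError("n_chunks must be >= 1")
    if n_blocks < 0:
        raise ValueError("n_blocks must be >= 0")
    base, extra = divmod(n_blocks, n_chunks)
    assignments = []
    start = 0
    for i in range(n_chunks):
        stop = start + base + (1 if i < extra else 0)
        assignments.append((start, stop))
        start = stop
    return ChunkPlan(tuple(assignments), n_chunks)
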