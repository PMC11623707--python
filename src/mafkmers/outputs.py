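"""Writers (and round-trip readers) for the two output formats plus report.

Per-genome mode writes one ``<genome>.txt`` per genome with ``<KMER>
<COUNT>`` lines.  Single-file mode writes ``kmer_counts.txt`` with one line
per distinct k-mer: ``<KMER> <GENOME>:<COUNT>[,<GENOME>:<COUNT>...]``.  Both
orderings are fixed (k-mers lexicographic, genomes alphabetical within a
line) so identical results always produce identical bytes.  ``report.txt``
summarises the run and lists any count-cap overflows.
"""

from __future__ import annotations

from pathlib import Path

from .count_store import CountResult

__all__ = [
    "DEFAULT_OUT_DIR",
    "write_per_genome",
    "write_single_file",
    "write_report",
    "read_per_genome_dir",
    "read_single_file",
]

DEFAULT_OUT_DIR = "results_counter"


def write_per_genome(result: CountResult, out_dir: str | Path) -> list[Path]:
    """Write one ``<genome>.txt`` per genome; returns the written paths.

    Lines are ``<KMER> <COUNT>`` sorted by k-mer; a genome with no k-mers
    still gets an (empty) file so the output inventory matches the input.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for genome, table in sorted(result.string_tables().items()):
        path = out_dir / f"{genome}.txt"
        with open(path, "w") as fh:
            for kmer in sorted(table):
                fh.write(f"{kmer} {table[kmer]}\n")
        paths.append(path)
    return paths


def write_single_file(result: CountResult, out_dir: str | Path) -> Path:
    """Write the consolidated ``kmer_counts.txt`` grouped by k-mer.

    Each line lists every genome in which the k-mer occurs, genomes sorted
    by name; zero-count genomes are omitted.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tables = result.string_tables()
    all_kmers = sorted({kmer for table in tables.values() for kmer in table})
    path = out_dir / "kmer_counts.txt"
    with open(path, "w") as fh:
        for kmer in all_kmers:
            entries = ",".join(
                f"{genome}:{tables[genome][kmer]}"
                for genome in sorted(tables)
                if kmer in tables[genome]
            )
            fh.write(f"{kmer} {entries}\n")
    return path


def write_report(result: CountResult, out_dir: str | Path) -> Path:
    """Write the human-readable run report, including any overflows."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = result.report
    path = out_dir / "report.txt"
    lines = [
        "mafkmers run report",
        f"blocks processed: {report.n_blocks}",
        f"records processed: {report.n_records}",
        f"total k-mers emitted: {report.total_kmers}",
        f"count cap: {report.count_cap}",
        "distinct k-mers per genome:",
    ]
    for genome in sorted(report.distinct_per_genome):
        lines.append(f"  {genome}: {report.distinct_per_genome[genome]}")
    if report.overflows:
        lines.append(f"overflowed entries (counts saturated at {report.count_cap}):")
        for genome, kmer, cap in report.overflows:
            lines.append(f"  {kmer} {genome} cap={cap}")
    else:
        lines.append("no overflows")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_per_genome_dir(out_dir: str | Path) -> dict[str, dict[str, int]]:
    """Parse per-genome output files back into string tables."""
    out_dir = Path(out_dir)
    tables: dict[str, dict[str, int]] = {}
    for path in sorted(out_dir.glob("*.txt")):
        if path.name in ("kmer_counts.txt", "report.txt"):
            continue
        table: dict[str, int] = {}
        for line in path.read_text().splitlines():
            kmer, count = line.split()
            table[kmer] = int(count)
        tables[path.stem] = table
    return tables


def read_single_file(path: str | Path) -> dict[str, dict[str, int]]:
    """Parse ``kmer_counts.txt`` back into per-genome string tables."""
    tables: dict[str, dict[str, int]] = {}
    for line in Path(path).read_text().splitlines():
        kmer, entries = line.split()
        for entry in entries.split(","):
            genome, count = entry.split(":")
            tables.setdefault(genome, {})[kmer] = int(count)
    return tables
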