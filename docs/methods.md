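# Methods

## What is being counted

A MAF file is a stream of alignment blocks; each block holds one aligned
row per sequence, with `-`/`.` gap characters padding the rows to equal
column width. `mafkmers` treats k-mers as substrings of the *original*
sequences, so each row is first ungapped (gap characters deleted, the
window continuing across former gap positions) and uppercased. Soft-masked
lowercase is annotation, not sequence identity, so it does not affect
counts. Rows are grouped by genome, taken as the prefix of the MAF `src`
field before the first dot (`hg38.chr1 → hg38`); a `src` without a dot is
its own genome name. That prefix rule is a convention of this package — MAF
itself does not define a genome/sequence split — and users with
unconventional `src` naming should pre-normalise their files.

Windows containing a character outside the alphabet (N in DNA, anything
not A–Z in protein, e.g. `*`) are skipped individually; the window still
advances one position, so a single N removes exactly k windows. K-mers
never span record or block boundaries: blocks are independent alignments of
(generally) non-adjacent regions, so joining them would manufacture k-mers
that exist in no genome. Minus-strand rows are counted as stored in the
file — MAF already stores the reverse-complemented sequence for `-` strand
rows, and re-complementing them would double-apply the transformation. The
canonical flag (`-c`) is the mechanism for strand-symmetric counting: each
DNA k-mer is pooled with its reverse complement under the lexicographically
smaller of the two.

## Encoding and width tiers

K-mers are packed big-endian into integers at 2 bits per base (A=00, C=01,
G=10, T=11) or 5 bits per amino-acid letter (A=0 … Z=25). Big-endian
packing makes integer order coincide with lexicographic order at fixed k,
so canonical selection is `min` on code values and sorted output needs no
string comparison. Supported k ranges follow fixed-width storage tiers:
nucleotide 32-bit for k ≤ 15, 64-bit for 16–31, 128-bit for 32–63; peptide
16-bit for k = 3, 32-bit for 4–6, 64-bit for 7–12, 128-bit for 13–25.
Python integers are arbitrary-precision, so the tiers act here as a
validated capability contract (the supported k ranges and the
`width_class` query) rather than a physical storage layout.

The peptide alphabet is all 26 letters, not the 20 canonical amino acids:
5 bits admit 32 symbols, and being permissive about B/J/O/U/X/Z avoids
silently dropping windows from proteomes that use ambiguity or
non-standard codes. The stop character `*` is deliberately excluded;
windows containing it are skipped like N in DNA.

## Counting strategy

Counts are aggregated twice. First per block: rows within an alignment
block are highly similar, so the same k-mer recurs across rows, and a
per-block map (one entry per distinct (genome, k-mer)) turns many window
hits into a single downstream update. Second globally, with a two-tier
store: a key's first occurrence enters a *singleton set* with no stored
count, and only a reoccurrence moves it to a *counted map* starting at
two. At large k most k-mers occur exactly once per genome, so the singleton
tier holds the bulk of keys without per-key count storage; the tests verify
the two-tier store is observationally identical to a plain counter.
Per-key counts saturate at a configurable cap (255, 65535 or the default
4294967295) and saturated keys are listed in the run report — saturation
plus a report was chosen over wrapping because a completed run with flagged
entries is diagnosable, silent wrap-around is not.

Genome names map to dense integer ids in first-seen file order. The default
capacity of 256 ids reflects that almost all alignments contain far fewer
genomes; large-genome mode raises it to 65536, and exceeding the active
capacity is a loud error that names the remedy.

## Parallel merging as a contract

The pipeline is specified by its observable result, not its thread
mechanics: the block list is split into `n_workers` contiguous chunks of
whole blocks (any two chunks differ by at most one block), producers build
per-block aggregates, and each (genome, k-mer) entry is merged into one of
`n_workers` partitions chosen by `splitmix64(code) mod n_workers`. The
splitmix64 finalizer is a fixed, public 64-bit avalanche mixer, chosen so
partition routing is reproducible across runs, platforms and Python
versions (codes wider than 64 bits are XOR-folded first). Because a given
k-mer code lands in exactly one partition and per-key addition commutes,
the union of partitions — and hence every output byte — is independent of
the worker count; genome-id assignment happens in file order before
production starts so it cannot race. The current implementation runs
producers in a thread pool when `n_workers > 1`; any scheduling is
conformant because the tests compare all worker counts against the serial
run.

## Outputs

Per-genome mode writes `<genome>.txt` with `<KMER> <COUNT>` lines;
single-file mode writes `kmer_counts.txt` with
`<KMER> <genome>:<count>[,...]` lines grouped by k-mer. The formats
themselves fix no ordering, so this package imposes one — k-mers
lexicographic, genomes alphabetical within a line, genomes with zero count
omitted, empty genomes still receiving an (empty) per-genome file — making
identical results byte-identical on disk. `report.txt` always records
blocks, records, total emitted k-mers, distinct k-mers per genome, the
active count cap and every overflowed entry (or an explicit "no overflows"
line).

## Synthetic data and the oracle

The bundled generator emits well-formed MAF: each block draws a random
ancestral sequence and derives every genome's row from it with per-column
substitutions (default 5%), deletions/gaps (5%), ambiguity characters
(1%), soft-masking (5%) and per-record minus-strand flags (20%), over
blocks of 50–200 columns — small primate-alignment-like defaults chosen to
exercise every parsing and counting path, including the intra-block
redundancy the block-level aggregation exploits. It returns the ungapped
record strings as ground truth, deliberately bypassing the gap-removal code
under test. The independent oracle counts by sliding character windows over
those strings with plain dict-of-string tables — no codec, no partitions,
no two-tier store — and is the equivalence reference for the full pipeline
across randomized conditions (1–50 blocks, 1–20 genomes, every width tier,
canonical on/off).

What the generator does not emulate: realistic indel length distributions,
substitution-rate heterogeneity, phylogenetic tree structure, chromosome
fragmentation, or MAF annotation lines carrying information (`i`/`e`/`q`
lines are parsed-and-ignored, as in real multiz output). Passing tests
therefore demonstrate counting correctness on structurally representative
input, not biological realism of the fixtures.

## Problem sizes and numerical choices

Randomized equivalence tests use 100 seeded configurations with blocks of
20–100 columns; the acceptance script uses 40 configurations plus a
reference run of 30 blocks × 5 genomes at k = 15 — sizes chosen so the
whole suite re-runs comfortably on a single CPU while still covering every
storage tier and flag combination. All randomness is seeded; hypothesis
tests run derandomized. Degenerate inputs are defined, not errors: an
empty MAF yields an empty result, a record shorter than k contributes
nothing, an all-gap row has size 0, and `n_chunks > n_blocks` simply leaves
surplus chunks empty.

## Known limitations

* The genome-from-`src` prefix rule can mis-group files whose assembly
  names themselves contain dots.
* Counting is in-memory; alignments whose distinct-key count exceeds RAM
  need an external-memory counter, which is out of scope.
* Pure-Python throughput is far below a native implementation's; the
  package prioritises a fully specified, testable contract (exact counts,
  deterministic bytes, worker invariance) over raw speed.
* Column-coordinate (alignment-space) k-mer analysis and per-chromosome
  stratification within a genome are out of scope.
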