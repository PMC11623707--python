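# mafkmers

Per-genome k-mer counting over the alignment blocks of Multiple Alignment
Format (MAF) files.

Whole-genome alignments (UCSC multiz, Cactus exports, …) store their
sequences inside MAF alignment blocks, which ordinary k-mer counters
(Jellyfish, KMC, DSK) cannot read without first exploding the file into
per-genome FASTA. `mafkmers` counts k-mers directly in the MAF: for every
genome in the alignment it produces the spectrum of its k-mer occurrences,
for nucleotide (k ≤ 63) and peptide (3 ≤ k ≤ 25) alphabets, optionally
aggregating each DNA k-mer with its reverse complement. It is aimed at
comparative genomics workflows that need per-assembly k-mer spectra from an
existing alignment.

## Method

For a record with aligned text `t`, gap characters are removed and a window
of length k slides over the resulting sequence; windows containing an
out-of-alphabet character (N, `*`) are skipped. K-mers are packed into
integers — 2 bits per base (A=00, C=01, G=10, T=11), 5 bits per amino acid —
big-endian, so integer order equals lexicographic order and the canonical
form of a k-mer `m` is simply `min(m, revcomp(m))` on code values. With the
canonical flag, counts satisfy

    count_canonical(min(m, m̄)) = count(m) + count(m̄)   for m ≠ m̄

K-mers are first aggregated per alignment block (rows of a block are highly
similar, so many windows repeat) and each block aggregate is merged into the
global tables with a single update per distinct key. Globally, a key's first
occurrence enters a singleton set with no stored count; only a reoccurrence
promotes it to a counted map starting at two — cheap for the large-k regime
where most k-mers are unique. Merging is partitioned: a fixed 64-bit
avalanche hash of the k-mer code, modulo the worker count, routes every key
to exactly one partition, so results are identical for any worker count.

## Worked example

Count canonical 5-mers in the bundled fixture alignment (3 primate genomes,
8 blocks) and write one file per genome plus a report:

```
$ mafkmers -c 5 tests/fixtures/example.maf 4 --out_dir results_counter
INFO processed 8 blocks, 24 records, 1824 k-mers; outputs in results_counter
$ head -3 results_counter/hg38.txt
AAAAG 2
AAACA 2
AAACC 4
$ head -5 results_counter/report.txt
mafkmers run report
blocks processed: 8
records processed: 24
total k-mers emitted: 1824
count cap: 4294967295
```

`AAAAG 2` means the canonical 5-mer AAAAG (covering both AAAAG and its
reverse complement CTTTT) occurs twice across hg38's ungapped sequence in
the alignment; 1824 is the total number of valid windows over all genomes.
With `-s` the same counts are consolidated into a single `kmer_counts.txt`
grouped by k-mer:

```
$ mafkmers -c -s 5 tests/fixtures/example.maf 4 --out_dir results_single
$ head -2 results_single/kmer_counts.txt
AAAAG gorGor6:3,hg38:2,panTro6:1
AAACA gorGor6:2,hg38:2,panTro6:1
```

Other flags: `--amino` (peptide alphabet), `--large_genome_count` (raise the
genome-ID capacity from 256 to 65536), `--max_kmer_count 8|16|32` (per-key
count cap; saturated counts are listed in the report rather than wrapping).

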