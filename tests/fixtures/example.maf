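##maf version=1 scoring=synthetic

a score=6252.0
s hg38.chr1 0 95 + 100000000 AAGGCCAATAAACCaNTCTGACTGGCCgAATAGGGATATAGGcAACGA-ANGTGCGGGGACCCT-G-GA-AGTGACGCTTTC-CCGTTGCCTAAACCTTT
s panTro6.chr1 0 93 + 100000000 AAGCCCAATA-ACCACTCTGACTGGC-GA-TAGGGATATAGGCAACGACATT-GCGGCGAcC-TTGCGACTGTGACGCTTTCGCCGTtGCCTAA-CCT-T
s gorGor6.chr1 0 92 + 100000000 AAG-CCAATATACC-GTCTGACTGG-CGAATAG-GATAGAGCCaACGA-ATGTGCGGCGACCCTTGCGCCAGTGAC-NT-TCACCGTTGCCTAAACC-AT

a score=5727.0
s hg38.chr1 95 102 - 100000000 ATC-TcATAGaCAC-TCGGGTTgaGAGATGGCGaCG-TCAGTGCATGAGGCCGTCCCCAGaAG-TCCCCTATGCTGT-CATCGTCGTTcCCGATGAAGACGTCTACT
s panTro6.chr1 93 101 + 100000000 ATCGTCATA-A-ACTTCgGGTNGAGAGATGGCGACGG-CAGTGCATGAgGCcGTCCCC-GAAGCTCACCTATGCTGTCCGTcGT-GtGCCCGATGAAGAC-TCTACT
s gorGor6.chr1 92 102 + 100000000 ATCGTCATaGACACtTCGGGTTTAGAGaTGGCGACGGTC-GTGC-TGAGGCCGTCCCNAGCAGC-CCCCTATGCTGTCCGNCGTTGTTCCCG-T-AAGANGTCTACT

a score=4403.0
s hg38.chr1 197 59 - 100000000 CTTAC-AAGGCTTCCTaaAAG-AATGTTTACGAGACCGTAGTCACATA-AG-GACACTGGCGC
s panTro6.chr1 194 61 - 100000000 CTTACTAA-GCTTGCT-AAAgCAATGTTNACGAGACCGTAGTCACATATAGCAACACTGGCGc
s gorGor6.chr1 194 61 - 100000000 CTTAcTAAGGCTGGCTAaAAGCAATGTTTACGAGACNGAAGTCACAGaTAGCAAcA-TGGC-C

a score=750.0
s hg38.chr1 256 106 + 100000000 AACCGgTGAGGCATTTGTTTCACACA-TTCTGACtTATTAAGGAGgATCTGTcAAcTTCATGCGNACTTCATTTACTGATAATTAA-GCTTGaCTGTGCAACAGGGGA
s panTro6.chr1 255 105 + 100000000 AACTGGNGAGGCN-TTGTTTCACACATTTCTGAATTCTTAAAGACGATCTgTCAACTNCATGCGG-CTACAATTATTGATAATTAAAGCTGGANtgtGTAACAg-GGA
s gorGor6.chr1 255 103 + 100000000 AACCgGTAAGg-ATTTGTTTCAC-cATTTCTGACTTATTAAGGACGAACTGTCAACTTCatGCGG-CTTCAtTTATTGAT-ATTAAAGGTGG-CTGTGTAACAGGGGA

a score=3323.0
s hg38.chr1 362 91 + 100000000 -T-TTT-CC-ATAGTCCCACTTAT-TTATGCAATTACTTTACGTT-G-CtGACTTAACCTTGTACTCTAGGCAAATGANCTTaCGCCCCATGGTGCAC
s panTro6.chr1 360 91 + 100000000 TGCTTTC-CCATaGTCCCACTTgTGTTATGTAATTACTATACG-tnG-CTGACTTAAACT-GTA-T-tAGGCAAAtG-CCTTACGCCCCATAGTGCAC
s gorGor6.chr1 358 95 + 100000000 -GCTTTTCN-ATAGTCCCaCTTGTCTTATGTAATTACTATACGTTGGTcTGACTAAATCTtGTACTC-AGGCAAaTGAGCTTACGCCCCATGGAGCAC

a score=6020.0
s hg38.chr1 453 63 + 100000000 GAAACCCGAACGGGCTaAACCGCAACTGTTACGTtCCTAGA-ACTGGAAGTaTGAGTCTGTCAT
s panTro6.chr1 451 60 + 100000000 GAAACCTGAACGGGCNAAACCG--AcTGCTACgTTCCTANACAcTGGAAGT-TGTGTC-GTCAT
s gorGor6.chr1 453 60 + 100000000 GAAACCCGAACGGGACA-A-CGCA-TTGCT-CGTtCCTAGaTACTGGAAGTATGTGTCTGTCAT

a score=1279.0
s hg38.chr1 516 104 + 100000000 ACTGGCAGGtGCCTCCTTTTGAT-AA-tGTCTATACcGTTGGGAGCTTCTGTAGaAGNcGCAGGCAAGCGTAANGGAAATGA-GCCGGGCTCAGCGNACTTAaCTC--T
s panTro6.chr1 511 104 + 100000000 ACTGGCAGGTGCCTCCTTTTGATCAAAGGTCT-TACAG-TGGgAGCTTCTgTCGAAGTCGCAGCCAAGCG-AAGAgAaAT-AAGCCGGGCTCAGCGTACTtAAA-CTCT
s gorGor6.chr1 513 107 + 100000000 ACTGGCATGTGNCTCCTTTtGATCAAAGGcCTATACAGNtGGGAGCTTCGGTCGA-GTCG-AGGCAAGCGTAAgGGaAATGATGCCGGGCTCAGCGTACATAAAtCTCT

a score=1080.0
s hg38.chr1 620 66 - 100000000 ACCCAgAAAGGCTACGAgTCCGGCAACACCgCcCGGCTAG-TCTTAcTTCAGCGCTCGTNACAGAAC
s panTro6.chr1 615 63 + 100000000 ACCCAGAAAGNTTACGAGTCtGGCAACACCGccCG-CTAg-T-TTAGT-CAGCGCTCGTTACAGAAT
s gorGor6.chr1 620 66 + 100000000 ACCCTGAaAGGCTACGAGGC-GGCAacACCGCTCGGCTAgGTCTtAGTCCACCGCTCGTTACAGAAT

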