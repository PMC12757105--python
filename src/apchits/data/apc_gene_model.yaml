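# APC protein coordinate system (1-based, closed intervals).
#
# The mutation cluster region (MCR) spans codons 1286-1513.  The seven
# 20-amino-acid beta-catenin-binding repeats (20AARs) are taken from the
# public APC domain annotation (UniProt P25054); truncations inside the MCR
# retain at most three of them, and truncations at codons 1928/1933 retain
# exactly five.
gene_name: APC
protein_length: 2843
annotation_source: UniProt P25054 domain annotation
mcr: [1286, 1513]
repeats_20aar:
  - [1262, 1281]
  - [1376, 1395]
  - [1492, 1511]
  - [1572, 1591]
  - [1827, 1846]
  - [1952, 1971]
  - [2029, 2048]
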