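# Reference tables

`dm6.chrom.sizes` — the sequence-length table of the *Drosophila
melanogaster* dm6 assembly (all 1,870 sequences, including unplaced
scaffolds). It is not bundled; download it with:

    curl -o data/dm6.chrom.sizes \
        https://hgdownload.soe.ucsc.edu/goldenPath/dm6/bigZips/dm6.chrom.sizes

With the file in place, the genome-arithmetic acceptance tests verify the
published genome-wide totals (144,916 one-kb tiling bins; 29,918 raw 10 kb /
5 kb sliding windows) and `scripts/acceptance.py` reports them.
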