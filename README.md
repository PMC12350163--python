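# markbins

Bin-level chromatin analysis of combinatorial histone marks at piRNA source
loci.

In *Drosophila* germ cells, the HP1-family protein Rhino marks dual-strand
piRNA clusters and licenses non-canonical transcription of transposon-rich
heterochromatin. Rhino binds H3K9me3 in vitro, yet occupies only a fraction
of H3K9me3 chromatin in vivo: a subset of its targets is explained by the
zinc-finger co-factor Kipferl, and another subset by the co-occurrence of
H3K9me3 with H3K27me3 (deposited by the PRC2 methyltransferase E(z)). This
package implements the genome-wide, bin-level analysis used to dissect that
combinatorial histone code, as a tested and reusable pipeline:

* **Genome binning and mappability** — fixed-size tiling (trailing bin
  kept) and sliding windows; exact-match *n*-mer mappability where a k-mer
  is unique iff it occurs once in the genome over both strands; per-position
  values are (unique *n*-mers overlapping the position)/*n* and per-bin
  values are unique k-mer starts per bp. Bins with mappability < 20%, below
  a minimum size, or from the mitochondrial genome are removed, and bins are
  labelled euchromatin/heterochromatin by midpoint.
* **Signal quantification** — fragments are counted into bins when at least
  half the fragment overlaps (`>=` rule, so an exact split counts in both
  bins); counts are normalized as cpm or as FPKM on the mappable effective
  length, count x 10^9 / (library x length x mappability); IgG/input
  background is subtracted on a 50 bp window grid after SES scaling (the
  scale factor matches background to signal over the least-enriched half of
  the windows) with negatives clamped to zero; standard transforms
  (log2 fold change with pseudocount, cap-and-log10, minimum-of-strands,
  median-of-ratios size factors).
* **Combinatorial-mark classification** — tie-aware ROC curves built from
  cumulative TP/FP counts with trapezoidal AUC; mark combination as the
  per-bin mean of two enrichment tracks; consensus peaks supported by >= 2
  replicates; per-bin presence calls; 2x2 odds ratios (a·d/b·c, Haldane 0.5
  when a cell is empty) with two-sided Fisher exact p values; Venn region
  counts; equal-rank level groups for violin-style summaries.
* **Dependency classification** — a bin is Rhino-dependent when its mean
  piRNA fold loss (control/depleted cpm) across depletion strategies
  exceeds 2; Rhino-dependent bins are split into E(z)-dependent,
  Kipferl-dependent, both, or neither at a 4-fold threshold; occupancy
  peaks with >= 3-fold enrichment form a high-confidence set whose members
  are Kipferl-dependent iff they vanish in the Kipferl knockdown; the
  delta-group analysis ranks bins by the H3K27me3 change after E(z) loss
  into six equal groups, optionally restricted to bins above the 90th
  percentile of euchromatic H3K9me3.
* **Synthetic data with ground truth** — a seeded generator produces a toy
  genome (with exact-repeat blocks, a mitochondrion-like sequence and an
  unplaced scaffold), per-bin mark states, cluster and dependency labels,
  negative-binomial fragment counts and stranded piRNA reads responding to
  each knockdown, so every stage is testable without any real data.

## Worked example

```bash
markbins simulate --seed 1 --out fixture/
markbins run-all --fixture fixture/ --out results/
```

or equivalently in Python:

```python
from markbins import SimulationConfig, run_pipeline
from markbins.simulate import simulate_cohort, write_fixture

cohort = simulate_cohort(SimulationConfig(seed=1))
write_fixture(cohort, "fixture")
result = run_pipeline("fixture", "results")
print(result.classify.auc_table)
```

On the default cohort (five 600 kb chromosomes, 1 kb bins, two replicates
per track) this prints

```
              H3K9me3  H3K27me3  combined_mean
dual_strand  0.937269   0.85328       0.968833
unistrand    0.458516   0.43502       0.394760
```

i.e. H3K9me3 signal alone predicts dual-strand cluster bins with AUC 0.937
and H3K27me3 with 0.853, while the mean of the two marks classifies better
than either alone (AUC 0.969) — the combinatorial-code signature the
analysis is designed to detect. Unistrand clusters, placed in unmarked
chromatin by the generator, are not predicted by either mark. The same run
yields stratified odds ratios for reader-protein binding of 312.8
(both marks) > 13.4 (H3K9me3 only) > 1 > 0.29 (H3K27me3 only), recovers 140
Rhino-dependent bins (125 true dual-strand cluster bins plus sampling
noise), and splits the high-confidence occupancy peaks into 223
Kipferl-dependent and 118 Kipferl-independent peaks, exactly matching the
simulated truth.

Result tables (`bins.tsv`, `mark_enrichment.tsv`, `auc.tsv`, `or_table.tsv`,
`venn.tsv`, `dependency.tsv`, `peak_dependency.tsv`, `delta_groups.tsv`,
`report.json`, `manifest.json`) are deterministic: re-running with the same
seed and inputs reproduces identical bytes.

## Layout

```
src/markbins/
  genome.py      FASTA / chrom.sizes containers and I/O
  binning.py     tiling, sliding windows, mappability, filtering, compartments
  quantify.py    fragment counting, FPKM/cpm, SES background subtraction, transforms
  classify.py    ROC/AUC, consensus peaks, presence calls, odds ratios, Venn, level groups
  dependency.py  Rhino / E(z) / Kipferl dependency of bins and peaks, delta groups
  simulate.py    synthetic cohort generator with ground truth
  evaluate.py    scoring pipeline output against the simulated truth
  pipeline.py    stage orchestration, result tables, manifest
  cli.py         `markbins` command-line interface
```
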