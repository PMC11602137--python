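# dsbdart

Strand-resolved analysis of nascent transcription around sequence-specific DNA
double-strand breaks (DSBs).

## What this is for

When a restriction enzyme such as AsiSI (recognition motif 5′-GCGATCGC-3′) is
conditionally activated in cells, it cuts a defined set of genomic sites,
and chromatin-associated RNA sequencing (chrRNA-seq) captures the nascent
transcription these breaks induce — *damage-associated RNA transcripts*
(DARTs), which arise on both strands and decay with distance from the cut.
Because chrRNA-seq libraries are stranded, each read reports a transcript
orientation, and transcription at a break can be split into **sense** (running
with the neighbouring gene) and **antisense** (running against it).

`dsbdart` implements that analysis as a tested, reusable pipeline for
computational biologists working with DSB-induction systems:

- protocol-aware assignment of alignments to transcript strands
  (dUTP-type "reverse" libraries or "forward" ones);
- CPM-normalized per-base coverage, split by strand
  (CPM at base *p* = reads covering *p* × 10⁶ / library size);
- DSB-anchored flank matrices: one row per site, one column per bin over
  `[anchor − flank, anchor + flank)` (defaults 2.5 kb flanks, 1 bp bins →
  5000 columns);
- sense/antisense annotation of matrix bins against gene orientation, with
  per-site summation over gene regions and removal of sites whose flank
  overlaps no gene;
- site stratification: cleavage-efficiency ranking from DSB-capture read
  counts in ±500 bp windows, HR-prone vs NHEJ-prone labelling from the
  RAD51 (±4 kb) to XRCC4 (±1 kb) coverage ratio (top/bottom *k* = 30),
  and high/low transcription classes from baseline sense coverage;
- statistics: metagene profiles (mean ± SEM per bin), windowed coverage
  sums, log₂ fold changes `log2((W_cond + c) / (W_ctrl + c))` over a 500 bp
  window at the break, two-sample Wilcoxon (Mann–Whitney) rank-sum tests,
  replicate PCA, and 2^(−ΔΔCt) qPCR fold enrichment;
- figures: metagene line plots with separate sense/antisense scales,
  heatmaps ordered by ascending cleavage efficiency, per-site fill plots,
  box plots, PCA scatters;
- a synthetic-data generator with a machine-readable truth file, so every
  stage can be validated at desk scale against planted ground truth.

Inputs are plain text: BED6 reads/sites/genes (SAM/BAM via an optional
adapter), GTF gene annotation, chrom.sizes, bedGraph tracks, FASTA for motif
scanning. All coordinates are 0-based half-open throughout.

## Worked example

Run the shipped demo (a 2 × 300 kb genome, 50 genes, 12 cut + 12 uncut sites
and one deliberately gene-free site, two replicates per condition):

```bash
dsbdart run --config examples/demo.yaml --seed 7 --outdir demo_out
```

```
INFO dsbdart.pipeline: excluded site (no gene in flank): free_001
INFO dsbdart.stats: log2_fold_change: 11 sites with zero coverage in both conditions
pipeline complete: 39 outputs under demo_out
```

`demo_out/manifest.json` then records, among other things:

```
median_log2fc_sense_cut      0.373
median_log2fc_antisense_cut  0.936
ranksum p (anti vs sense)    3.7e-05
PCA explained variance       [0.997, 0.002, 0.001, 0.000]
```

Reading: the simulated knockdown multiplies damage-induced transcription by
1.3 (sense) and 2.0 (antisense) at cut sites, and the windowed fold-change
medians recover those planted multipliers on the log₂ scale
(log₂ 1.3 ≈ 0.38, log₂ 2 = 1) up to sampling noise at this small scale; the
rank-sum test confirms the antisense increase exceeds the sense one, and PC1
separates the two conditions while replicates stay together. The gene-free
site `free_001` is removed by the exclusion rule because its reads cannot be
oriented. Individual stages are also available as subcommands
(`simulate`, `coverage`, `matrix`, `orient`, `stratify`, `metagene`,
`foldchange`, `test`, `pca`, `scanmotif`, `plot`) and as library functions.

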