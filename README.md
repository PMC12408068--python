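# loophub

Analysis toolkit for chromatin-loop topology around condition-specific
(methylation-sensitive) CTCF peaks, with a truth-labelled synthetic data
generator so that every stage is testable without external downloads.

The pipeline covers:

- **Condition-specific peak sets** — peaks called only in the treated
  condition (zero overlap with any baseline peak), annotated by midpoint
  with the priority promoter > TTS > exon > intron > intergenic.
- **Loop topology** — per-peak distinct-loop counts over filtered loop
  lists (FDR < 0.01, > 4 PETs per condition), maximally-looping partner
  counts, and a superenhancer-style "highly looping" caller: peaks are
  ranked by loop count, the curve is scaled to the unit square, and the
  cutoff sits where the tangent slope reaches 1 (argmin of scaled count −
  scaled rank); peaks above the cutoff count are highly looping.
- **Differential loop strength** — replicate-consistency filters (total
  PETs ≥ 8 across samples; loops strong in one replicate, absent in the
  other are removed), pseudocount CPM, mean logCPM and log2 fold-change
  between conditions, and fold-change stratification by anchor overlap
  with a peak set (Mann-Whitney comparison).
- **Speckle-signal integration** — mapping 20 kb binned signal onto
  peaks/loops (unweighted mean of overlapping bins), equal-count decile
  stratification (pandas-qcut semantics, duplicate edges dropped), the
  ≥ 90th-percentile genome-wide speckle-association rule, Pearson
  correlation of loop strength with signal, and strand-aware aggregate
  profiles.
- **Contact pileups** — per-chromosome observed/expected at 10 kb,
  blacklist exclusion (within 1000 bp), per-bin deduplication keeping the
  strongest peak, minus-strand reflection across the diagonal, and
  cellwise mean O/E windows reported as log2(mean O/E).
- **Expression clusters** — differential-gene selection (p-adj < 0.05,
  |log2FC| > 0.5), per-gene z-scoring, K-means (K=4) with seeded restarts
  and deterministic label ordering, and per-cluster covariates (mean peak
  binding fold-change on member genes; speckle signal over genes).
- **Synthetic data** — a seeded generator that plants hub anchors near
  speckle-signal peaks, condition-specific peaks on gene bodies,
  negative-binomial replicate PET counts whose means scale with anchor
  speckle signal, strengthened loops (2^delta in condition B),
  distance-decay contact matrices with enriched loop pixels, and four
  expression archetypes — all recorded in machine-readable truth tables.

## Command line

```sh
loophub simulate --outdir data --seed 1           # synthetic dataset
loophub peaks    --cond-a data/peaks_A_1.bed --cond-a data/peaks_A_2.bed \
                 --cond-b data/peaks_B_1.bed --cond-b data/peaks_B_2.bed \
                 --genes data/genes.gff3 --genome data/genome.txt --out peaks.tsv
loophub topology --peaks peaks.tsv --loops data/loops.bedpe --out topo.tsv
loophub diffloops --loops data/loops.bedpe --peaks topo.tsv --out diff.tsv
loophub signal   --track data/son_B.bedgraph --genome data/genome.txt \
                 --peaks topo.tsv --out signal.tsv
loophub pileup   --matrix data/matrix_chr1.tsv.gz --matrix data/matrix_chr2.tsv.gz \
                 --peaks signal.tsv --subset speckle \
                 --blacklist data/blacklist.bed --out pileup.tsv
loophub clusters --expr data/expression.tsv --peaks signal.tsv \
                 --track data/son_A.bedgraph --genome data/genome.txt --out clusters.tsv
loophub run-all  --outdir out --seed 1            # everything, summary.json
```

`loophub run-all` writes a machine-readable `summary.json` recording every
threshold used plus the per-stage headline numbers.

## Formats

- BED6 / bedGraph: standard, 0-based half-open.
- BEDPE: 10 fixed columns, then per-sample PET columns declared in the
  header (`pet:<condition>:<replicate>`), then `fdr`. Anchors are
  canonicalized (anchor1 leftmost); inter-chromosomal rows are skipped
  with a warning.
- Contact matrices: one dense symmetric text matrix per chromosome with a
  `#contactmatrix chrom=… bin_size=… n_bins=…` header; `nan` marks
  missing entries; `.gz` supported.
- GFF3: genes and exons only, converted to half-open on read.
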