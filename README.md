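# methsplice

Genome-wide association analysis between gene-body CpG methylation and
alternative splicing for invertebrate genomes, with a synthetic-data
generator that plants a fully known ground truth in every input.

## The scientific problem

In many invertebrates (the honeybee *Apis mellifera* is the canonical
case) DNA methylation is largely confined to exons of gene bodies, and
its regulatory role is debated.  Rather than silencing transcription,
exon methylation appears linked to splicing: exons retained in the
mature transcript tend to be more methylated than exons that are
skipped, and methylated genes are enriched for alternative splice
variants.  Methylated and alternatively spliced genes also tend to be
longer, exon-richer and more conserved across species.

`methsplice` implements this analysis chain as a tested, reusable
pipeline operating on four standard inputs:

1. a gene/transcript/exon annotation (GFF3),
2. a per-CpG bisulfite methylation-call table
   (`chrom  pos  meth_reads  unmeth_reads`),
3. exon/intron RPKM and transcript FPKM tables,
4. a per-(gene, species) best-hit E-value table.

## Statistics implemented

* **Per-site methylation level** `mCG = m / (m + u)` from methylated
  (`m`) and unmethylated (`u`) read counts; region aggregates
  *relative* methylation `mCG/CG = Σ mCG / #CpG` and *absolute*
  methylation `mCG/length = Σ mCG / bp`.
* **Gene methylation call**: a gene is methylated iff its body (union
  span over all splice variants, introns included) contains ≥ 1 CpG
  with `mCG > 0`.
* **Inclusion calls**: an exon (or intron) with `RPKM > 0` is included
  in transcription, with `RPKM = 0` skipped.  A gene is alternatively
  spliced at threshold *t* when ≥ 2 structurally distinct transcripts
  have `FPKM ≥ t`.
* **Boundary meta-profiles**: methylation in 20 equal intervals across
  ± 200 bp of exon/intron start and end anchors (strand-aware), with a
  one-sided Wilcoxon rank-sum test per interval comparing included vs
  skipped features; gene-body profiles in 100 bp bins ± 2 kb of gene
  start/end by expression quintile.
* **Association tests**: Pearson/Spearman correlation of gene
  methylation with expression over expressed-and-methylated genes;
  Fisher's exact test of splicing enrichment in methylated genes across
  a grid of minimum-FPKM thresholds; ECDF contrasts of gene length and
  exon count with the continuity-corrected two-sided rank-sum test.
* **Conservation**: a gene counts as conserved in a species iff its
  best protein-alignment E-value is strictly below 1e-150; category
  contrasts use Fisher's exact test with hitless genes scored
  non-conserved.

Both exact tests are implemented from first principles (hypergeometric
summation; rank enumeration with midranks for ties) and are
cross-checked in the test suite against independent enumeration oracles
and against SciPy.

## Worked example

Simulate a bundle and run the full analysis:

```sh
methsplice simulate --outdir bundle --seed 1
methsplice run --indir bundle --outdir out
```

`out/` then contains headered TSVs (`gene_summary.tsv`,
`profile_exons_start.tsv`, `enrichment.tsv`, `correlation.tsv`,
`contrasts.tsv`, `conservation_contrasts.tsv`, …) plus a `manifest.json`
recording config, input checksums and row counts.  With the default
simulation (2000 genes, planted splicing odds ratio 3, included-exon
methylation at beta mean 0.4 vs 0.05 for skipped exons), the run at
seed 1 reports:

* `enrichment.tsv`, threshold 0: odds ratio **2.93**, Fisher
  P = 8.7e-19 over 1398 expressed genes — the planted 3-fold enrichment
  of splicing in methylated genes is recovered;
* `profile_exons_start.tsv`: all **10/10** within-exon intervals
  significantly more methylated in included than skipped exons
  (one-sided rank-sum, α = 0.05), while upstream intervals are flat;
* `correlation.tsv`: Pearson r = **0.003**, Spearman ρ = **0.001**
  (n = 693 expressed-and-methylated genes) — no gene-level
  methylation–expression correlation, as none is planted;
* `conservation_contrasts.tsv` (`H_sapiens`, methylated vs
  unmethylated): proportions **0.219 vs 0.097**, Fisher P ≈ 5e-14.

The same library calls are available programmatically
(`methsplice.simulate_bundle`, `methsplice.run_pipeline`, and the
individual analysis functions).

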