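# Methods

## Scope and model

`methsplice` analyses the relationship between gene-body CpG
methylation and transcription in genomes where methylation is
concentrated in exons.  The analysis chain is: per-site methylation
levels → gene methylation calls → exon/intron inclusion calls →
boundary-anchored methylation meta-profiles → gene-level association
tests (correlation, splicing enrichment, size-distribution contrasts)
→ cross-species conservation contrasts.  Raw sequencing, alignment,
methylation calling, transcript assembly and BLAST searches are out of
scope; all inputs arrive as tables.

## Methylation metrics

For a CpG site covered by `m` methylated and `u` unmethylated reads
(`m + u ≥ 1`), the level is `mCG = m / (m + u)`.  Over a region, two
aggregates are used:

* relative methylation `mCG/CG = (Σ site mCG) / (number of CpG sites)`,
  bounded in [0, 1] and undefined (NaN) for CpG-free regions;
* absolute methylation `mCG/length = (Σ site mCG) / (region length in
  bp)`, always defined and 0 iff no methylation mass is present.

These are the standard fractional readings of the two ratio labels;
the aggregation is the only interpretation that keeps the relative
value bounded and makes both metrics additive over region partitions
(a property the tests verify).  A gene is classified methylated when
any CpG in its body — the union span of all splice variants including
introns — has `mCG > 0`.  This is a deliberately permissive rule (a
single partially methylated read suffices); it is the convention the
downstream contrasts assume, and an optional minimum-coverage filter
(default off) is the only pre-filtering exposed.

Coordinates are 0-based half-open internally; loaders accept a
one-based flag.  A site is counted at its cytosine coordinate only; an
optional merge collapses plus/minus-strand records at adjacent
coordinates into one CpG.

## Inclusion and splicing calls

Exons with `RPKM > 0` are included in transcription, exons with
`RPKM = 0` are skipped; introns follow the same rule.  The hard zero
threshold mirrors the classification convention of the source analysis
rather than modelling count noise.  `RPKM = reads / (kb × millions of
mapped reads)`.  Gene expression is FPKM summed over transcripts
(consistent with fragment assignment across isoforms being additive).
A gene is alternatively spliced at threshold *t* when at least two
*structurally distinct* transcripts (compared on their ordered
exon-interval lists) reach `FPKM ≥ t` (strictly positive when
`t = 0`); duplicate structures are treated as assembly artifacts.  The
enrichment analysis sweeps *t* over a configurable grid (default 0,
0.5, 1, 2, 5) because abundance estimates are unreliable at low
expression; at each threshold only genes expressed there enter the
table, since an unexpressed gene's splicing status is unobservable.

## Meta-profiles

A boundary profile fixes ± `flank` bp (default 200) around a feature's
biological start or end and divides the window into `n_bins` equal
intervals (default 20, i.e. 20 bp bins).  Anchors are strand-aware:
bins are ordered 5'→3' in transcription direction, so "after the
start" always points into the feature.  Windows have fixed width
regardless of feature length; for features shorter than the flank the
inner bins extend past the feature (a geometric consequence of the
fixed-window design, shared by both classes being compared).  Windows
truncated at a chromosome edge keep their bins with reduced effective
lengths in the absolute-metric denominator rather than being dropped.

Each feature contributes one value per bin (absolute metric by
default; the relative metric is undefined in CpG-free bins and those
features drop out of that bin's sample).  Per bin, included and
skipped features are compared with a one-sided Wilcoxon rank-sum test
(included > skipped), at α = 0.05 per interval with no correction
across intervals by default — the per-interval testing convention of
the original analysis; Bonferroni and Benjamini–Hochberg are available
by flag.  The per-feature (rather than pooled) reading is required for
a rank-sum test within each interval to have per-observation samples.
A bin where either class has no defined values is reported untestable,
never significant.

Gene-body profiles rank expressed genes (FPKM > 0) into five
equal-size quintiles (ties broken by gene id for determinism; quintile
5 = highest expressed) and report the per-bin mean metric in 100 bp
bins ± 2 kb around gene start and end.  The gene interior between the
two anchored windows is not rescaled or stitched; only the two
anchored windows are produced.

## Statistical tests

`fisher_exact_2x2` sums hypergeometric probabilities over all tables
with the observed margins whose probability does not exceed the
observed table's (relative tie tolerance 1e-9) — the R `fisher.test`
convention; one-sided variants sum the corresponding tail.  The odds
ratio is the cross-product ratio, undefined when `b·c = 0`.

`wilcoxon_rank_sum` uses midranks; its statistic is the rank sum W of
the first sample.  With both samples ≤ 10 an exact P is computed by
enumerating every assignment of the pooled (possibly tied) ranks;
otherwise the normal approximation with tie-corrected variance and an
optional 0.5 continuity correction is used (matching R's
`wilcox.test` with `correct=TRUE`).  Two-sided exact P doubles the
smaller tail, capped at 1.

Correlations use the standard large-sample P machinery (t for Pearson,
tie-aware normal for Spearman, via SciPy).  Zero-variance inputs are
flagged undefined rather than erroring.

Distribution contrasts report full ECDFs of gene length (maximum
transcript extent including introns, over all splice variants) or exon
count (maximum over variants), tested two-sided with continuity
correction.  The four panel contrasts are methylated vs unmethylated
(all genes), spliced vs unspliced (expressed genes), and methylated vs
unmethylated within each splicing stratum.

Conservation: a gene is conserved in a species iff its best E-value is
strictly `< 1e-150`; a value of exactly 1e-150 is non-conserved.
Duplicate (gene, species) rows keep the minimum E-value.  Genes absent
from the table had no hit and count as non-conserved, so proportions
are always over the full gene universe of the contrast; restricting a
contrast to a stratum (e.g. spliced vs unspliced within methylated
genes) is done by restricting that universe.

## The synthetic-data generator

The generator emulates the statistical structure the analysis is built
to detect, not sequencing physics (no raw reads, bisulfite conversion
errors or alignment artifacts).  Per gene it plants three Bernoulli
flags — methylated, alternatively spliced, expressed — with the
spliced flag drawn conditionally on the methylation flag so that the
population odds ratio is exactly `splicing_odds_ratio` while the
marginal spliced fraction stays at `frac_genes_spliced` (the
conditional rates are solved by root-finding).  Genes are placed
without overlap or nesting, keeping CpG ownership unambiguous; spliced
genes get a second transcript missing one exon.

Methylated genes are planted longer (`meth_length_scale`, default 2×
on feature lengths) and exon-richer (`meth_exon_factor`, default 1.5×
on exon counts), emulating the observed association of methylation
with gene size; both knobs can be set to 1 for size-neutral genomes.

CpG sites follow a Poisson process (mean spacing 60 bp — a gene-dense,
CpG-rich caricature at desk scale).  True site levels are Beta draws
per context: included exons Beta(4, 6) (mean 0.4), skipped exons
Beta(1, 19) (mean 0.05), introns Beta(1, 49), intergenic Beta(1, 99)
— ordered included > skipped > intron, matching the qualitative
profile structure of exon-targeted methylomes.  Genes planted
unmethylated are forced to a true level of exactly 0 so the
`mCG > 0` rule is exactly recoverable.  Read depth is Poisson(30);
observed counts are Binomial(depth, level); zero-depth sites are
unobserved.  Degenerate Beta parameters (α = 0 or β = 0) produce exact
point masses for boundary testing.

Included exons/introns of expressed genes get lognormal(1, 1.2) RPKM,
skipped features exactly 0 (a noise switch adds sub-threshold uniform
noise for robustness experiments); transcript FPKM is lognormal for
expressed genes and 0 otherwise, so inclusion and splicing calls
recover the planted labels exactly with the noise switch off.
Conservation flags are Bernoulli per (species, planted category), with
E-values of 1e-200 (conserved) or 1e-100 (non-conserved) straddling
the threshold; 30% of non-conserved gene–species pairs are omitted
from the table to exercise the no-hit path.

Because skipped features are exactly zero and unmethylated genes
exactly unmethylated, passing recovery tests demonstrates correctness
of the analysis logic, not robustness to count noise, coverage bias,
annotation error or overlapping genes — real data differ in all four
respects.

## Numerical and design choices

* Equal-width bins require `2 × flank` divisible by `n_bins`; the
  boundary default is 20 bins of 20 bp across the ± 200 bp window.
* Expression tables are joined to the annotation by feature id; exon
  ids number the gene's merged exon union in genomic order
  (`gene.e1…`), intron ids the gaps between union exons (`gene.i1…`).
* The Fisher test is two-sided by default (one-sided available); the
  "expressed" restriction for the correlation analysis is
  `gene FPKM > 0` (threshold configurable).
* Determinism: every generator stage derives its RNG from (seed, stage
  index); equal config + seed reproduces all outputs byte for byte,
  and the pipeline manifest contains no timestamps or absolute paths.
* Degenerate inputs are flagged, not fatal: untestable bins, degenerate
  contingency margins and zero-variance correlations are reported with
  NaN statistics and a `testable`/`defined` flag.

## Validation problem sizes

The test suite validates type-I error control of the per-interval test
with 200 replicate null genomes (~230 genes, ~690 exons per class,
identical Beta levels in all contexts), effect recovery with 50
replicates at ~2400 exons per class (exon lengths 200–400 bp so all 10
downstream intervals lie within exons), enrichment recovery at 2000
genes against a precomputed 99% Monte-Carlo sampling interval of the
odds ratio, length-shift detection with 100 replicates at 500 genes
per group, and conservation recovery at 2000 genes against exact
binomial 99% intervals.  Exact-test equivalence is checked
exhaustively for all 2×2 tables with N ≤ 40 and by full assignment
enumeration for rank-sum samples up to size 8.

## Known limitations

* Expression is planted, not derived from read counts, so RPKM/FPKM
  magnitudes carry no depth-dependent uncertainty.
* Only one alternative transcript per spliced gene is simulated; real
  isoform diversity is richer.
* Intron inclusion is planted independently of methylation, so intron
  profiles are null by construction.
* The gene universe for conservation proportions is a configuration
  choice; with real data the choice (all annotated genes vs analysed
  genes) materially affects proportions and should be recorded.
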